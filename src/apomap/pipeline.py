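"""End-to-end orchestration: generate/ingest -> segment -> map -> tabulate,
profile registration batches, and model scenario runs.

Every run is deterministic given its configuration: the top-level seed is
fanned out to per-embryo / per-batch streams through
``numpy.random.SeedSequence`` spawning, and the configuration (seed included)
is echoed into every summary the pipeline writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from .errors import ConfigError, RegistrationError
from .mapping import (
    ApoptosisHistogram,
    EventRecord,
    exclude_midline,
    map_events,
    order_boundaries,
    tabulate_histogram,
)
from .model import simulate_scenario, count_bands, subthreshold_area
from .profiles import (
    RegisteredProfile,
    average_registered,
    detect_landmark_peaks,
    register_profiles,
)
from .segmentation import detect_events, segment_stripes, skeletonize_stripes
from .synthetic import (
    GroundTruth,
    SyntheticEmbryoSpec,
    generate_embryo_image,
    generate_profile_samples,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "MappingResult",
    "ProfileResult",
    "run_mapping_pipeline",
    "run_profile_pipeline",
    "run_model_scenario",
]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (synthetic batch or image files)."""

    # input: either synthetic generation ...
    synthetic: dict = field(default_factory=dict)  # SyntheticEmbryoSpec overrides
    n_embryos: int = 5
    # ... or pre-existing TIFFs
    images: list[str] = field(default_factory=list)
    channels: dict = field(
        default_factory=lambda: {"landmark": 0, "event": 1, "signal": 2}
    )
    # segmentation
    stripe_threshold: float | None = None  # default: stripe_intensity / 2
    event_threshold: float | None = None
    stripe_min_area_px: int = 50
    event_min_area_px: int = 4
    event_max_area_px: int | None = None
    prune_len_px: int = 10
    # mapping
    midline_fraction: float = 0.20
    n_bins: int = 10
    normalize_histogram: bool = True
    # profiles
    n_samples: int = 10
    jitter_sd_px: float = 2.0
    bins_per_segment: int = 50
    peak_min_separation_px: float | None = None  # default: half the stripe spacing
    peak_min_prominence: float | None = None
    # bookkeeping
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    def spec(self, seed: int | None = None) -> SyntheticEmbryoSpec:
        d = dict(self.synthetic)
        if seed is not None:
            d["seed"] = int(seed)
        d.setdefault("seed", self.seed)
        return SyntheticEmbryoSpec.from_dict(d)

    def echo(self) -> dict:
        return asdict(self)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class MappingResult:
    records_per_embryo: list[list[EventRecord]]
    histogram: ApoptosisHistogram
    summary: dict
    ground_truths: list[GroundTruth | None]


def _map_one_embryo(
    image: np.ndarray, config: RunConfig, spec: SyntheticEmbryoSpec | None
) -> list[EventRecord]:
    ch = config.channels
    n_chan = image.shape[0]
    for role in ("landmark", "event"):
        if role not in ch or not 0 <= ch[role] < n_chan:
            raise ConfigError(
                f"channel role {role!r} missing or out of range for {n_chan}-channel image"
            )
    ref_intensity = spec.stripe_intensity if spec is not None else float(image[ch["landmark"]].max())
    s_thr = config.stripe_threshold if config.stripe_threshold is not None else ref_intensity / 2
    e_thr = config.event_threshold if config.event_threshold is not None else s_thr
    labels = segment_stripes(image[ch["landmark"]], s_thr, config.stripe_min_area_px)
    skeleton = skeletonize_stripes(labels, prune_len=config.prune_len_px)
    events = detect_events(
        image[ch["event"]], e_thr, config.event_min_area_px, config.event_max_area_px
    )
    boundaries = order_boundaries(skeleton)
    records = map_events(events.events, boundaries)
    exclude_midline(records, 0.0, image.shape[1], config.midline_fraction)
    return records


def run_mapping_pipeline(config: RunConfig) -> MappingResult:
    """Full event-mapping chain over a batch of embryos.

    Generates synthetic embryos (or reads configured TIFFs), segments stripes
    and events, maps every event into segment-relative coordinates, applies
    midline exclusion, and tabulates the cross-embryo position histogram.
    Writes event/histogram CSVs and a JSON summary when ``out_dir`` is set.
    """
    logging.basicConfig(level=config.log_level)
    per_embryo: list[list[EventRecord]] = []
    truths: list[GroundTruth | None] = []
    if config.images:
        for path in config.images:
            img = _io.read_image(path)
            per_embryo.append(_map_one_embryo(img, config, None))
            truths.append(None)
    else:
        for s in _child_seeds(config.seed, config.n_embryos):
            spec = config.spec(seed=s)
            img, gt = generate_embryo_image(spec)
            per_embryo.append(_map_one_embryo(img, config, spec))
            truths.append(gt)

    hist = tabulate_histogram(per_embryo, config.n_bins, config.normalize_histogram)
    n_total = sum(len(r) for r in per_embryo)
    n_mid = sum(r.excluded_midline for recs in per_embryo for r in recs)
    n_unmap = sum(r.unmappable and not r.excluded_midline for recs in per_embryo for r in recs)
    n_kept = sum(r.retained for recs in per_embryo for r in recs)
    assert n_kept + n_mid + n_unmap == n_total  # conservation
    summary = {
        "n_embryos": len(per_embryo),
        "events_detected": n_total,
        "events_retained": n_kept,
        "events_midline_excluded": n_mid,
        "events_unmappable": n_unmap,
        "config": config.echo(),
    }
    logger.info(
        "mapped %d embryos: %d events (%d retained, %d midline-excluded, %d unmappable)",
        len(per_embryo), n_total, n_kept, n_mid, n_unmap,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = [
            _io.records_to_frame(recs, embryo_id=i) for i, recs in enumerate(per_embryo)
        ]
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(out / "events.csv", index=False)
        _io.histogram_to_frame(hist).to_csv(out / "histogram.csv", index=False)
        _io.write_json(out / "summary.json", summary)
    return MappingResult(per_embryo, hist, summary, truths)


@dataclass
class ProfileResult:
    profile: RegisteredProfile
    failures: list[tuple[int, str]]
    summary: dict


def run_profile_pipeline(config: RunConfig, samples=None) -> ProfileResult:
    """Profile batch: simulate ROI traces, register each to its landmark peaks,
    average with SEM.

    Per-sample registration failures are recorded and skipped; the batch fails
    only when fewer than two samples register.  ``samples`` may supply
    pre-extracted :class:`~apomap.synthetic.ProfileSample` traces (e.g. from
    real ROIs); by default a synthetic batch is generated from the config.
    """
    logging.basicConfig(level=config.log_level)
    spec = config.spec()
    if samples is None:
        samples = generate_profile_samples(
            spec, config.n_samples, jitter_sd_px=config.jitter_sd_px
        )
    spacing = float(np.min(np.diff(spec.boundary_x_px)))
    sep = config.peak_min_separation_px or spacing / 2
    prom = (
        config.peak_min_prominence
        if config.peak_min_prominence is not None
        else spec.stripe_intensity / 4
    )
    registered, failures = [], []
    names = None
    for i, sample in enumerate(samples):
        try:
            peaks = detect_landmark_peaks(sample.traces["landmark"], sep, prom)
            traces = np.vstack([sample.traces[c] for c in sample.channels])
            registered.append(register_profiles(traces, peaks, config.bins_per_segment))
            names = tuple(sample.channels)
        except RegistrationError as exc:
            logger.warning("sample %d failed to register: %s", i, exc)
            failures.append((i, str(exc)))
    if len(registered) < 2:
        raise RegistrationError(
            f"only {len(registered)} of {len(samples)} samples registered; need >= 2"
        )
    # samples may span different peak counts; crop to the common segment count
    n_seg = min(r.shape[1] // config.bins_per_segment for r in registered)
    width = n_seg * config.bins_per_segment
    profile = average_registered(
        [r[:, :width] for r in registered], config.bins_per_segment, channel_names=names
    )
    summary = {
        "n_samples": len(samples),
        "n_registered": len(registered),
        "n_failed": len(failures),
        "n_segments": profile.n_segments,
        "config": config.echo(),
    }
    if names and "signal" in names and "reporter" in names:
        a = profile.mean[names.index("signal")]
        b = profile.mean[names.index("reporter")]
        summary["pearson_r_signal_reporter"] = float(np.corrcoef(a, b)[0, 1])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        long_rows = []
        for si, reg in enumerate(profile.values):
            for ci, cname in enumerate(profile.channel_names):
                for bi, v in enumerate(reg[ci]):
                    long_rows.append(
                        (si, cname, bi // profile.bins_per_segment,
                         bi % profile.bins_per_segment, v)
                    )
        pd.DataFrame(
            long_rows, columns=["sample_id", "channel", "segment", "bin", "value"]
        ).to_csv(out / "profiles_long.csv", index=False)
        summ_rows = []
        for ci, cname in enumerate(profile.channel_names):
            for bi in range(profile.mean.shape[1]):
                summ_rows.append((cname, bi, profile.mean[ci, bi], profile.sem[ci, bi]))
        pd.DataFrame(
            summ_rows, columns=["channel", "bin_global", "mean", "sem"]
        ).to_csv(out / "profiles_summary.csv", index=False)
        _io.write_json(out / "profile_summary.json", summary)
    return ProfileResult(profile, failures, summary)


def run_model_scenario(
    name: str,
    n_boundaries: int = 14,
    threshold: float | None = None,
    resolution: float = 0.01,
    out_dir: str | None = None,
) -> dict:
    """Run one survival-model scenario and summarize its death bands."""
    kwargs = {} if threshold is None else {"threshold": threshold}
    land = simulate_scenario(name, n_boundaries=n_boundaries, resolution=resolution, **kwargs)
    summary = {
        "scenario": name,
        "n_boundaries": n_boundaries,
        "threshold": land.threshold,
        "band_count": count_bands(land),
        "bands": land.bands,
        "subthreshold_fraction": float(land.hid_mask.mean()),
        "subthreshold_area_segments": subthreshold_area(land),
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(
            {"x": land.grid_x, "S": land.S, "hid_mask": land.hid_mask}
        ).to_csv(out / f"landscape_{name}.csv", index=False)
        _io.write_json(out / f"landscape_{name}.json", summary)
    return summary
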