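"""Synthetic segmented-embryo images and profile traces with known ground truth.

The generator emulates the statistical structure of a ventral-view projection
of the embryonic epidermis: a landmark channel carrying the periodic
Engrailed-like boundary stripes, an event channel carrying punctate apoptotic
figures (cleaved-caspase positives), and a continuous signaling channel whose
smooth peaks sit at segment boundaries.  Every rendered object is echoed in a
:class:`GroundTruth` record so that downstream segmentation, mapping and
registration can be validated against known truth.

Conventions: the x axis (image columns) is the anterior->posterior axis with
anterior at low x; the y axis (rows) is dorsal->ventral, with the ventral
midline running horizontally through the image center.  Pixel coordinates are
0-based ``(row=y, col=x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from skimage.draw import disk as _disk

__all__ = [
    "SyntheticEmbryoSpec",
    "EventTruth",
    "GroundTruth",
    "ProfileSample",
    "generate_embryo_image",
    "generate_profile_samples",
]

#: guard band (px) kept free of event centers around the midline-band edge so
#: that centroid rounding can never flip an event's midline classification
_MIDLINE_GUARD_PX = 0.75


def _default_boundaries(n: int, spacing: float = 60.0, margin: float = 60.0) -> list[float]:
    return [margin + i * spacing for i in range(n)]


@dataclass
class SyntheticEmbryoSpec:
    """Parameters of one synthetic embryo.

    Defaults describe the study conditions the pipeline is built for: 14
    boundary stripes (the full complement of trunk Engrailed stripes) spaced
    60 px apart, punctate events whose intra-segment relative A/P position
    follows a mid-segment-enriched beta(2, 2) law, a 20% ventral-midline band,
    and additive Gaussian noise at 10% of the stripe intensity.
    """

    image_height_px: int = 400
    image_width_px: int = 900
    n_segments: int = 14  # number of boundary stripes
    boundary_x_px: Sequence[float] | None = None
    stripe_width_px: float = 6.0
    stripe_intensity: float = 200.0
    event_count: int = 200
    event_position_dist: tuple = ("beta", 2.0, 2.0)
    event_radius_px: float = 3.0
    midline_fraction: float = 0.20
    noise_sd: float = 20.0
    profile_period_px: float = 60.0
    profile_peak_amplitude: float = 100.0
    profile_baseline: float = 150.0
    seed: int = 0
    # optional sinusoidal stripe curvature so distance mapping is genuinely 2D
    stripe_wiggle_amplitude_px: float = 0.0
    stripe_wiggle_period_px: float = 200.0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be positive")
        if self.boundary_x_px is None:
            self.boundary_x_px = _default_boundaries(self.n_segments)
        self.boundary_x_px = [float(b) for b in self.boundary_x_px]
        if len(self.boundary_x_px) != self.n_segments:
            raise ValueError("boundary_x_px length must equal n_segments")
        diffs = np.diff(self.boundary_x_px)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("boundary_x_px must be strictly increasing")
        if len(diffs) and not np.all(diffs > self.stripe_width_px):
            raise ValueError("boundary spacing must exceed stripe_width_px")
        if self.stripe_width_px <= 0 or self.event_radius_px <= 0:
            raise ValueError("stripe_width_px and event_radius_px must be positive")
        if self.event_count < 0:
            raise ValueError("event_count must be non-negative")
        if not 0.0 <= self.midline_fraction <= 1.0:
            raise ValueError("midline_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.profile_period_px <= 0:
            raise ValueError("profile_period_px must be positive")
        dist = tuple(self.event_position_dist)
        if dist[0] not in ("uniform", "beta"):
            raise ValueError(f"unsupported event_position_dist family {dist[0]!r}")
        if dist[0] == "beta" and (len(dist) != 3 or dist[1] <= 0 or dist[2] <= 0):
            raise ValueError("beta distribution requires positive (alpha, beta)")
        self.event_position_dist = dist

    def to_dict(self) -> dict:
        d = asdict(self)
        d["event_position_dist"] = list(self.event_position_dist)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticEmbryoSpec":
        d = dict(d)
        if "event_position_dist" in d:
            d["event_position_dist"] = tuple(d["event_position_dist"])
        return cls(**d)


@dataclass
class EventTruth:
    x_px: float
    y_px: float
    true_rel_pos: float
    segment_index: int
    is_midline: bool


@dataclass
class GroundTruth:
    """What the generator actually rendered, for validation."""

    boundary_x_px: list[float]
    events: list[EventTruth]
    profile_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "boundary_x_px": self.boundary_x_px,
                "events": [asdict(e) for e in self.events],
                "profile_params": self.profile_params,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            boundary_x_px=d["boundary_x_px"],
            events=[EventTruth(**e) for e in d["events"]],
            profile_params=d.get("profile_params", {}),
        )


def _sample_rel(rng: np.random.Generator, dist: tuple) -> float:
    if dist[0] == "uniform":
        return float(rng.uniform(0.0, 1.0))
    return float(rng.beta(dist[1], dist[2]))


def _warped_phase(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Phase increasing by 2*pi between consecutive peak positions.

    Outside [peaks[0], peaks[-1]] the phase continues at the slope of the
    nearest interval, so the signal stays periodic at the edge spacing.
    """
    idx = np.arange(len(peaks), dtype=float)
    slope0 = 1.0 / (peaks[1] - peaks[0])
    slope1 = 1.0 / (peaks[-1] - peaks[-2])
    cyc = np.interp(x, peaks, idx)
    below = x < peaks[0]
    above = x > peaks[-1]
    cyc = np.where(below, (x - peaks[0]) * slope0, cyc)
    cyc = np.where(above, idx[-1] + (x - peaks[-1]) * slope1, cyc)
    return 2.0 * np.pi * cyc


def _stripe_centers(spec: SyntheticEmbryoSpec, y: np.ndarray) -> np.ndarray:
    """Per-row stripe center x for each boundary; shape (n_stripes, len(y))."""
    base = np.asarray(spec.boundary_x_px)[:, None]
    if spec.stripe_wiggle_amplitude_px == 0:
        return np.broadcast_to(base, (len(spec.boundary_x_px), len(y))).copy()
    wig = spec.stripe_wiggle_amplitude_px * np.sin(
        2.0 * np.pi * y[None, :] / spec.stripe_wiggle_period_px
    )
    return base + wig


def generate_embryo_image(
    spec: SyntheticEmbryoSpec,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 3-channel synthetic embryo.

    Channel 0: boundary (landmark) stripes; channel 1: punctate events;
    channel 2: continuous signaling channel peaking at boundaries.

    Returns ``(image, ground_truth)`` with image shaped ``(3, H, W)`` float32.
    Identical spec (including seed) gives bit-identical output.
    """
    if spec.event_count > 0 and spec.n_segments < 2:
        raise ValueError("event_count > 0 requires at least 2 boundary stripes")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height_px, spec.image_width_px
    img = np.zeros((3, H, W), dtype=np.float32)

    # --- channel 0: stripes (optionally wiggled per row) ---
    rows = np.arange(H)
    centers = _stripe_centers(spec, rows)
    half = spec.stripe_width_px / 2.0
    cols = np.arange(W)
    for s in range(centers.shape[0]):
        mask = np.abs(cols[None, :] - centers[s][:, None]) <= half
        img[0][mask] = spec.stripe_intensity

    # --- channel 1: events ---
    bounds = np.asarray(spec.boundary_x_px)
    events: list[EventTruth] = []
    r = spec.event_radius_px
    band_half = spec.midline_fraction * H / 2.0
    mid_y = H / 2.0
    for _ in range(spec.event_count):
        # y: uniform over the rows an event disk fits in, avoiding the guard
        # band around the midline-band edge
        while True:
            y = float(rng.uniform(r + 1.0, H - r - 1.0))
            if abs(abs(y - mid_y) - band_half) > _MIDLINE_GUARD_PX:
                break
        is_mid = abs(y - mid_y) < band_half
        if is_mid:
            x = float(rng.uniform(bounds[0], bounds[-1]))
            seg = int(np.clip(np.searchsorted(bounds, x, side="right") - 1, 0, len(bounds) - 2))
        else:
            seg = int(rng.integers(0, spec.n_segments - 1))
            rel = _sample_rel(rng, spec.event_position_dist)
            x = float(bounds[seg] + rel * (bounds[seg + 1] - bounds[seg]))
        a, b = bounds[seg], bounds[seg + 1]
        events.append(EventTruth(x, y, (x - a) / (b - a), seg, is_mid))
        rr, cc = _disk((y, x), r, shape=(H, W))
        img[1][rr, cc] = spec.stripe_intensity

    # --- channel 2: signaling profile, constant along y ---
    phase = _warped_phase(cols.astype(float), bounds) if len(bounds) >= 2 else np.zeros(W)
    sig = spec.profile_baseline + spec.profile_peak_amplitude * np.cos(phase)
    img[2] = sig[None, :]

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)

    gt = GroundTruth(
        boundary_x_px=list(bounds),
        events=events,
        profile_params={
            "period_px": spec.profile_period_px,
            "peak_amplitude": spec.profile_peak_amplitude,
            "baseline": spec.profile_baseline,
        },
    )
    return img, gt


@dataclass
class ProfileSample:
    """One simulated ROI trace set: landmark + signal (+ anticorrelated reporter)."""

    traces: dict[str, np.ndarray]
    true_peaks_px: np.ndarray  # jittered landmark peak positions of this sample

    @property
    def channels(self) -> list[str]:
        return list(self.traces)


def generate_profile_samples(
    spec: SyntheticEmbryoSpec,
    n_samples: int,
    jitter_sd_px: float = 2.0,
    include_reporter: bool = True,
) -> list[ProfileSample]:
    """Simulate per-sample 1D intensity traces over the A/P axis.

    Each sample has a ``landmark`` channel with Gaussian peaks at per-sample
    jittered boundary positions and a ``signal`` channel whose smooth peaks sit
    exactly at those jittered boundaries (segment-warped cosine).  When
    ``include_reporter`` is set, a ``reporter`` channel equal to
    ``2*baseline - signal`` is added — a perfectly anticorrelated readout, the
    arrangement used to test anticorrelation recovery after registration.

    Jitter emulates the inter-sample segment-width variation that registration
    is supposed to remove.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(spec.boundary_x_px) < 2:
        raise ValueError("profile samples require >= 2 boundary positions")
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.image_width_px, dtype=float)
    bounds = np.asarray(spec.boundary_x_px, dtype=float)
    min_gap = float(np.min(np.diff(bounds)))
    max_jit = 0.35 * min_gap
    sigma = max(spec.stripe_width_px, 1.0)

    samples: list[ProfileSample] = []
    for _ in range(n_samples):
        jit = np.clip(rng.normal(0.0, jitter_sd_px, size=len(bounds)), -max_jit, max_jit)
        peaks = bounds + jit
        landmark = np.zeros_like(x)
        for p in peaks:
            landmark += spec.stripe_intensity * np.exp(-0.5 * ((x - p) / sigma) ** 2)
        signal = spec.profile_baseline + spec.profile_peak_amplitude * np.cos(
            _warped_phase(x, peaks)
        )
        traces = {"landmark": landmark, "signal": signal}
        if include_reporter:
            traces["reporter"] = 2.0 * spec.profile_baseline - signal
        if spec.noise_sd > 0:
            for name in traces:
                traces[name] = np.clip(
                    traces[name] + rng.normal(0.0, spec.noise_sd, size=x.shape), 0.0, None
                )
        samples.append(ProfileSample(traces=traces, true_peaks_px=peaks))
    return samples
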