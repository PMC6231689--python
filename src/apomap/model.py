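"""Threshold-survival model of segmental EGFR signaling.

Each segment boundary is flanked by two prosurvival ligand sources (a
Vein-like domain just anterior and a Rhomboid/Spitz-like domain just
posterior of the boundary stripe).  Every source spreads with symmetric
exponential decay, and the signaling landscape is their sum:

    S(x) = sum_s  A_s * exp(-|x - p_s| / lambda_s)

Epidermal cells survive where S stays above a survival threshold; wherever S
drops below it, the proapoptotic gene *hid* is derepressed and a band of
apoptosis forms.  Scenario presets edit the wild-type source list the way
segmentation mutants do: a pair-rule mutant (*ftz*) deletes the sources of
every other segment, *ptc* adds ectopic mid-segment Rhomboid-like sources,
an *EGFR* null removes everything, and single/double ligand-class mutants
drop one or both ligand classes.

Positions are in segment-width units (boundary i at x = i).  The default
amplitude/decay/threshold calibration places the wild-type landscape safely
above threshold everywhere (no cell death in normally patterned segments)
and each single ligand class alone still above threshold (ligand redundancy),
while a segment stripped of both of its sources dips below threshold at
mid-segment — one apoptotic band per mispatterned segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LigandSource",
    "SignalingLandscape",
    "wildtype_sources",
    "default_grid",
    "build_landscape",
    "apply_threshold",
    "scenario",
    "count_bands",
    "subthreshold_area",
    "SCENARIOS",
    "DEFAULT_AMPLITUDE",
    "DEFAULT_DECAY_LENGTH",
    "DEFAULT_THRESHOLD",
    "DEFAULT_SOURCE_OFFSET",
]

DEFAULT_AMPLITUDE = 1.0
DEFAULT_DECAY_LENGTH = 0.15  # segment widths
DEFAULT_THRESHOLD = 0.06
DEFAULT_SOURCE_OFFSET = 0.1  # source distance from its boundary, segment widths

SCENARIOS = (
    "wildtype",
    "ftz",
    "ptc",
    "egfr_null",
    "vn_only",
    "rho_only",
    "vn_rho_double",
)


@dataclass(frozen=True)
class LigandSource:
    """One segmental prosurvival ligand source."""

    position: float  # A/P coordinate, segment-width units
    amplitude: float = DEFAULT_AMPLITUDE
    decay_length: float = DEFAULT_DECAY_LENGTH
    ligand_id: str = "rho"  # "vn" (Vein-like) or "rho" (Rhomboid/Spitz-like)
    dependency: str = ""  # patterning gene whose loss removes this source

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay_length <= 0:
            raise ValueError("amplitude and decay_length must be positive")


@dataclass
class SignalingLandscape:
    """1D signaling intensity with optional threshold-derived death bands."""

    grid_x: np.ndarray
    S: np.ndarray
    threshold: float | None = None
    hid_mask: np.ndarray | None = None  # True where S < threshold
    bands: list[tuple[float, float]] = field(default_factory=list)


def wildtype_sources(
    n_boundaries: int = 14,
    amplitude: float = DEFAULT_AMPLITUDE,
    decay_length: float = DEFAULT_DECAY_LENGTH,
    offset: float = DEFAULT_SOURCE_OFFSET,
    pair_rule_gene: str = "ftz",
) -> list[LigandSource]:
    """Wild-type source layout: a vn-like and a rho-like source per boundary.

    Boundary i sits at x = i; its Vein-like source at i - offset belongs to
    segment i-1 and its Rhomboid-like source at i + offset to segment i.
    Sources lying in alternate (even-indexed) segments are tagged with the
    pair-rule dependency, so deleting them removes the ligand supply of every
    other segment — seven of the thirteen interior segments for the standard
    fourteen-boundary trunk.
    """
    if n_boundaries < 2:
        raise ValueError("need at least 2 boundaries")
    sources = []
    for i in range(n_boundaries):
        for lig, pos in (("vn", i - offset), ("rho", i + offset)):
            seg = int(np.floor(pos))  # segment containing this source
            dep = pair_rule_gene if seg % 2 == 0 else ""
            sources.append(
                LigandSource(pos, amplitude, decay_length, ligand_id=lig, dependency=dep)
            )
    return sources


def default_grid(
    n_boundaries: int = 14, resolution: float = 0.01
) -> np.ndarray:
    """Evenly spaced A/P grid spanning the boundaries (segment-width units)."""
    return np.arange(0.0, n_boundaries - 1 + resolution / 2, resolution)


def build_landscape(
    sources: list[LigandSource], grid: np.ndarray
) -> SignalingLandscape:
    """Sum the exponential-decay contributions of all sources on the grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1D and strictly increasing")
    S = np.zeros_like(grid)
    for s in sources:
        S += s.amplitude * np.exp(-np.abs(grid - s.position) / s.decay_length)
    return SignalingLandscape(grid_x=grid, S=S)


def apply_threshold(
    landscape: SignalingLandscape, threshold: float = DEFAULT_THRESHOLD
) -> SignalingLandscape:
    """Mark sub-threshold (hid-derepressed) points and extract maximal bands."""
    mask = landscape.S < threshold
    bands: list[tuple[float, float]] = []
    x = landscape.grid_x
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    bands = [(float(x[a]), float(x[b])) for a, b in zip(starts, ends)]
    return SignalingLandscape(
        grid_x=x, S=landscape.S, threshold=float(threshold), hid_mask=mask, bands=bands
    )


def count_bands(landscape: SignalingLandscape) -> int:
    """Number of maximal contiguous sub-threshold runs."""
    if landscape.hid_mask is None:
        raise ValueError("apply_threshold first")
    return len(landscape.bands)


def subthreshold_area(landscape: SignalingLandscape) -> float:
    """Total A/P length (segment widths) where signaling is sub-threshold."""
    if landscape.hid_mask is None:
        raise ValueError("apply_threshold first")
    if not len(landscape.grid_x):
        return 0.0
    dx = float(np.median(np.diff(landscape.grid_x)))
    return float(landscape.hid_mask.sum() * dx)


def scenario(
    name: str,
    base: list[LigandSource] | None = None,
    ectopic_amplitude: float | None = None,
) -> list[LigandSource]:
    """Edit a wild-type source list the way a mutant genotype does.

    - ``wildtype``: unchanged.
    - ``ftz``: removes every source tagged with the pair-rule dependency
      (ligand peaks fail to appear in alternate segments).
    - ``ptc``: adds one ectopic mid-segment rho-like source per segment.
    - ``egfr_null``: no functional signaling — empty list.
    - ``vn_only`` / ``rho_only``: the other ligand class is lost.
    - ``vn_rho_double``: both ligand classes lost (equals egfr_null at the
      ligand level).
    """
    if base is None:
        base = wildtype_sources()
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if name == "wildtype":
        return list(base)
    if name == "ftz":
        return [s for s in base if not s.dependency]
    if name == "ptc":
        boundaries = sorted({round(s.position) for s in base})
        amp = ectopic_amplitude
        if amp is None:
            amp = base[0].amplitude if base else DEFAULT_AMPLITUDE
        decay = base[0].decay_length if base else DEFAULT_DECAY_LENGTH
        ectopic = [
            LigandSource(b + 0.5, amp, decay, ligand_id="rho", dependency="ptc_ectopic")
            for b in boundaries[:-1]
        ]
        return list(base) + ectopic
    if name == "egfr_null" or name == "vn_rho_double":
        return []
    if name == "vn_only":
        return [s for s in base if s.ligand_id == "vn"]
    if name == "rho_only":
        return [s for s in base if s.ligand_id == "rho"]
    raise AssertionError("unreachable")


def simulate_scenario(
    name: str,
    n_boundaries: int = 14,
    threshold: float = DEFAULT_THRESHOLD,
    resolution: float = 0.01,
    **wt_kwargs,
) -> SignalingLandscape:
    """Convenience: wild-type layout -> scenario edit -> landscape -> threshold."""
    base = wildtype_sources(n_boundaries=n_boundaries, **wt_kwargs)
    sources = scenario(name, base)
    land = build_landscape(sources, default_grid(n_boundaries, resolution))
    return apply_threshold(land, threshold)
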