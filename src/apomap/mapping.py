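"""Segment-relative mapping of point events and histogram tabulation.

Each event is assigned to the pair of boundary skeletons bracketing its x
coordinate, its Euclidean distances to the nearest pixel of the anterior and
posterior skeleton are measured with an exact k-d tree query (k = 1), and its
intra-segment position is expressed as a percentage of segment width:

    rel_pos_pct = 100 * d_anterior / (d_anterior + d_posterior)

For straight parallel boundaries this reduces to the exact linear coordinate;
for curved boundaries it remains well defined.  Events in a configurable band
around the ventral midline (default 20% of the D-V extent) are excluded from
tabulation, as are events anterior of the first or posterior of the last
boundary (unmappable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats

from .errors import MappingError
from .segmentation import BoundarySkeleton

__all__ = [
    "EventRecord",
    "ApoptosisHistogram",
    "TTestResult",
    "order_boundaries",
    "map_event",
    "map_events",
    "exclude_midline",
    "tabulate_histogram",
    "compare_mean_intensity",
]


@dataclass
class EventRecord:
    event_id: int
    x_px: float
    y_px: float
    d_anterior_px: float = np.nan
    d_posterior_px: float = np.nan
    rel_pos_pct: float = np.nan
    segment_index: int = -1
    excluded_midline: bool = False
    unmappable: bool = False

    @property
    def retained(self) -> bool:
        return not (self.unmappable or self.excluded_midline)


@dataclass
class ApoptosisHistogram:
    """Per-embryo binned event positions with cross-embryo mean and SD."""

    bin_edges_pct: np.ndarray
    per_embryo_counts: np.ndarray  # (n_embryos, n_bins) integer counts
    mean_frequency: np.ndarray
    sd: np.ndarray
    normalized: bool = True  # mean/sd over per-embryo fractions, not raw counts


class _OrderedBoundaries:
    """Boundary skeletons sorted along A/P, with lazy per-stripe k-d trees."""

    def __init__(self, skeleton: BoundarySkeleton):
        if len(skeleton) < 2:
            raise MappingError("cannot define a segment: fewer than 2 boundary stripes")
        self.stripes = skeleton.stripes
        self.median_x = skeleton.median_x
        if np.any(np.diff(self.median_x) < 1.0):
            raise MappingError("ambiguous boundary order: stripe median x closer than 1 px")
        self._trees: list[cKDTree | None] = [None] * len(self.stripes)

    def __len__(self) -> int:
        return len(self.stripes)

    def tree(self, i: int) -> cKDTree:
        if self._trees[i] is None:
            # pixels stored (row, col); query in (x, y) = (col, row)
            self._trees[i] = cKDTree(self.stripes[i][:, ::-1].astype(float))
        return self._trees[i]


def order_boundaries(skeleton: BoundarySkeleton) -> _OrderedBoundaries:
    """Validate and order boundary stripes along the A/P axis."""
    return _OrderedBoundaries(skeleton)


def map_event(
    event_id: int,
    x: float,
    y: float,
    boundaries: _OrderedBoundaries,
) -> EventRecord:
    """Map one event to its flanking boundary pair.

    The flanking pair is the consecutive stripe pair whose median x brackets
    the event's x; distances are exact minima over every pixel of those two
    skeletons.  Events outside [first, last] median x are flagged unmappable.
    """
    rec = EventRecord(event_id=event_id, x_px=float(x), y_px=float(y))
    med = boundaries.median_x
    i = int(np.searchsorted(med, x, side="right")) - 1
    if i < 0 or i >= len(med) - 1:
        rec.unmappable = True
        return rec
    d_ant, _ = boundaries.tree(i).query([x, y], k=1)
    d_post, _ = boundaries.tree(i + 1).query([x, y], k=1)
    rec.segment_index = i
    rec.d_anterior_px = float(d_ant)
    rec.d_posterior_px = float(d_post)
    denom = rec.d_anterior_px + rec.d_posterior_px
    rec.rel_pos_pct = 100.0 * rec.d_anterior_px / denom if denom > 0 else 0.0
    return rec


def map_events(
    points: Sequence[tuple[float, float]],
    boundaries: _OrderedBoundaries,
) -> list[EventRecord]:
    return [map_event(i, x, y, boundaries) for i, (x, y) in enumerate(points)]


def exclude_midline(
    records: list[EventRecord],
    dv_min_px: float,
    dv_max_px: float,
    fraction: float = 0.20,
) -> list[EventRecord]:
    """Flag events in the ventral-midline band; return the retained records.

    The band is centered on the middle of ``[dv_min_px, dv_max_px]`` and spans
    ``fraction`` of that D-V extent (default 20%), excluding apoptotic figures
    of the developing nervous system from epidermal tabulation.  Flags are set
    in place on every record; the returned list holds only records outside the
    band (unmappable records keep their flag and are returned too — they are
    dropped later, at tabulation).
    """
    if not dv_min_px < dv_max_px:
        raise ValueError("dv_min_px must be < dv_max_px")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    center = 0.5 * (dv_min_px + dv_max_px)
    half = 0.5 * fraction * (dv_max_px - dv_min_px)
    kept = []
    for r in records:
        r.excluded_midline = fraction > 0 and abs(r.y_px - center) < half
        if not r.excluded_midline:
            kept.append(r)
    return kept


def tabulate_histogram(
    records_per_embryo: list[list[EventRecord]],
    n_bins: int = 10,
    normalize: bool = True,
) -> ApoptosisHistogram:
    """Bin retained event positions on [0, 100] per embryo; average across.

    Bins are half-open ``[edge_i, edge_{i+1})`` with the last bin closed.  With
    ``normalize`` (default), each embryo's counts are converted to fractions of
    its retained events before the cross-embryo mean and SD — embryos with
    different event loads then weigh equally, matching the frequency reading
    of the histogram.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not records_per_embryo:
        raise MappingError("zero embryos: nothing to tabulate")
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts = np.zeros((len(records_per_embryo), n_bins), dtype=int)
    for e, recs in enumerate(records_per_embryo):
        vals = [r.rel_pos_pct for r in recs if r.retained and np.isfinite(r.rel_pos_pct)]
        counts[e], _ = np.histogram(vals, bins=edges)
    if normalize:
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, counts / totals, 0.0)
    else:
        freq = counts.astype(float)
    ddof = 1 if len(records_per_embryo) > 1 else 0
    return ApoptosisHistogram(
        bin_edges_pct=edges,
        per_embryo_counts=counts,
        mean_frequency=freq.mean(axis=0),
        sd=freq.std(axis=0, ddof=ddof),
        normalized=normalize,
    )


@dataclass
class TTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float


def compare_mean_intensity(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TTestResult:
    """Unpaired two-sample Student t test (equal variance, two-sided).

    Returns the group means and standard deviations (the quantities plotted in
    group-comparison bar charts) together with the t statistic and p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        p=float(p),
    )
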