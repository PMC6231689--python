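"""Stripe and event segmentation: threshold, label, skeletonize, centroid.

Turns the raw landmark (stripe) channel into single-pixel boundary skeletons
and the event channel into point events.  The interactive pixel-classification
step used in many imaging workflows is replaced by a deterministic global
threshold + connected components, which is sufficient for projected epidermal
images with bright periodic stripes; the threshold is an explicit parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _label, regionprops
from skimage.morphology import thin as _thin

from .errors import NoLandmarksError

logger = logging.getLogger(__name__)

__all__ = [
    "BoundarySkeleton",
    "EventSet",
    "segment_stripes",
    "skeletonize_stripes",
    "detect_events",
    "prune_skeleton",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class BoundarySkeleton:
    """Ordered single-pixel-wide stripe centerlines (segmental landmarks).

    ``stripes[i]`` is an ``(N_i, 2)`` integer array of ``(row, col)`` pixels of
    the i-th skeleton curve; stripes are stored sorted by median column
    (anterior -> posterior), so the list index is the A/P order index.
    """

    stripes: list[np.ndarray]
    source_image_id: str = ""

    def __post_init__(self) -> None:
        order = np.argsort([float(np.median(s[:, 1])) for s in self.stripes], kind="stable")
        self.stripes = [np.asarray(self.stripes[i], dtype=int) for i in order]

    @property
    def median_x(self) -> np.ndarray:
        return np.array([float(np.median(s[:, 1])) for s in self.stripes])

    def __len__(self) -> int:
        return len(self.stripes)


@dataclass
class EventSet:
    """Detected point events (one centroid per retained component)."""

    events: list[tuple[int, int]]  # (x, y) pixel centroids
    areas_px: list[int] = field(default_factory=list)
    source_image_id: str = ""

    def __len__(self) -> int:
        return len(self.events)


def segment_stripes(
    stripe_channel: np.ndarray,
    intensity_threshold: float,
    min_area_px: int = 50,
) -> np.ndarray:
    """Threshold + 8-connected components, relabelled in A/P (median-x) order.

    Returns a label image where label ``i`` (1-based) is the i-th stripe from
    the anterior.  Raises :class:`NoLandmarksError` when nothing survives the
    area filter — event mapping is undefined without boundary landmarks.
    """
    chan = np.asarray(stripe_channel)
    if chan.ndim != 2:
        raise ValueError("stripe channel must be 2D")
    if not np.all(np.isfinite(chan)):
        raise ValueError("stripe channel must be finite-valued")
    lab = _label(chan > intensity_threshold, connectivity=2)
    keep = []
    for p in regionprops(lab):
        if p.area >= min_area_px:
            keep.append((float(np.median(p.coords[:, 1])), p.label))
    if not keep:
        raise NoLandmarksError("no landmarks found")
    keep.sort()
    out = np.zeros_like(lab)
    for new, (_, old) in enumerate(keep, start=1):
        out[lab == old] = new
    return out


def _degree(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndi.convolve(sk.astype(int), kernel, mode="constant") * sk


def _bfs_farthest(pixels: set, start: tuple) -> tuple[tuple, dict]:
    """BFS over 8-connected skeleton pixels; returns the farthest pixel and
    the predecessor map of the search tree."""
    from collections import deque

    prev = {start: None}
    q = deque([start])
    last = start
    while q:
        cur = q.popleft()
        last = cur
        for dr, dc in _NEIGHBORS:
            nb = (cur[0] + dr, cur[1] + dc)
            if nb in pixels and nb not in prev:
                prev[nb] = cur
                q.append(nb)
    return last, prev


def prune_skeleton(sk: np.ndarray, prune_len: int = 10) -> np.ndarray:
    """Reduce a thinned component to a single branch-free curve.

    When junction pixels (three or more skeletal neighbors) are present, the
    skeleton is reduced to its longest geodesic path — the shortest 8-connected
    path between the two mutually farthest pixels of its largest connected
    piece.  A shortest path can contain no chords, so every interior pixel of
    the result has exactly two neighbors.  Side branches are expected to be
    short spurs; removal of any piece longer than ``prune_len`` is logged, as
    it may indicate a genuinely forked structure.
    """
    sk = sk.astype(bool)
    if not np.any(_degree(sk) >= 3):
        return sk.copy()
    pixels = set(map(tuple, np.argwhere(sk)))
    # largest connected piece
    comps = []
    remaining = set(pixels)
    while remaining:
        seed = next(iter(remaining))
        _, prev = _bfs_farthest(remaining, seed)
        comp = set(prev)
        comps.append(comp)
        remaining -= comp
    comp = max(comps, key=len)
    u, _ = _bfs_farthest(comp, next(iter(comp)))
    v, prev = _bfs_farthest(comp, u)
    path = []
    cur = v
    while cur is not None:
        path.append(cur)
        cur = prev[cur]
    removed = len(pixels) - len(path)
    if removed > prune_len:
        logger.warning(
            "pruning removed %d pixels (> prune_len=%d); component may be forked",
            removed, prune_len,
        )
    out = np.zeros_like(sk)
    for p in path:
        out[p] = True
    return out


def skeletonize_stripes(
    labeled: np.ndarray,
    prune_len: int = 10,
    source_image_id: str = "",
) -> BoundarySkeleton:
    """Reduce each labeled stripe to a one-pixel-wide pruned medial curve.

    Components that collapse to fewer than 2 pixels (degenerate blobs) are
    dropped with a warning.
    """
    labels = [l for l in np.unique(labeled) if l != 0]
    if not labels:
        raise NoLandmarksError("no labeled components to skeletonize")
    stripes = []
    for l in labels:
        sk = prune_skeleton(_thin(labeled == l), prune_len=prune_len)
        coords = np.argwhere(sk)
        if len(coords) < 2:
            logger.warning("dropping degenerate stripe label %d (skeleton < 2 px)", l)
            continue
        stripes.append(coords)
    if not stripes:
        raise NoLandmarksError("all stripes degenerate after skeletonization")
    return BoundarySkeleton(stripes=stripes, source_image_id=source_image_id)


def detect_events(
    event_channel: np.ndarray,
    intensity_threshold: float,
    min_area_px: int = 4,
    max_area_px: int | None = None,
    source_image_id: str = "",
) -> EventSet:
    """Reduce punctate event blobs to centroid points.

    Components with area outside ``[min_area_px, max_area_px]`` are discarded
    (small = noise specks; large = fused doublets when a cap is given).  An
    empty result is valid.
    """
    chan = np.asarray(event_channel)
    if chan.ndim != 2:
        raise ValueError("event channel must be 2D")
    lab = _label(chan > intensity_threshold, connectivity=2)
    events, areas = [], []
    for p in regionprops(lab):
        if p.area < min_area_px:
            continue
        if max_area_px is not None and p.area > max_area_px:
            continue
        cy, cx = p.centroid
        events.append((int(round(cx)), int(round(cy))))
        areas.append(int(p.area))
    return EventSet(events=events, areas_px=areas, source_image_id=source_image_id)
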