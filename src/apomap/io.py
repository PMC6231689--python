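"""File I/O: multi-channel TIFF, ground-truth JSON sidecars, CSV tables, YAML specs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .mapping import ApoptosisHistogram, EventRecord
from .segmentation import BoundarySkeleton, EventSet
from .synthetic import GroundTruth, SyntheticEmbryoSpec

__all__ = [
    "write_embryo_tiff",
    "read_image",
    "write_ground_truth",
    "read_ground_truth",
    "load_spec_yaml",
    "skeleton_to_frame",
    "events_to_frame",
    "records_to_frame",
    "histogram_to_frame",
]


def write_embryo_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a (C, H, W) image as a multi-page TIFF, one page per channel."""
    tifffile.imwrite(
        str(path),
        np.asarray(image, dtype=np.float32),
        photometric="minisblack",
        planarconfig="separate",
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF as (C, H, W); a single-page file becomes one channel."""
    img = tifffile.imread(str(path))
    if img.ndim == 2:
        img = img[None]
    return np.asarray(img)


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(gt.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def load_spec_yaml(path: str | Path) -> SyntheticEmbryoSpec:
    with open(path) as fh:
        return SyntheticEmbryoSpec.from_dict(yaml.safe_load(fh) or {})


def skeleton_to_frame(skeleton: BoundarySkeleton) -> pd.DataFrame:
    rows = []
    for i, coords in enumerate(skeleton.stripes):
        for r, c in coords:
            rows.append((i, int(c), int(r)))
    return pd.DataFrame(rows, columns=["stripe_id", "x", "y"])


def events_to_frame(events: EventSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i, x, y, a)
            for i, ((x, y), a) in enumerate(zip(events.events, events.areas_px))
        ],
        columns=["event_id", "x", "y", "area"],
    )


def records_to_frame(records: list[EventRecord], embryo_id: int | str = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": embryo_id,
            "event_id": [r.event_id for r in records],
            "x": [r.x_px for r in records],
            "y": [r.y_px for r in records],
            "d_ant": [r.d_anterior_px for r in records],
            "d_post": [r.d_posterior_px for r in records],
            "rel_pos_pct": [r.rel_pos_pct for r in records],
            "segment_index": [r.segment_index for r in records],
            "excluded_midline": [r.excluded_midline for r in records],
            "unmappable": [r.unmappable for r in records],
        }
    )


def histogram_to_frame(hist: ApoptosisHistogram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_left_pct": hist.bin_edges_pct[:-1],
            "bin_right_pct": hist.bin_edges_pct[1:],
            "mean_frequency": hist.mean_frequency,
            "sd": hist.sd,
        }
    )


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
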