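"""ROI intensity profiles, landmark-peak registration, cross-sample averaging.

A rectangular ROI (fixed physical height, default 75 um) spanning several
contiguous segments is collapsed to per-channel column means along the A/P
axis.  Each sample's profile is then registered to the peaks of its landmark
(Engrailed) channel: every inter-peak interval is linearly resampled onto a
fixed number of evenly spaced bins (default 50 per segment), normalizing away
the segment-width variation between samples.  Registered samples are averaged
per bin with the standard error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import RegistrationError

__all__ = [
    "RawProfile",
    "RegisteredProfile",
    "extract_profile",
    "detect_landmark_peaks",
    "register_profiles",
    "average_registered",
]

DEFAULT_ROI_HEIGHT_UM = 75.0
DEFAULT_BINS_PER_SEGMENT = 50


@dataclass
class RawProfile:
    """Per-channel mean-intensity traces along the A/P axis of one ROI."""

    traces: np.ndarray  # (n_channels, width_px)
    roi: tuple[int, int, int, int]  # (x0, y0, width_px, height_px)
    pixel_size_um: float = 1.0
    channel_names: tuple[str, ...] = ()

    @property
    def height_um(self) -> float:
        return self.roi[3] * self.pixel_size_um


@dataclass
class RegisteredProfile:
    """Landmark-registered samples with per-bin mean and SEM.

    ``values`` is (n_samples, n_channels, n_segments*bins_per_segment);
    ``mean`` and ``sem`` are (n_channels, n_segments*bins_per_segment).
    """

    n_segments: int
    bins_per_segment: int
    values: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    channel_names: tuple[str, ...] = ()


def extract_profile(
    image: np.ndarray,
    roi: tuple[int, int, int, int],
    pixel_size_um: float = 1.0,
    channel_names: tuple[str, ...] = (),
) -> RawProfile:
    """Column-mean traces over the ROI rows, ordered anterior -> posterior.

    ``image`` is (n_channels, H, W); ``roi`` is (x0, y0, width, height) in
    pixels.  Raises if the ROI leaves the image.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None]
    x0, y0, w, h = roi
    _, H, W = img.shape
    if x0 < 0 or y0 < 0 or w < 1 or h < 1 or x0 + w > W or y0 + h > H:
        raise ValueError(f"ROI {roi} outside image bounds {(H, W)}")
    traces = img[:, y0 : y0 + h, x0 : x0 + w].mean(axis=1)
    return RawProfile(
        traces=traces, roi=(x0, y0, w, h), pixel_size_um=pixel_size_um,
        channel_names=tuple(channel_names),
    )


def detect_landmark_peaks(
    trace: np.ndarray,
    min_separation_px: float,
    min_prominence: float,
    smooth_window_px: int = 5,
) -> np.ndarray:
    """Locate landmark (boundary) peaks: smoothed prominence-based maxima.

    The trace is lightly smoothed with a moving average before peak finding so
    that pixel noise does not split peaks.  Fewer than two peaks means the
    profile cannot be registered.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("trace must be 1D with length >= 3")
    if smooth_window_px > 1:
        k = np.ones(smooth_window_px) / smooth_window_px
        y = np.convolve(y, k, mode="same")
    peaks, _ = find_peaks(y, distance=max(1, int(round(min_separation_px))),
                          prominence=min_prominence)
    if len(peaks) < 2:
        raise RegistrationError("cannot register: fewer than 2 landmark peaks")
    return peaks.astype(float)


def register_profiles(
    raw: RawProfile | np.ndarray,
    peaks: np.ndarray,
    bins_per_segment: int = DEFAULT_BINS_PER_SEGMENT,
) -> np.ndarray:
    """Resample each inter-peak interval onto evenly spaced bins.

    Every segment (interval between consecutive landmark peaks) is sampled at
    ``bins_per_segment`` evenly spaced positions by linear interpolation; a
    segment's left peak falls on its bin 0 and its right peak on bin 0 of the
    next segment.  Trace regions outside [first peak, last peak] are
    discarded.  Returns (n_channels, n_segments*bins_per_segment).
    """
    traces = raw.traces if isinstance(raw, RawProfile) else np.asarray(raw, dtype=float)
    if traces.ndim == 1:
        traces = traces[None]
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 2:
        raise RegistrationError("cannot register: fewer than 2 peaks")
    if np.any(np.diff(peaks) <= 0):
        raise RegistrationError("cannot register: coincident or unordered peaks")
    if bins_per_segment < 2:
        raise ValueError("bins_per_segment must be >= 2")
    frac = np.arange(bins_per_segment) / bins_per_segment
    xs = np.concatenate(
        [p0 + frac * (p1 - p0) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    )
    grid = np.arange(traces.shape[1], dtype=float)
    return np.vstack([np.interp(xs, grid, t) for t in traces])


def average_registered(
    samples: list[np.ndarray],
    bins_per_segment: int = DEFAULT_BINS_PER_SEGMENT,
    channel_names: tuple[str, ...] = (),
) -> RegisteredProfile:
    """Per-bin mean and SEM across registered samples.

    Requires at least two samples of identical shape (SEM is undefined for a
    single sample).
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 registered samples (SEM undefined otherwise)")
    arrs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in samples]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("registered samples must share a common shape")
    if shape[1] % bins_per_segment:
        raise ValueError("sample length is not a multiple of bins_per_segment")
    values = np.stack(arrs)
    mean = values.mean(axis=0)
    sem = values.std(axis=0, ddof=1) / np.sqrt(len(arrs))
    return RegisteredProfile(
        n_segments=shape[1] // bins_per_segment,
        bins_per_segment=bins_per_segment,
        values=values,
        mean=mean,
        sem=sem,
        channel_names=tuple(channel_names),
    )
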