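"""Blink detection, pupil cleaning, and microsaccade detection.

Blinks are flagged from the pupil trace by multiple independent criteria:
missing samples, rapid sample-to-sample fluctuations, and outlier values
relative to the session median. Microsaccades are detected from gaze
velocity with median-based (robust) per-axis thresholds, following the
standard moving-window velocity estimator used throughout the fixational
eye-movement literature. Both detectors return a binary timecourse with
exactly one value per recording sample (0 = event absent, 1 = present).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from ._utils import (
    intervals_from_mask,
    mask_from_intervals,
    merge_close_intervals,
    moving_average,
)
from .recording import RawRecording


@dataclass
class BlinkDetectionParams:
    velocity_threshold: float = 10.0  # recorder units per ms
    outlier_mad_mult: float = 5.0  # multiplier on the median absolute deviation
    pad_ms: float = 50.0
    merge_gap_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in ("velocity_threshold", "outlier_mad_mult", "pad_ms", "merge_gap_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MicrosaccadeParams:
    velocity_window: int = 5  # samples in the moving-average velocity estimate
    lam: float = 6.0  # multiplier on the median-based velocity SD
    min_duration_ms: float = 6.0
    max_amplitude_deg: float = 1.0  # larger events are saccades, not microsaccades
    min_separation_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.velocity_window < 3 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be odd and >= 3")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.min_duration_ms < 1:
            raise ValueError("min_duration_ms must be >= 1")


@dataclass
class BinaryEventTimecourse:
    """0/1 per recording sample, 1 exactly on the union of ``intervals``."""

    values: np.ndarray
    kind: str
    intervals: list[tuple[int, int]]
    t0_ms: int = 0

    @classmethod
    def from_intervals(
        cls, kind: str, intervals: list[tuple[int, int]], n: int, t0_ms: int = 0
    ) -> "BinaryEventTimecourse":
        mask = mask_from_intervals(intervals, n, t0_ms)
        return cls(values=mask.astype(np.uint8), kind=kind, intervals=intervals, t0_ms=t0_ms)

    @classmethod
    def from_mask(
        cls, kind: str, mask: np.ndarray, t0_ms: int = 0
    ) -> "BinaryEventTimecourse":
        return cls(
            values=np.asarray(mask, dtype=bool).astype(np.uint8),
            kind=kind,
            intervals=intervals_from_mask(mask, t0_ms),
            t0_ms=t0_ms,
        )

    @property
    def mask(self) -> np.ndarray:
        return self.values.astype(bool)

    @property
    def n_events(self) -> int:
        return len(self.intervals)


def detect_blinks(
    recording: RawRecording, params: BlinkDetectionParams | None = None
) -> BinaryEventTimecourse:
    """Flag blink intervals in the pupil trace.

    A sample falls inside a blink interval iff it is missing, its absolute
    sample-to-sample pupil change exceeds ``velocity_threshold``, or its
    value deviates from the session median by more than
    ``outlier_mad_mult`` x MAD. Flagged samples are padded by ``pad_ms`` on
    each side and intervals separated by less than ``merge_gap_ms`` merge.
    """
    params = params or BlinkDetectionParams()
    pupil = recording.pupil
    valid = recording.valid
    if not valid.any():
        raise ValueError("no valid pupil samples")
    flagged = ~valid
    dv = np.abs(np.diff(pupil))
    fast = np.zeros_like(flagged)
    with np.errstate(invalid="ignore"):
        hit = dv > params.velocity_threshold
    hit = np.where(np.isnan(dv), False, hit)
    fast[1:] |= hit
    fast[:-1] |= hit  # a fast transition implicates both samples
    med = np.nanmedian(pupil)
    mad = np.nanmedian(np.abs(pupil - med))
    with np.errstate(invalid="ignore"):
        outlier = np.abs(pupil - med) > params.outlier_mad_mult * max(mad, 1e-12)
    outlier = np.where(np.isnan(pupil), False, outlier)
    flagged = flagged | fast | outlier
    pad = int(round(params.pad_ms))
    if pad > 0 and flagged.any():
        flagged = binary_dilation(flagged, structure=np.ones(2 * pad + 1, dtype=bool))
    intervals = merge_close_intervals(
        intervals_from_mask(flagged, recording.t0_ms), params.merge_gap_ms
    )
    return BinaryEventTimecourse.from_intervals(
        "blink", intervals, recording.n_samples, recording.t0_ms
    )


def clean_pupil(
    recording: RawRecording,
    blinks: BinaryEventTimecourse,
    smooth_ms: float = 50.0,
) -> np.ndarray:
    """Interpolate blink intervals and smooth the pupil trace.

    Blink samples are replaced by linear interpolation between the nearest
    valid bracketing samples (leading/trailing gaps take the nearest valid
    value); the result is smoothed by a centered moving average of width
    ``smooth_ms``. Output has no missing values and the input sample count.
    """
    if blinks.values.size != recording.n_samples:
        raise ValueError("blink timecourse not aligned to recording")
    pupil = recording.pupil.copy()
    pupil[blinks.mask] = np.nan
    good = ~np.isnan(pupil)
    if not good.any():
        raise ValueError("no valid pupil samples")
    idx = np.arange(pupil.size)
    pupil = np.interp(idx, idx[good], pupil[good])
    return moving_average(pupil, int(round(smooth_ms)))


def _window_velocity(x: np.ndarray, window: int, dt_s: float) -> np.ndarray:
    """Moving-window velocity: centered difference averaged over the window.

    For window ``2m + 1``, v[t] = sum_{k=1..m} (x[t+k] - x[t-k]) scaled to
    units of x per second; the m edge samples on each side are NaN
    (undetectable).
    """
    m = (window - 1) // 2
    v = np.full(x.size, np.nan)
    if x.size < window:
        return v
    acc = np.zeros(x.size - 2 * m)
    for k in range(1, m + 1):
        acc += x[m + k : x.size - m + k] - x[m - k : x.size - m - k]
    denom = 2.0 * sum(range(1, m + 1)) * dt_s
    v[m : x.size - m] = acc / denom
    return v


def _median_sd(v: np.ndarray) -> float:
    """Median-based estimate of the velocity SD, robust to saccadic outliers."""
    v = v[np.isfinite(v)]
    var = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(var, 1e-12)))


def detect_microsaccades(
    recording: RawRecording,
    params: MicrosaccadeParams | None = None,
    exclude: BinaryEventTimecourse | None = None,
) -> BinaryEventTimecourse:
    """Detect microsaccades from gaze velocity with median-based thresholds.

    Horizontal and vertical velocities from the moving-window estimator are
    normalized by per-axis thresholds lambda x median-based SD; a candidate
    event is a run of samples with elliptic criterion
    (vx/ex)^2 + (vy/ey)^2 > 1 lasting at least ``min_duration_ms``.
    Candidates overlapping ``exclude`` (blink) intervals or whose gaze
    displacement exceeds ``max_amplitude_deg`` are discarded; surviving
    events closer than ``min_separation_ms`` merge.
    """
    params = params or MicrosaccadeParams()
    n = recording.n_samples
    if n < params.velocity_window:
        raise ValueError("recording shorter than velocity_window")
    dt_s = 1e-3
    vx = _window_velocity(recording.gaze_x, params.velocity_window, dt_s)
    vy = _window_velocity(recording.gaze_y, params.velocity_window, dt_s)
    ex = params.lam * _median_sd(vx)
    ey = params.lam * _median_sd(vy)
    with np.errstate(invalid="ignore"):
        crit = (vx / ex) ** 2 + (vy / ey) ** 2 > 1.0
    crit = np.where(np.isnan(vx) | np.isnan(vy), False, crit)
    exclude_mask = exclude.mask if exclude is not None else np.zeros(n, dtype=bool)
    candidates = []
    for s, e in intervals_from_mask(crit):
        if e - s < params.min_duration_ms:
            continue
        if exclude_mask[s:e].any():
            continue
        a = max(s - 1, 0)
        amp = float(
            np.hypot(
                recording.gaze_x[e - 1] - recording.gaze_x[a],
                recording.gaze_y[e - 1] - recording.gaze_y[a],
            )
        )
        if amp > params.max_amplitude_deg:
            continue
        candidates.append((s, e))
    merged = merge_close_intervals(candidates, params.min_separation_ms)
    merged = [(s + recording.t0_ms, e + recording.t0_ms) for s, e in merged]
    return BinaryEventTimecourse.from_intervals(
        "microsaccade", merged, n, recording.t0_ms
    )
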