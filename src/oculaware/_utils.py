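"""Small shared numerics: moving averages, run-length interval helpers, seeding."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

# Named substreams of the master seed. Order is part of the on-disk contract:
# inserting a name must append, never reorder, or seeded outputs change.
_SUBSTREAMS = (
    "trials",
    "pupil_noise",
    "blinks",
    "microsaccades",
    "gaze",
    "responses",
    "blanks",
    "brightness",
    "field_potentials",
    "folds",
    "permutations",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named component of the master seed."""
    try:
        idx = _SUBSTREAMS.index(name)
    except ValueError:
        raise KeyError(f"unknown substream {name!r}") from None
    child = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))[idx]
    return np.random.default_rng(child)


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average of odd-rounded ``width`` samples, edge-replicated."""
    width = max(int(width), 1)
    if width % 2 == 0:
        width += 1
    if width == 1:
        return np.asarray(x, dtype=float).copy()
    return uniform_filter1d(np.asarray(x, dtype=float), size=width, mode="nearest")


def intervals_from_mask(mask: np.ndarray, t0_ms: int = 0) -> list[tuple[int, int]]:
    """Half-open [start_ms, end_ms) runs of True in a 1-ms-grid boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    ends = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(int(s) + t0_ms, int(e) + t0_ms) for s, e in zip(starts, ends)]


def mask_from_intervals(
    intervals: list[tuple[int, int]], n: int, t0_ms: int = 0
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        lo = max(int(s) - t0_ms, 0)
        hi = min(int(e) - t0_ms, n)
        if hi > lo:
            mask[lo:hi] = True
    return mask


def merge_close_intervals(
    intervals: list[tuple[int, int]], gap_ms: float
) -> list[tuple[int, int]]:
    """Merge intervals whose gap is strictly below ``gap_ms``."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] < gap_ms:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
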