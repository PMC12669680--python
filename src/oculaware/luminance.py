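"""Pupillary light response to real and illusory brightness.

For each participant, the minimum of the mean baselined pupil trace in the
first 1500 ms after stimulus onset is taken per stimulus (white, glare,
nonglare). A least-squares line is fit through the three minima against
the stimulus rank (white = 1, glare = 2, nonglare = 3), so the expected
luminance-graded constriction — deepest for white, weakest for nonglare —
appears as a positive slope. The group test is a Wilcoxon signed-rank of
the per-participant slopes against 0 (one-sided by default), with exact
zeros retained via Pratt handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import holm_adjust

STIMULUS_ORDER = ("white", "glare", "nonglare")
_RANKS = np.array([1.0, 2.0, 3.0])


@dataclass
class SlopeResult:
    minima: np.ndarray  # (min_white, min_glare, min_nonglare), recorder units
    slope: float  # recorder units per stimulus rank
    intercept: float


def min_constriction(
    mean_trace: np.ndarray, offsets_ms: np.ndarray, window_ms: float = 1500.0
) -> float:
    """Minimum of a mean baselined pupil trace over (0, window_ms]."""
    offsets_ms = np.asarray(offsets_ms)
    sel = (offsets_ms > 0) & (offsets_ms <= window_ms)
    if not sel.any() or offsets_ms[sel].max() < window_ms:
        raise ValueError(f"trace does not cover (0, {window_ms}] ms")
    window = np.asarray(mean_trace, dtype=float)[sel]
    if np.isnan(window).all():
        raise ValueError("window contains no finite samples")
    return float(np.nanmin(window))


def fit_slope(minima: np.ndarray) -> SlopeResult:
    """Least-squares line through the minima against ranks (1, 2, 3)."""
    minima = np.asarray(minima, dtype=float)
    if minima.shape != (3,):
        raise ValueError("expected one minimum per stimulus (white, glare, nonglare)")
    # closed-form least squares for the equally spaced ranks (1, 2, 3):
    # exact (no float residue) on degenerate equal-minima input
    slope = (minima[2] - minima[0]) / 2.0
    intercept = minima.mean() - slope * 2.0
    return SlopeResult(minima=minima, slope=float(slope), intercept=float(intercept))


def luminance_slope_test(
    minima_by_group: dict[str, np.ndarray],
    alternative: str = "greater",
) -> tuple[dict[str, list[SlopeResult]], pd.DataFrame]:
    """Per-participant slopes and the group test against a null slope of 0.

    ``minima_by_group`` maps a participant-group name (e.g. controls,
    patients-sighted, aware-blind) to an (n_participants, 3) array of
    minima ordered white, glare, nonglare. Each group with at least 2
    participants gets a Wilcoxon signed-rank test of slopes versus 0
    (Pratt handling of exact zeros); Holm correction is applied across the
    participant-group family.
    """
    slopes_by_group: dict[str, list[SlopeResult]] = {}
    rows = []
    for group, minima in minima_by_group.items():
        minima = np.atleast_2d(np.asarray(minima, dtype=float))
        results = [fit_slope(m) for m in minima]
        slopes_by_group[group] = results
        slopes = np.array([r.slope for r in results])
        if slopes.size < 2:
            rows.append({"group": group, "n": slopes.size, "statistic": np.nan, "p_raw": np.nan, "skipped": "fewer than 2 participants"})
            continue
        if np.all(slopes == 0):
            # degenerate all-zero sample: no evidence against the null
            rows.append({"group": group, "n": slopes.size, "statistic": 0.0, "p_raw": 1.0, "skipped": None})
            continue
        res = stats.wilcoxon(slopes, zero_method="pratt", alternative=alternative)
        rows.append({"group": group, "n": slopes.size, "statistic": float(res.statistic), "p_raw": float(res.pvalue), "skipped": None})
    report = pd.DataFrame(rows)
    report["p_holm"] = np.nan
    ok = report["p_raw"].notna()
    if ok.any():
        report.loc[ok, "p_holm"] = holm_adjust(report.loc[ok, "p_raw"])
    return slopes_by_group, report
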