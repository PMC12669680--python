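"""Behavioral metrics for the visual perception and brightness tasks.

Perception rate is the fraction of presented targets answered with a
keypress within 5000 ms of onset; orientation accuracy is the fraction of
perceived targets whose key matched the target orientation (chance 0.5).
Brightness judgments are scored 1 / 0.5 / 0 points per pairwise trial
(brighter / equal / dimmer), so 10 trials per pairing give each stimulus a
0-20 point range over its two pairings. The correspondence table reduces
task behavior, verbal report, and eye metrics to present/absent calls per
participant's blind field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import holm_adjust, signed_rank_test
from .recording import TARGET_CLASSES
from .synth import BRIGHTNESS_PAIRINGS, BRIGHTNESS_STIMULI

RESPONSE_WINDOW_MS = 5000
_KEY_OF_CLASS = {"target-plus": "plus", "target-x": "x"}


@dataclass
class BehavioralSummary:
    field: str
    n_targets: int
    n_perceived: int
    perception_rate: float | None
    false_positive_rate: float | None
    rts_s: np.ndarray
    orientation_accuracy: float | None = None
    flags: list[str] = field(default_factory=list)


def match_presses(
    events: pd.DataFrame,
    responses: pd.DataFrame,
    window_ms: int = RESPONSE_WINDOW_MS,
) -> pd.DataFrame:
    """Greedily credit each press to at most one target.

    Presses are scanned in time order; each is assigned to the earliest
    still-unmatched target whose window (onset, onset + window_ms]
    contains it. Returns one row per target with its matched press (if
    any), and the set of unmatched presses is recoverable by difference.
    """
    targets = events[events["event_class"].isin(TARGET_CLASSES)].reset_index(drop=True)
    matched_press = np.full(len(targets), -1)
    press_times = responses["press_ms"].to_numpy() if len(responses) else np.array([])
    press_used = np.zeros(press_times.size, dtype=bool)
    onsets = targets["onset_ms"].to_numpy()
    for pi, t in enumerate(press_times):
        eligible = np.flatnonzero(
            (matched_press == -1) & (onsets < t) & (t <= onsets + window_ms)
        )
        if eligible.size:
            matched_press[eligible[0]] = pi
            press_used[pi] = True
    out = targets.copy()
    out["press_idx"] = matched_press
    out["perceived"] = matched_press >= 0
    out["press_ms"] = np.where(
        out["perceived"],
        press_times[np.maximum(matched_press, 0)] if press_times.size else -1,
        np.nan,
    )
    out["key"] = [
        responses["key"].iloc[pi] if pi >= 0 else None for pi in matched_press
    ]
    out["rt_ms"] = out["press_ms"] - out["onset_ms"]
    out.attrs["n_presses"] = int(press_times.size)
    out.attrs["n_unmatched_presses"] = int((~press_used).sum())
    return out


def score_perception(
    events: pd.DataFrame,
    responses: pd.DataFrame,
    window_ms: int = RESPONSE_WINDOW_MS,
) -> tuple[dict[str, BehavioralSummary], pd.DataFrame]:
    """Per-field behavioral summaries plus the press-to-target matching.

    The false-positive rate — unmatched presses over total presses — is a
    session-level quantity (presses carry no field label) and is reported
    identically in every field's summary; it is None when no press was
    made. A field with zero presented targets gets rate None and a flag.
    """
    matches = match_presses(events, responses, window_ms)
    n_presses = matches.attrs["n_presses"]
    n_unmatched = matches.attrs["n_unmatched_presses"]
    fpr = (n_unmatched / n_presses) if n_presses > 0 else None
    summaries: dict[str, BehavioralSummary] = {}
    for fld in events["field"].unique():
        sub = matches[matches["field"] == fld]
        n_t = len(sub)
        n_p = int(sub["perceived"].sum())
        flags = []
        if n_t == 0:
            flags.append("no targets presented in field")
            rate = None
        else:
            rate = n_p / n_t
        rts = sub.loc[sub["perceived"], "rt_ms"].to_numpy() / 1000.0
        if np.any(rts > 3.0):
            flags.append(f"{int(np.sum(rts > 3.0))} responses later than 3 s (possible offset-locked)")
        summaries[fld] = BehavioralSummary(
            field=fld,
            n_targets=n_t,
            n_perceived=n_p,
            perception_rate=rate,
            false_positive_rate=fpr,
            rts_s=rts,
            flags=flags,
        )
    return summaries, matches


def score_orientation(matches: pd.DataFrame, field_name: str | None = None) -> float:
    """Orientation accuracy: correct keys over perceived targets.

    Raises if the session is a one-target task version (only plus-oriented
    targets, no orientation discrimination) or if nothing was perceived.
    """
    sub = matches if field_name is None else matches[matches["field"] == field_name]
    if sub["event_class"].nunique() < 2:
        raise ValueError("one-target task version: orientation accuracy undefined")
    perc = sub[sub["perceived"]]
    if len(perc) == 0:
        raise ValueError("no perceived targets")
    correct = sum(
        _KEY_OF_CLASS[cls] == key for cls, key in zip(perc["event_class"], perc["key"])
    )
    return correct / len(perc)


def binomial_above_chance(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial p-value, P(X >= k) under p0."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)


@dataclass
class RTComparison:
    test: str
    n: int
    statistic: float
    p: float
    skipped: str | None = None
    flags: list[str] = field(default_factory=list)


def compare_rt(
    rts_a: np.ndarray, rts_b: np.ndarray, paired: bool = True
) -> RTComparison:
    """Two-sided comparison of two reaction-time samples (seconds).

    Paired mode trims both samples to the common length in trial order and
    uses a Wilcoxon signed-rank test; unpaired mode falls back to a
    rank-sum (Mann-Whitney U) test and flags the fallback.
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return RTComparison("none", min(a.size, b.size), np.nan, np.nan, skipped="fewer than 2 observations per side")
    if paired:
        flags = []
        m = min(a.size, b.size)
        if a.size != b.size:
            flags.append("unequal lengths trimmed to common trial count")
        w, p, n = signed_rank_test(a[:m] - b[:m], alternative="two-sided")
        return RTComparison("wilcoxon-signed-rank", n, w, p, flags=flags)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RTComparison("mann-whitney-u", a.size + b.size, float(u), float(p), flags=["unpaired fallback"])


# ---------------------------------------------------------------------------
# brightness perception


@dataclass
class BrightnessScore:
    points: dict[str, float]  # per stimulus, 0..(2 * n_per_pair)
    n_trials: dict[tuple[str, str], int]  # per pairing


def score_brightness(choices: pd.DataFrame) -> BrightnessScore:
    """Score one participant's pairwise brightness judgments.

    Each trial awards 1 point to the stimulus reported brighter, 0.5 to
    both when reported equal, and 0 to the dimmer stimulus, so the two
    stimuli of a pairing always split that pairing's trial count.
    """
    unknown = (set(choices["stim_a"]) | set(choices["stim_b"])) - set(BRIGHTNESS_STIMULI)
    if unknown:
        raise ValueError(f"unknown stimulus identity {sorted(unknown)}")
    points = {s: 0.0 for s in BRIGHTNESS_STIMULI}
    n_trials = {pair: 0 for pair in BRIGHTNESS_PAIRINGS}
    for _, row in choices.iterrows():
        a, b, choice = row["stim_a"], row["stim_b"], row["choice"]
        pair = (a, b) if (a, b) in n_trials else (b, a)
        n_trials[pair] += 1
        if choice == "first-brighter":
            points[a] += 1.0
        elif choice == "second-brighter":
            points[b] += 1.0
        elif choice == "equal":
            points[a] += 0.5
            points[b] += 0.5
        else:
            raise ValueError(f"unknown choice {choice!r}")
    return BrightnessScore(points=points, n_trials=n_trials)


def brightness_group_report(scores: list[BrightnessScore]) -> pd.DataFrame:
    """Friedman test over the three stimuli plus Holm-corrected post-hocs.

    Post-hoc paired Wilcoxon tests compare glare vs nonglare and nonglare
    vs isoluminant across participants. Tests are skipped (with reason)
    when any participant has a pairing with zero trials or fewer than 2
    participants are available.
    """
    rows = []
    if len(scores) < 2:
        return pd.DataFrame(
            [{"test": "friedman", "statistic": np.nan, "p_raw": np.nan, "p_holm": np.nan, "skipped": "fewer than 2 participants"}]
        )
    if any(n == 0 for s in scores for n in s.n_trials.values()):
        return pd.DataFrame(
            [{"test": "friedman", "statistic": np.nan, "p_raw": np.nan, "p_holm": np.nan, "skipped": "a pairing with zero trials"}]
        )
    mat = np.array([[s.points[st] for st in BRIGHTNESS_STIMULI] for s in scores])
    chi2, p_f = stats.friedmanchisquare(*mat.T)
    rows.append({"test": "friedman", "statistic": float(chi2), "p_raw": float(p_f), "skipped": None})
    post = []
    for a, b in (("glare", "nonglare"), ("nonglare", "isoluminant")):
        ia, ib = BRIGHTNESS_STIMULI.index(a), BRIGHTNESS_STIMULI.index(b)
        w, p, n = signed_rank_test(mat[:, ia] - mat[:, ib], alternative="two-sided")
        post.append({"test": f"{a} vs {b}", "statistic": w, "p_raw": p, "skipped": None})
    adj = holm_adjust([r["p_raw"] for r in post])
    for r, pa in zip(post, adj):
        r["p_holm"] = pa
    rows[0]["p_holm"] = rows[0]["p_raw"]
    rows.extend(post)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correspondence among measures


@dataclass
class CorrespondenceRow:
    participant: str
    task_behavior: str  # "present" / "absent"
    verbal_report: str
    eye_metrics: str

    @property
    def agree(self) -> bool:
        return self.task_behavior == self.verbal_report == self.eye_metrics


def correspondence_table(
    perception_rates: dict[str, float],
    verbal_fractions: dict[str, float],
    eye_metric_present: dict[str, bool],
    rate_threshold: float = 0.25,
    verbal_threshold: float = 0.10,
) -> tuple[list[CorrespondenceRow], int]:
    """Present/absent designation of the three blind-field measures.

    Task behavior is present iff the blind-field perception rate is
    strictly greater than 0.25; verbal report iff awareness was reported
    on strictly more than 10% of trials; eye metrics iff at least one
    metric showed a stimulus-evoked response. Returns the rows and the
    number of participants on whom all three measures agree.
    """
    rows = []
    for pid in perception_rates:
        rows.append(
            CorrespondenceRow(
                participant=pid,
                task_behavior="present" if perception_rates[pid] > rate_threshold else "absent",
                verbal_report="present" if verbal_fractions.get(pid, 0.0) > verbal_threshold else "absent",
                eye_metrics="present" if eye_metric_present.get(pid, False) else "absent",
            )
        )
    return rows, sum(r.agree for r in rows)
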