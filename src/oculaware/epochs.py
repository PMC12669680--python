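"""Stimulus- and blank-locked epoch extraction, baselining, and exclusion.

Epochs are 18,001 ms (offsets -9000..+9000 ms on the 1-ms grid) centered at
event onset. Every stimulus event is paired with one blank event sampled
uniformly from the interstimulus interval 4000-7000 ms after that
stimulus's onset; the pairing survives exclusion bookkeeping, so paired
analyses can drop a pair whenever either member is excluded. Pupil epochs
are baselined to the mean of the 1000 ms immediately preceding the event;
binary (blink/microsaccade) epochs are never baselined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import moving_average
from .preprocess import BinaryEventTimecourse

ANALYSIS_START_MS = -1000
ANALYSIS_END_MS = 6000


@dataclass
class EpochWindow:
    pre_ms: int = 9000
    post_ms: int = 9000
    analysis_start_ms: int = ANALYSIS_START_MS
    analysis_end_ms: int = ANALYSIS_END_MS
    baseline_ms: int = 1000  # pre-event

    def __post_init__(self) -> None:
        if self.pre_ms < 0 or self.post_ms < 0:
            raise ValueError("window half-widths must be nonnegative")
        if not (-self.pre_ms <= self.analysis_start_ms <= self.analysis_end_ms <= self.post_ms):
            raise ValueError("analysis window must be contained in the total window")
        if self.baseline_ms > self.pre_ms:
            raise ValueError("baseline interval must fit in the pre-event window")

    @property
    def offsets_ms(self) -> np.ndarray:
        return np.arange(-self.pre_ms, self.post_ms + 1)

    @property
    def n_samples(self) -> int:
        return self.pre_ms + self.post_ms + 1


@dataclass
class EpochSet:
    """Epochs x samples matrix with metadata and an inclusion mask."""

    data: np.ndarray
    offsets_ms: np.ndarray
    meta: pd.DataFrame  # event_class, field, block, event_ms, is_blank, pair_id
    included: np.ndarray
    exclusion_reason: np.ndarray
    missing: np.ndarray | None = field(default=None, repr=False)
    raw_data: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def exclusion_fraction(self) -> float:
        return 1.0 - self.n_included / self.n_epochs if self.n_epochs else 0.0

    def analysis_slice(
        self, start_ms: int = ANALYSIS_START_MS, end_ms: int = ANALYSIS_END_MS
    ) -> np.ndarray:
        return (self.offsets_ms >= start_ms) & (self.offsets_ms <= end_ms)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask, dtype=bool)
        return EpochSet(
            data=self.data[mask],
            offsets_ms=self.offsets_ms,
            meta=self.meta.loc[mask].reset_index(drop=True),
            included=self.included[mask],
            exclusion_reason=self.exclusion_reason[mask],
            missing=self.missing[mask] if self.missing is not None else None,
            raw_data=self.raw_data[mask] if self.raw_data is not None else None,
        )

    # -- serialization: binary arrays + metadata CSV + window JSON --------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.save(outdir / "data.npy", self.data)
        np.save(outdir / "offsets_ms.npy", self.offsets_ms)
        if self.missing is not None:
            np.save(outdir / "missing.npy", self.missing)
        if self.raw_data is not None:
            np.save(outdir / "raw_data.npy", self.raw_data)
        meta = self.meta.copy()
        meta["included"] = self.included
        meta["exclusion_reason"] = self.exclusion_reason
        meta.to_csv(outdir / "meta.csv", index=False)
        with open(outdir / "window.json", "w") as fh:
            json.dump(
                {
                    "pre_ms": int(-self.offsets_ms[0]),
                    "post_ms": int(self.offsets_ms[-1]),
                },
                fh,
            )

    @classmethod
    def load(cls, outdir: str | Path) -> "EpochSet":
        outdir = Path(outdir)
        meta = pd.read_csv(outdir / "meta.csv")
        included = meta.pop("included").to_numpy(dtype=bool)
        reason = meta.pop("exclusion_reason").to_numpy(dtype=object)
        reason = np.where(pd.isna(reason), None, reason)
        missing_p = outdir / "missing.npy"
        raw_p = outdir / "raw_data.npy"
        return cls(
            data=np.load(outdir / "data.npy"),
            offsets_ms=np.load(outdir / "offsets_ms.npy"),
            meta=meta,
            included=included,
            exclusion_reason=reason,
            missing=np.load(missing_p) if missing_p.exists() else None,
            raw_data=np.load(raw_p) if raw_p.exists() else None,
        )


@dataclass
class FractionTrace:
    """Per-sample event fraction across epochs (mean in [0, 1] pre-smoothing)."""

    mean: np.ndarray
    sem: np.ndarray
    n_epochs: int
    kind: str
    offsets_ms: np.ndarray | None = None


def sample_blank_events(
    events: pd.DataFrame,
    block_end_ms: dict[int, int],
    rng: np.random.Generator,
    lo_ms: int = 4000,
    hi_ms: int = 7000,
    guard_ms: int = 1000,
) -> pd.DataFrame:
    """Draw one blank event per stimulus from the interstimulus interval.

    The blank time is uniform in [onset + ``lo_ms``, onset + ``hi_ms``],
    clipped to end ``guard_ms`` before the next stimulus onset (or before
    the block end for the final trial). The blank inherits the stimulus's
    class and field labels so stimulus and blank epochs pair one-to-one;
    stimuli whose admissible interval is empty get no blank (logged via the
    returned frame's ``pair_id`` gaps).
    """
    rows = []
    for block, grp in events.groupby("block", sort=True):
        onsets = grp["onset_ms"].to_numpy()
        for j, (idx, ev) in enumerate(grp.iterrows()):
            lo = ev["onset_ms"] + lo_ms
            if j + 1 < len(grp):
                hi = min(ev["onset_ms"] + hi_ms, int(onsets[j + 1]) - guard_ms)
            else:
                hi = min(ev["onset_ms"] + hi_ms, int(block_end_ms[block]) - 1)
            if hi < lo:
                continue
            rows.append(
                {
                    "onset_ms": int(rng.integers(lo, hi + 1)),
                    "event_class": ev["event_class"],
                    "field": ev["field"],
                    "block": block,
                    "pair_id": idx,
                }
            )
    return pd.DataFrame(rows, columns=["onset_ms", "event_class", "field", "block", "pair_id"])


def combine_stimulus_and_blanks(
    events: pd.DataFrame, blanks: pd.DataFrame
) -> pd.DataFrame:
    """Stack stimulus and blank events with ``is_blank`` and shared ``pair_id``.

    Stimuli without a sampled blank are dropped so that pairing is a
    bijection on the combined set.
    """
    stim = events.loc[blanks["pair_id"]].copy()
    stim["pair_id"] = blanks["pair_id"].to_numpy()
    stim["is_blank"] = False
    blk = blanks.copy()
    blk["is_blank"] = True
    return pd.concat([stim, blk], ignore_index=True)


def extract_epochs(
    timecourse: np.ndarray | BinaryEventTimecourse,
    events: pd.DataFrame,
    window: EpochWindow | None = None,
    baseline: bool = False,
    t0_ms: int = 0,
    missing: np.ndarray | None = None,
) -> EpochSet:
    """Segment a timecourse into event-centered epochs.

    Binary timecourses must not request baselining. Samples outside the
    recording extent are padded as missing (NaN). When ``baseline`` is set
    the per-epoch mean of the ``window.baseline_ms`` pre-event samples is
    subtracted and the unbaselined values are kept in ``raw_data``.
    """
    window = window or EpochWindow()
    if isinstance(timecourse, BinaryEventTimecourse):
        if baseline:
            raise ValueError("binary epochs are never baselined")
        values = timecourse.values.astype(float)
        t0_ms = timecourse.t0_ms
    else:
        values = np.asarray(timecourse, dtype=float)
    n = values.size
    n_ep = len(events)
    data = np.full((n_ep, window.n_samples), np.nan)
    miss = None
    if missing is not None:
        missing = np.asarray(missing, dtype=bool)
        miss = np.ones((n_ep, window.n_samples), dtype=bool)
    for i, onset in enumerate(events["onset_ms"].to_numpy()):
        c = int(onset) - t0_ms
        lo, hi = c - window.pre_ms, c + window.post_ms + 1
        src_lo, src_hi = max(lo, 0), min(hi, n)
        if src_hi <= src_lo:
            continue
        dst_lo = src_lo - lo
        data[i, dst_lo : dst_lo + (src_hi - src_lo)] = values[src_lo:src_hi]
        if miss is not None:
            miss[i, dst_lo : dst_lo + (src_hi - src_lo)] = missing[src_lo:src_hi]
    meta = events.reset_index(drop=True).copy()
    if "is_blank" not in meta.columns:
        meta["is_blank"] = False
    if "pair_id" not in meta.columns:
        meta["pair_id"] = np.arange(n_ep)
    meta = meta.rename(columns={"onset_ms": "event_ms"})
    raw = None
    if baseline:
        raw = data.copy()
        offs = window.offsets_ms
        base = (offs >= -window.baseline_ms) & (offs < 0)
        with np.errstate(invalid="ignore"):
            data = data - np.nanmean(data[:, base], axis=1, keepdims=True)
    return EpochSet(
        data=data,
        offsets_ms=window.offsets_ms,
        meta=meta,
        included=np.ones(n_ep, dtype=bool),
        exclusion_reason=np.full(n_ep, None, dtype=object),
        missing=miss,
        raw_data=raw,
    )


def apply_pupil_exclusion(
    epochs: EpochSet,
    extreme_threshold: float = 1750.0,
    missing_frac: float = 0.5,
) -> EpochSet:
    """Exclude pupil epochs with extreme values or heavy missingness.

    Within the analysis interval (-1000..+6000 ms), an epoch is excluded
    iff any raw (pre-baseline) value is strictly greater than
    ``extreme_threshold`` or the fraction of missing samples is strictly
    greater than ``missing_frac``. The mask and reasons are updated in
    place on a copy of ``epochs``.
    """
    sel = epochs.analysis_slice()
    values = epochs.raw_data if epochs.raw_data is not None else epochs.data
    included = epochs.included.copy()
    reason = epochs.exclusion_reason.copy()
    with np.errstate(invalid="ignore"):
        extreme = np.nanmax(np.where(np.isnan(values[:, sel]), -np.inf, values[:, sel]), axis=1) > extreme_threshold
    if epochs.missing is not None:
        frac_missing = epochs.missing[:, sel].mean(axis=1)
    else:
        frac_missing = np.isnan(values[:, sel]).mean(axis=1)
    too_missing = frac_missing > missing_frac
    for i in range(epochs.n_epochs):
        if not included[i]:
            continue
        if extreme[i]:
            included[i], reason[i] = False, "extreme"
        elif too_missing[i]:
            included[i], reason[i] = False, "missing"
    return EpochSet(
        data=epochs.data,
        offsets_ms=epochs.offsets_ms,
        meta=epochs.meta,
        included=included,
        exclusion_reason=reason,
        missing=epochs.missing,
        raw_data=epochs.raw_data,
    )


def apply_binary_exclusion(
    epochs: EpochSet,
    zero_frac: float = 0.5,
    literal_zero_rule: bool = False,
) -> EpochSet:
    """Exclude binary epochs with prolonged loss of eye tracking.

    An epoch is excluded iff strictly more than ``zero_frac`` of the
    analysis-interval samples lack valid tracking (requires the epochs to
    carry a ``missing`` mask). With ``literal_zero_rule`` the criterion is
    instead applied to the fraction of 0-valued samples, which also
    excludes epochs that merely contain few events.
    """
    sel = epochs.analysis_slice()
    if literal_zero_rule:
        frac = np.nanmean(epochs.data[:, sel] == 0, axis=1)
    else:
        if epochs.missing is None:
            raise ValueError("tracking-validity mask required (or use literal_zero_rule)")
        frac = epochs.missing[:, sel].mean(axis=1)
    included = epochs.included.copy()
    reason = epochs.exclusion_reason.copy()
    for i in np.flatnonzero(included & (frac > zero_frac)):
        included[i], reason[i] = False, "untracked"
    return EpochSet(
        data=epochs.data,
        offsets_ms=epochs.offsets_ms,
        meta=epochs.meta,
        included=included,
        exclusion_reason=reason,
        missing=epochs.missing,
        raw_data=epochs.raw_data,
    )


def enforce_pairing(epochs: EpochSet) -> EpochSet:
    """Drop both members of a stimulus/blank pair when either is excluded."""
    included = epochs.included.copy()
    reason = epochs.exclusion_reason.copy()
    for pid, grp in epochs.meta.groupby("pair_id"):
        idx = grp.index.to_numpy()
        if not included[idx].all():
            for i in idx:
                if included[i]:
                    included[i], reason[i] = False, "partner-excluded"
    return EpochSet(
        data=epochs.data,
        offsets_ms=epochs.offsets_ms,
        meta=epochs.meta,
        included=included,
        exclusion_reason=reason,
        missing=epochs.missing,
        raw_data=epochs.raw_data,
    )


def fraction_timecourse(
    epochs: EpochSet, smooth_ms: float = 100.0, kind: str = "event"
) -> FractionTrace:
    """Mean and SEM of a binary epoch set, with the mean smoothed."""
    data = epochs.data[epochs.included]
    if data.shape[0] == 0:
        raise ValueError("no epochs")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(data, axis=0)
        n_eff = np.sum(~np.isnan(data), axis=0)
        sd = np.nanstd(data, axis=0, ddof=1) if data.shape[0] > 1 else np.zeros_like(mean)
    sem = np.where(n_eff > 0, sd / np.sqrt(np.maximum(n_eff, 1)), np.nan)
    smoothed = moving_average(np.nan_to_num(mean, nan=0.0), int(round(smooth_ms)))
    smoothed[np.isnan(mean)] = np.nan
    return FractionTrace(
        mean=smoothed,
        sem=sem,
        n_epochs=int(data.shape[0]),
        kind=kind,
        offsets_ms=epochs.offsets_ms,
    )
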