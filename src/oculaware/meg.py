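"""Single-sensor field-potential epoching and cluster-based permutation tests.

The evoked analysis compares stimulus-locked epochs against blank-event
epochs on one occipital sensor. Epochs are 8001 ms centered on the
(trigger-corrected) event; statistics are nonparametric: per-sample
two-sample t-values thresholded at a cluster-forming critical value, with
contiguous same-sign supra-threshold runs scored by their summed-t mass and
compared against a max-mass permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclass
class FieldPotentialEpochSet:
    """Epochs x samples matrix of field potentials in fT on a shared grid."""

    data: np.ndarray
    offsets_ms: np.ndarray
    condition: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.data.shape[1] != self.offsets_ms.size:
            raise ValueError("data and offsets_ms disagree on sample count")
        if self.data.shape[0] != self.condition.size:
            raise ValueError("data and condition disagree on epoch count")

    def select(self, condition: str) -> np.ndarray:
        return self.data[self.condition == condition]

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.save(outdir / "data.npy", self.data)
        np.save(outdir / "offsets_ms.npy", self.offsets_ms)
        pd.DataFrame({"condition": self.condition}).to_csv(
            outdir / "condition.csv", index=False
        )
        with open(outdir / "sampling_rate.txt", "w") as fh:
            fh.write(str(self.sampling_rate))

    @classmethod
    def load(cls, outdir) -> "FieldPotentialEpochSet":
        from pathlib import Path

        outdir = Path(outdir)
        with open(outdir / "sampling_rate.txt") as fh:
            fs = float(fh.read().strip())
        return cls(
            data=np.load(outdir / "data.npy"),
            offsets_ms=np.load(outdir / "offsets_ms.npy"),
            condition=pd.read_csv(outdir / "condition.csv")["condition"].to_numpy(),
            sampling_rate=fs,
        )


@dataclass
class ClusterResult:
    """Temporal clusters with mass statistics and permutation p-values."""

    clusters: list[tuple[float, float, float]]  # (start_ms, end_ms, mass)
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    t_trace: np.ndarray = field(repr=False, default=None)
    t_offsets_ms: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[tuple[float, float, float]]:
        return [c for c, p in zip(self.clusters, self.p_values) if p <= self.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"start_ms": s, "end_ms": e, "mass": m, "p": p}
                for (s, e, m), p in zip(self.clusters, self.p_values)
            ]
        )


def preprocess_field(
    trace: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (0.1, 115.0),
    notches: tuple[float, ...] = (60.0, 120.0),
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass plus narrow notch filtering of a sensor trace."""
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"band edges {band} incompatible with sampling rate {sampling_rate}"
        )
    x = np.asarray(trace, dtype=float)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    for f0 in notches:
        if f0 >= nyq:
            continue
        b, a = signal.iirnotch(f0, notch_q, fs=sampling_rate)
        y = signal.filtfilt(b, a, y)
    return y


def epoch_field(
    trace: np.ndarray,
    events: pd.DataFrame,
    sampling_rate: float = 1000.0,
    trigger_correction_ms: float = 19.0,
    half_window_ms: float = 4000.0,
    t0_ms: float = 0.0,
) -> FieldPotentialEpochSet:
    """Segment a sensor trace into epochs centered at corrected event times.

    The trigger correction compensates the projector's presentation delay:
    an event marked at trigger time t actually appeared at
    t + ``trigger_correction_ms``, so epochs are centered there. Events whose
    window extends outside the recording are dropped (and reported via the
    returned epoch count).
    """
    x = np.asarray(trace, dtype=float)
    step_ms = 1000.0 / sampling_rate
    half = int(round(half_window_ms / step_ms))
    offsets = np.arange(-half, half + 1) * step_ms
    rows, labels = [], []
    for _, ev in events.iterrows():
        center = (ev["onset_ms"] + trigger_correction_ms - t0_ms) / step_ms
        c = int(round(center))
        if c - half < 0 or c + half >= x.size:
            continue
        rows.append(x[c - half : c + half + 1])
        labels.append(ev.get("condition", ev.get("event_class", "event")))
    if not rows:
        return FieldPotentialEpochSet(
            data=np.empty((0, offsets.size)),
            offsets_ms=offsets,
            condition=np.asarray(labels),
            sampling_rate=sampling_rate,
        )
    return FieldPotentialEpochSet(
        data=np.vstack(rows),
        offsets_ms=offsets,
        condition=np.asarray(labels),
        sampling_rate=sampling_rate,
    )


def _t_per_sample(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; zero variance maps to t=0."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(np.isfinite(t), t, 0.0)


def _clusters_from_t(
    t: np.ndarray, t_crit: float
) -> list[tuple[int, int, float]]:
    """Maximal contiguous same-sign runs of |t| > t_crit; mass = sum of t."""
    idx = np.flatnonzero(np.abs(t) > t_crit)
    if idx.size == 0:
        return []
    s = np.sign(t[idx])
    breaks = np.flatnonzero((np.diff(idx) > 1) | (s[1:] != s[:-1]))
    return [
        (int(g[0]), int(g[-1]) + 1, float(t[g[0] : g[-1] + 1].sum()))
        for g in np.split(idx, breaks + 1)
    ]


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    offsets_ms: np.ndarray,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
    test_window_ms: tuple[float, float] = (0.0, 500.0),
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    final_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-based permutation test between two epoch conditions.

    Each epoch is baseline-corrected by its own mean over ``baseline_ms``.
    Clusters of samples in ``test_window_ms`` whose two-sample |t| exceeds
    the two-sided critical value at ``cluster_alpha`` are scored by summed
    t; the permutation null is the maximum |mass| over ``n_perm`` random
    exchanges of condition labels, and cluster p-values use the standard
    add-one estimator (1 + #{null >= observed}) / (1 + n_perm).
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 epochs per condition")
    offsets = np.asarray(offsets_ms, dtype=float)
    base = (offsets >= baseline_ms[0]) & (offsets < baseline_ms[1])
    test = (offsets >= test_window_ms[0]) & (offsets < test_window_ms[1])
    if not base.any() or not test.any():
        raise ValueError("baseline or test window not covered by epoch grid")
    a = a - a[:, base].mean(axis=1, keepdims=True)
    b = b - b[:, base].mean(axis=1, keepdims=True)
    at, bt = a[:, test], b[:, test]
    na, nb = at.shape[0], bt.shape[0]
    df = na + nb - 2
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)

    t_obs = _t_per_sample(at, bt)
    obs_clusters = _clusters_from_t(t_obs, t_crit)

    pooled = np.vstack([at, bt])
    null_max = np.zeros(n_perm)
    idx = np.arange(na + nb)
    for k in range(n_perm):
        rng.shuffle(idx)
        tp = _t_per_sample(pooled[idx[:na]], pooled[idx[na:]])
        perm_clusters = _clusters_from_t(tp, t_crit)
        if perm_clusters:
            null_max[k] = max(abs(m) for _, _, m in perm_clusters)

    test_offsets = offsets[test]
    clusters_ms = []
    p_values = []
    for i0, i1, mass in obs_clusters:
        clusters_ms.append(
            (float(test_offsets[i0]), float(test_offsets[i1 - 1] + 1), mass)
        )
        p_values.append((1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm))
    return ClusterResult(
        clusters=clusters_ms,
        p_values=np.asarray(p_values),
        n_permutations=n_perm,
        alpha=final_alpha,
        t_trace=t_obs,
        t_offsets_ms=test_offsets,
    )
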