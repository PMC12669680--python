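"""Two-level stacking classification of stimulus versus blank epochs.

Three first-level linear maximum-margin (hinge-loss) classifiers — one per
eye metric (pupil, blink, microsaccade) — are trained with ten-fold
cross-validation on binned epoch samples from the 4000 ms after event
onset. Their out-of-fold signed decision scores become the three features
of a second-level linear classifier evaluated with the *same* fold
partition (nested cross-validation), so no epoch's second-level prediction
is informed by a first-level model that saw it. Accuracy is the fraction
of correctly predicted held-out epochs; chance is the majority-class
proportion of the epoch set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from ._utils import substream
from .epochs import EpochSet

METRICS = ("pupil", "blink", "microsaccade")


@dataclass
class FoldAssignment:
    """Per-epoch fold ids (1..n_folds); paired epochs share a fold."""

    fold_id: np.ndarray
    n_folds: int
    stratified: bool = True

    def __post_init__(self) -> None:
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        present = np.unique(self.fold_id)
        if not np.all((present >= 1) & (present <= self.n_folds)):
            raise ValueError("fold ids must lie in 1..n_folds")


@dataclass
class StackedClassifierResult:
    first_level_scores: np.ndarray  # epochs x metrics, signed margin distance
    metrics: tuple[str, ...]
    second_level_scores: np.ndarray
    predictions: np.ndarray  # bool, True = stimulus
    labels: np.ndarray  # bool, True = stimulus
    fold_id: np.ndarray
    accuracy: float
    chance: float
    n_epochs: int
    condition: tuple[str, str] | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "chance": self.chance,
            "n_epochs": self.n_epochs,
            "condition": list(self.condition) if self.condition else None,
            "metrics": list(self.metrics),
        }


def build_feature_matrix(
    epochs: EpochSet, feature_end_ms: int = 4000, bin_ms: int = 20
) -> np.ndarray:
    """Bin-averaged features from (0, feature_end_ms] for included epochs.

    Consecutive non-overlapping bins of ``bin_ms`` yield
    ``feature_end_ms / bin_ms`` features per epoch; ``bin_ms`` must divide
    ``feature_end_ms``. Pass ``bin_ms=1`` for raw-sample features.
    """
    if feature_end_ms % bin_ms != 0:
        raise ValueError("bin_ms must divide feature_end_ms")
    sel = (epochs.offsets_ms > 0) & (epochs.offsets_ms <= feature_end_ms)
    window = epochs.data[epochs.included][:, sel]
    n_bins = feature_end_ms // bin_ms
    binned = window.reshape(window.shape[0], n_bins, bin_ms)
    # bins past the recording edge are all-NaN; treat them as 0 signal
    counts = np.sum(~np.isnan(binned), axis=2)
    sums = np.nansum(np.nan_to_num(binned, nan=0.0), axis=2)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def assign_folds(
    pair_id: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Assign stimulus/blank pairs to folds, both members sharing a fold.

    The assignment depends only on the pair identifiers and the seed, never
    on the data, and distributes pairs as evenly as possible. Because each
    pair contributes one stimulus and one blank epoch, pair-level
    round-robin assignment is label-stratified by construction.
    """
    pair_id = np.asarray(pair_id)
    unique_pairs = np.unique(pair_id)
    if unique_pairs.size < n_folds:
        raise ValueError("fewer pairs than folds")
    rng = substream(seed, "folds")
    order = rng.permutation(unique_pairs.size)
    fold_of_pair = {
        unique_pairs[p]: (rank % n_folds) + 1 for rank, p in enumerate(order)
    }
    fold_id = np.array([fold_of_pair[p] for p in pair_id])
    return FoldAssignment(fold_id=fold_id, n_folds=n_folds, stratified=stratified)


def _fit_level(
    X: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    C: float,
    level_name: str,
) -> np.ndarray:
    """Out-of-fold signed decision scores of a linear max-margin classifier."""
    scores = np.zeros(y.size)
    for f in range(1, folds.n_folds + 1):
        test = folds.fold_id == f
        train = ~test
        if not test.any():
            continue
        if y[train].all() or not y[train].any():
            raise ValueError(f"a class is absent from the training split of fold {f} ({level_name})")
        scaler = StandardScaler().fit(X[train])
        # the iteration cap trades late-stage hinge refinement for speed;
        # decision signs are stable well before it on these problem sizes
        clf = LinearSVC(C=C, max_iter=2000)
        with warnings.catch_warnings():
            # perfectly separable folds stall liblinear harmlessly
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(scaler.transform(X[train]), y[train])
        scores[test] = clf.decision_function(scaler.transform(X[test]))
    return scores


def fit_stacked_classifier(
    features_by_metric: dict[str, np.ndarray],
    labels: np.ndarray,
    folds: FoldAssignment,
    regularization: float = 1.0,
    condition: tuple[str, str] | None = None,
) -> StackedClassifierResult:
    """Fit the two-level stack and score held-out epochs.

    ``labels`` is boolean (True = stimulus epoch). A second-level score of
    exactly 0 predicts blank (conservative toward the null).
    """
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 epochs per class")
    metric_names = tuple(features_by_metric)
    n = y.size
    first = np.zeros((n, len(metric_names)))
    for j, m in enumerate(metric_names):
        X = np.asarray(features_by_metric[m], dtype=float)
        if X.shape[0] != n:
            raise ValueError(f"feature block {m!r} not aligned with labels")
        first[:, j] = _fit_level(X, y, folds, regularization, f"first-level {m}")
    second = _fit_level(first, y, folds, regularization, "second-level")
    predictions = second > 0.0
    accuracy = float(np.mean(predictions == y))
    chance = float(max(y.mean(), 1.0 - y.mean()))
    return StackedClassifierResult(
        first_level_scores=first,
        metrics=metric_names,
        second_level_scores=second,
        predictions=predictions,
        labels=y,
        fold_id=folds.fold_id,
        accuracy=accuracy,
        chance=chance,
        n_epochs=n,
        condition=condition,
    )


def classify_stimulus_vs_blank(
    epoch_sets: dict[str, EpochSet],
    category: str,
    field_name: str,
    n_folds: int = 10,
    seed: int = 0,
    regularization: float = 1.0,
    feature_end_ms: int = 4000,
    bin_ms: int = 20,
) -> StackedClassifierResult:
    """End-to-end stack for one condition (stimulus category x field).

    ``epoch_sets`` maps metric name to its EpochSet over the same events.
    Classification is restricted to the intersection of included epochs
    across the three metrics (the stack needs all three scores per epoch),
    and to pairs with both members present.
    """
    from .recording import NONTARGET_CLASSES, TARGET_CLASSES

    classes = TARGET_CLASSES if category == "target" else NONTARGET_CLASSES
    ref = next(iter(epoch_sets.values()))
    cond = (
        ref.meta["event_class"].isin(classes) & (ref.meta["field"] == field_name)
    ).to_numpy()
    included = cond.copy()
    for es in epoch_sets.values():
        included &= es.included
    # keep only complete pairs
    meta = ref.meta
    for pid, grp in meta.loc[included].groupby("pair_id"):
        if len(grp) != 2:
            included[grp.index.to_numpy()] = False
    sub_sets = {m: es.subset(included) for m, es in epoch_sets.items()}
    sub_ref = sub_sets[next(iter(sub_sets))]
    labels = ~sub_ref.meta["is_blank"].to_numpy()
    pair_id = sub_ref.meta["pair_id"].to_numpy()
    n_pairs = np.unique(pair_id).size
    if n_pairs < 2:
        raise ValueError("fewer than 2 complete stimulus/blank pairs")
    folds = assign_folds(pair_id, n_folds=min(n_folds, n_pairs), seed=seed)
    features = {
        m: build_feature_matrix(es, feature_end_ms, bin_ms) for m, es in sub_sets.items()
    }
    return fit_stacked_classifier(
        features, labels, folds, regularization, condition=(category, field_name)
    )


def permuted_label_accuracies(
    features_by_metric: dict[str, np.ndarray],
    labels: np.ndarray,
    folds: FoldAssignment,
    n_perm: int = 200,
    seed: int = 0,
    regularization: float = 1.0,
) -> np.ndarray:
    """Null accuracies of the full stack under random label permutation.

    Labels are shuffled before any fitting, so the whole nested pipeline
    runs on label-free data; the resulting accuracy distribution is the
    permutation null used both as a leakage check (it must center on
    chance) and as the operational criterion for eye-metric presence
    (observed accuracy above its 95th percentile).
    """
    rng = substream(seed, "permutations")
    y = np.asarray(labels, dtype=bool)
    accs = np.empty(n_perm)
    k = 0
    while k < n_perm:
        yp = rng.permutation(y)
        try:
            res = fit_stacked_classifier(features_by_metric, yp, folds, regularization)
        except ValueError:
            continue  # a degenerate shuffle emptied a class in some fold
        accs[k] = res.accuracy
        k += 1
    return accs


def eye_metric_presence(observed_accuracy: float, null_accuracies: np.ndarray) -> bool:
    """Presence call: accuracy above the 95th percentile of the null."""
    return bool(observed_accuracy > np.percentile(null_accuracies, 95))


# ---------------------------------------------------------------------------
# group statistics


def signed_rank_test(
    d: np.ndarray,
    alternative: str = "greater",
    zero_method: str = "wilcox",
) -> tuple[float, float, int]:
    """One-sample Wilcoxon signed-rank test on differences ``d``.

    Uses exact sign-flip enumeration (midranks, so ties are handled) when
    there are no zeros and n <= 16; otherwise defers to scipy with a
    normal approximation. Returns (statistic W+, p, n_effective).
    """
    d = np.asarray(d, dtype=float)
    if zero_method == "wilcox":
        d_eff = d[d != 0]
    else:
        d_eff = d
    n = d_eff.size
    if n == 0:
        return 0.0, 1.0, 0
    if zero_method == "wilcox" and n <= 16:
        ranks = stats.rankdata(np.abs(d_eff))
        w_obs = float(ranks[d_eff > 0].sum())
        signs = np.array(
            [[(k >> i) & 1 for i in range(n)] for k in range(2**n)], dtype=float
        )
        w_all = signs @ ranks
        p_ge = np.mean(w_all >= w_obs - 1e-12)
        p_le = np.mean(w_all <= w_obs + 1e-12)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return w_obs, float(p), n
    try:
        res = stats.wilcoxon(d, alternative=alternative, zero_method=zero_method, method="approx")
        return float(res.statistic), float(res.pvalue), n
    except ValueError:
        return 0.0, 1.0, n


def group_accuracy_stats(
    table: pd.DataFrame,
    against_chance: list[str] | None = None,
    paired_contrasts: list[tuple[str, str]] | None = None,
    unpaired_contrasts: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Group-level tests on per-participant accuracies.

    ``table`` needs columns participant, condition, accuracy, chance, and
    (for unpaired contrasts) group. Families:

    - against-chance: one-sided (greater) Wilcoxon signed-rank of accuracy
      minus per-participant chance, one test per named condition;
    - cross-condition: paired Wilcoxon between two conditions
      (participants present in both) and one-sided Mann-Whitney U between
      two participant groups within one condition, e.g. blind-field
      accuracy for aware versus unaware patients.

    Holm-Bonferroni correction is applied separately within each family.
    Tests with fewer than 2 observations are reported as skipped.
    """
    rows = []
    for cond in against_chance or []:
        sub = table[table["condition"] == cond]
        d = (sub["accuracy"] - sub["chance"]).to_numpy()
        if d.size < 2:
            rows.append(_stat_row("against-chance", f"{cond} > chance", d.size, np.nan, np.nan, "fewer than 2 observations"))
            continue
        w, p, n = signed_rank_test(d, alternative="greater")
        rows.append(_stat_row("against-chance", f"{cond} > chance", n, w, p))
    for a, b in paired_contrasts or []:
        sub = table[table["condition"].isin([a, b])].pivot_table(
            index="participant", columns="condition", values="accuracy"
        )
        sub = sub.dropna()
        if len(sub) < 2:
            rows.append(_stat_row("cross-condition", f"{a} vs {b}", len(sub), np.nan, np.nan, "fewer than 2 observations"))
            continue
        d = (sub[a] - sub[b]).to_numpy()
        w, p, n = signed_rank_test(d, alternative="two-sided")
        rows.append(_stat_row("cross-condition", f"{a} vs {b}", n, w, p))
    for cond, ga, gb in unpaired_contrasts or []:
        sub = table[table["condition"] == cond]
        xa = sub.loc[sub["group"] == ga, "accuracy"].to_numpy()
        xb = sub.loc[sub["group"] == gb, "accuracy"].to_numpy()
        if xa.size < 2 or xb.size < 2:
            rows.append(_stat_row("cross-condition", f"{cond}: {ga} > {gb}", xa.size + xb.size, np.nan, np.nan, "fewer than 2 observations"))
            continue
        u, p = stats.mannwhitneyu(xa, xb, alternative="greater")
        rows.append(_stat_row("cross-condition", f"{cond}: {ga} > {gb}", xa.size + xb.size, float(u), float(p)))
    report = pd.DataFrame(rows)
    if len(report):
        report["p_holm"] = np.nan
        for fam, grp in report.groupby("family"):
            ok = grp["p_raw"].notna()
            if ok.any():
                adj = multipletests(grp.loc[ok, "p_raw"], method="holm")[1]
                report.loc[grp.index[ok], "p_holm"] = adj
    return report


def _stat_row(family, test, n, stat, p, skipped=None):
    return {
        "family": family,
        "test": test,
        "n": n,
        "statistic": stat,
        "p_raw": p,
        "skipped": skipped,
    }


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
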