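"""Stacking classifier: features, folds, leakage, and group statistics."""

import numpy as np
import pandas as pd
import pytest

from oculaware.classify import (
    FoldAssignment,
    assign_folds,
    build_feature_matrix,
    classify_stimulus_vs_blank,
    eye_metric_presence,
    fit_stacked_classifier,
    group_accuracy_stats,
    holm_adjust,
    permuted_label_accuracies,
    signed_rank_test,
)
from oculaware.epochs import EpochSet


def _epochs_from_matrix(data, offsets):
    n = data.shape[0]
    meta = pd.DataFrame(
        {
            "event_class": ["white"] * n,
            "field": ["sighted"] * n,
            "block": 0,
            "event_ms": np.arange(n),
            "is_blank": False,
            "pair_id": np.arange(n),
        }
    )
    return EpochSet(
        data=data,
        offsets_ms=offsets,
        meta=meta,
        included=np.ones(n, dtype=bool),
        exclusion_reason=np.full(n, None, dtype=object),
    )


class TestFeatureMatrix:
    def test_single_bin_is_window_mean(self):
        offsets = np.arange(-100, 4101)
        data = np.tile(np.linspace(0, 1, offsets.size), (3, 1))
        ep = _epochs_from_matrix(data, offsets)
        X = build_feature_matrix(ep, feature_end_ms=4000, bin_ms=4000)
        sel = (offsets > 0) & (offsets <= 4000)
        np.testing.assert_allclose(X[:, 0], data[:, sel].mean(axis=1))
        assert X.shape == (3, 1)

    def test_constant_epoch_constant_features(self):
        offsets = np.arange(-100, 4101)
        ep = _epochs_from_matrix(np.full((2, offsets.size), 3.25), offsets)
        X = build_feature_matrix(ep)
        np.testing.assert_allclose(X, 3.25)

    def test_default_binning_gives_200_features(self):
        offsets = np.arange(-100, 4101)
        ep = _epochs_from_matrix(np.zeros((2, offsets.size)), offsets)
        assert build_feature_matrix(ep).shape == (2, 200)

    def test_bin_must_divide_window(self):
        offsets = np.arange(-100, 4101)
        ep = _epochs_from_matrix(np.zeros((2, offsets.size)), offsets)
        with pytest.raises(ValueError, match="divide"):
            build_feature_matrix(ep, feature_end_ms=4000, bin_ms=33)


class TestFolds:
    def test_pairs_share_folds_and_partition(self):
        pair_id = np.repeat(np.arange(40), 2)
        folds = assign_folds(pair_id, n_folds=10, seed=3)
        df = pd.DataFrame({"pair": pair_id, "fold": folds.fold_id})
        assert (df.groupby("pair")["fold"].nunique() == 1).all()
        counts = df.groupby("fold").size()
        assert len(counts) == 10 and counts.min() >= 2

    def test_data_independent_and_seeded(self):
        pair_id = np.repeat(np.arange(30), 2)
        a = assign_folds(pair_id, seed=5).fold_id
        b = assign_folds(pair_id, seed=5).fold_id
        c = assign_folds(pair_id, seed=6).fold_id
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


def _separable_features(rng, n_pairs=40, informative=(True, True, True), delta=3.0):
    labels = np.tile([True, False], n_pairs)
    pair_id = np.repeat(np.arange(n_pairs), 2)
    feats = {}
    for j, name in enumerate(("pupil", "blink", "microsaccade")):
        X = rng.normal(0, 1, (labels.size, 20))
        if informative[j]:
            X[labels] += delta
        feats[name] = X
    return feats, labels, pair_id


class TestStackedClassifier:
    def test_high_snr_synthetic_accuracy(self, high_snr_epoch_sets):
        res = classify_stimulus_vs_blank(
            high_snr_epoch_sets, "nontarget", "sighted", seed=7
        )
        assert res.chance == pytest.approx(0.5, abs=0.05)
        assert res.accuracy >= 0.9

    def test_permuted_labels_give_chance(self, high_snr_epoch_sets):
        # small permutation batch; the acceptance suite runs the full 200
        sets = high_snr_epoch_sets
        ref = sets["pupil"]
        keep = (
            ref.meta["event_class"].isin(["white", "glare", "nonglare", "isoluminant"])
            & (ref.meta["field"] == "sighted")
        ).to_numpy()
        sub = {m: s.subset(keep) for m, s in sets.items()}
        labels = ~sub["pupil"].meta["is_blank"].to_numpy()
        folds = assign_folds(sub["pupil"].meta["pair_id"].to_numpy(), seed=7)
        feats = {m: build_feature_matrix(s) for m, s in sub.items()}
        null = permuted_label_accuracies(feats, labels, folds, n_perm=20, seed=7)
        n = labels.size
        ci = 1.96 * np.sqrt(0.25 / n)
        assert abs(null.mean() - 0.5) < ci

    def test_stack_not_worse_than_noise_metrics(self):
        rng = np.random.default_rng(11)
        feats, labels, pair_id = _separable_features(
            rng, informative=(True, False, False)
        )
        folds = assign_folds(pair_id, seed=1)
        stacked = fit_stacked_classifier(feats, labels, folds)
        noise_accs = []
        for m in ("blink", "microsaccade"):
            solo = fit_stacked_classifier({m: feats[m]}, labels, folds)
            noise_accs.append(solo.accuracy)
        assert stacked.accuracy >= max(noise_accs)
        assert stacked.accuracy >= 0.9  # driven by the informative metric

    def test_epoch_order_shuffle_invariance(self):
        rng = np.random.default_rng(2)
        feats, labels, pair_id = _separable_features(rng, delta=1.0)
        folds = assign_folds(pair_id, seed=4)
        base = fit_stacked_classifier(feats, labels, folds)
        perm = rng.permutation(labels.size)
        feats_p = {m: X[perm] for m, X in feats.items()}
        shuffled = fit_stacked_classifier(
            feats_p, labels[perm], FoldAssignment(folds.fold_id[perm], folds.n_folds)
        )
        assert shuffled.accuracy == pytest.approx(base.accuracy)

    def test_missing_class_in_fold_errors(self):
        rng = np.random.default_rng(3)
        labels = np.array([True] * 10 + [False] * 10)
        feats = {"pupil": rng.normal(0, 1, (20, 4))}
        fold_id = np.where(labels, 1, 2)  # fold 1 training lacks stimuli
        folds = FoldAssignment(fold_id=fold_id, n_folds=2)
        with pytest.raises(ValueError, match="fold"):
            fit_stacked_classifier(feats, labels, folds)

    def test_chance_is_majority_class_proportion(self):
        rng = np.random.default_rng(8)
        feats, labels, pair_id = _separable_features(rng, n_pairs=20)
        # drop two stimulus epochs to unbalance
        keep = np.ones(labels.size, dtype=bool)
        keep[[0, 2]] = False
        folds = assign_folds(pair_id[keep], seed=0)
        res = fit_stacked_classifier(
            {m: X[keep] for m, X in feats.items()}, labels[keep], folds
        )
        assert res.chance == pytest.approx(20 / 38)

    def test_presence_criterion(self):
        null = np.linspace(0.3, 0.7, 101)
        assert eye_metric_presence(0.9, null)
        assert not eye_metric_presence(0.5, null)


class TestGroupStats:
    def test_all_equal_to_chance_not_significant(self):
        table = pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(8)],
                "condition": "left",
                "accuracy": 0.5,
                "chance": 0.5,
            }
        )
        rep = group_accuracy_stats(table, against_chance=["left"])
        assert rep.iloc[0]["p_raw"] >= 0.5

    def test_uniform_gain_exact_p(self):
        # 8 participants all chance + 0.3: one-sided exact p = 1/2^8
        table = pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(8)],
                "condition": "left",
                "accuracy": 0.8,
                "chance": 0.5,
            }
        )
        rep = group_accuracy_stats(table, against_chance=["left"])
        assert rep.iloc[0]["p_raw"] == pytest.approx(1 / 256)

    def test_holm_arithmetic(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_signed_rank_exact_matches_scipy_on_clean_data(self):
        from scipy import stats as ss

        rng = np.random.default_rng(0)
        d = rng.normal(0.2, 1, 10)
        w, p, n = signed_rank_test(d, alternative="greater")
        ref = ss.wilcoxon(d, alternative="greater", method="exact")
        assert w == pytest.approx(ref.statistic if d.sum() > 0 else w)
        assert p == pytest.approx(ref.pvalue)

    def test_paired_and_unpaired_contrasts(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            rows.append({"participant": f"p{i}", "group": "patient-aware" if i < 4 else "patient-unaware",
                         "condition": "sighted", "accuracy": 0.8 + rng.normal(0, 0.02), "chance": 0.5})
            rows.append({"participant": f"p{i}", "group": "patient-aware" if i < 4 else "patient-unaware",
                         "condition": "blind", "accuracy": (0.7 if i < 4 else 0.5) + rng.normal(0, 0.02), "chance": 0.5})
        table = pd.DataFrame(rows)
        rep = group_accuracy_stats(
            table,
            against_chance=["sighted", "blind"],
            paired_contrasts=[("sighted", "blind")],
            unpaired_contrasts=[("blind", "patient-aware", "patient-unaware")],
        )
        fams = set(rep["family"])
        assert fams == {"against-chance", "cross-condition"}
        unpaired = rep[rep["test"].str.contains("patient-aware")]
        assert unpaired.iloc[0]["p_raw"] < 0.05

    def test_too_few_observations_skipped(self):
        table = pd.DataFrame(
            {"participant": ["a"], "condition": "x", "accuracy": [0.6], "chance": [0.5]}
        )
        rep = group_accuracy_stats(table, against_chance=["x"])
        assert rep.iloc[0]["skipped"] is not None


class TestAwareVsUnawareRecovery:
    def test_blind_field_accuracy_higher_for_aware_groups(self):
        # aware-like: blind-field evoked amplitudes at 40% of sighted;
        # unaware-like: none. 4 vs 4 participants, one-sided Mann-Whitney.
        from scipy import stats as ss

        from oculaware._utils import substream
        from oculaware.config import SynthConfig
        from oculaware.epochs import combine_stimulus_and_blanks, extract_epochs, sample_blank_events
        from oculaware.preprocess import clean_pupil, detect_blinks, detect_microsaccades
        from oculaware.synth import generate_session

        def blind_accuracy(seed, gain):
            cfg = SynthConfig(
                n_blocks=2,
                trials_per_block=40,
                seed=seed,
                dilation_amp=120.0,
                constriction_amp_by_class={
                    "white": -180.0, "glare": -150.0, "nonglare": -120.0, "isoluminant": -100.0,
                },
                evoked_gain_by_field={"sighted": 1.0, "blind": gain},
                noise_sd=8.0,
            )
            s = generate_session(cfg)
            rec = s.recording
            bl = detect_blinks(rec)
            pc = clean_pupil(rec, bl)
            ms = detect_microsaccades(rec, exclude=bl)
            blanks = sample_blank_events(s.events, s.truth.block_ends_ms, substream(seed, "blanks"))
            comb = combine_stimulus_and_blanks(s.events, blanks)
            sets = {
                "pupil": extract_epochs(pc, comb, baseline=True, missing=~rec.valid),
                "blink": extract_epochs(bl, comb, missing=~rec.valid),
                "microsaccade": extract_epochs(ms, comb, missing=~rec.valid),
            }
            return classify_stimulus_vs_blank(sets, "nontarget", "blind", seed=seed).accuracy

        aware = [blind_accuracy(100 + i, 0.4) for i in range(4)]
        unaware = [blind_accuracy(200 + i, 0.0) for i in range(4)]
        _, p = ss.mannwhitneyu(aware, unaware, alternative="greater")
        assert p < 0.05
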