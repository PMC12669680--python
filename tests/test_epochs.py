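"""Epoch extraction, blank pairing, baselining, exclusion, fractions."""

import numpy as np
import pandas as pd
import pytest

from oculaware._utils import substream
from oculaware.config import RateModulation, SynthConfig
from oculaware.epochs import (
    EpochWindow,
    apply_binary_exclusion,
    apply_pupil_exclusion,
    combine_stimulus_and_blanks,
    enforce_pairing,
    extract_epochs,
    fraction_timecourse,
    sample_blank_events,
)
from oculaware.preprocess import BinaryEventTimecourse
from oculaware.synth import generate_session


def _events(onsets, cls="white", field="sighted", block=0):
    return pd.DataFrame(
        {
            "onset_ms": onsets,
            "event_class": cls,
            "field": field,
            "block": block,
        }
    )


class TestBlankSampling:
    def test_blanks_respect_interstimulus_constraints(self):
        events = _events([10000, 20000])
        rng = np.random.default_rng(0)
        times = []
        for _ in range(1000):
            blanks = sample_blank_events(events, {0: 40000}, rng)
            times.extend(
                blanks.loc[blanks["pair_id"] == 0, "onset_ms"].tolist()
            )
        times = np.array(times)
        assert times.min() >= 14000
        assert times.max() <= min(17000, 20000 - 1000)

    def test_final_blank_precedes_block_end(self):
        events = _events([5000])
        rng = np.random.default_rng(1)
        for _ in range(200):
            blanks = sample_blank_events(events, {0: 10500}, rng)
            assert (blanks["onset_ms"] < 10500).all()
            assert (blanks["onset_ms"] >= 9000).all()

    def test_impossible_blank_omitted(self):
        events = _events([5000])
        blanks = sample_blank_events(events, {0: 8500}, np.random.default_rng(0))
        assert len(blanks) == 0  # admissible interval is empty

    def test_deterministic_under_seed(self):
        events = _events([8000, 20000, 32000])
        a = sample_blank_events(events, {0: 45000}, substream(4, "blanks"))
        b = sample_blank_events(events, {0: 45000}, substream(4, "blanks"))
        pd.testing.assert_frame_equal(a, b)

    def test_blank_inherits_class_and_field(self):
        events = _events([10000], cls="glare", field="blind")
        blanks = sample_blank_events(events, {0: 30000}, np.random.default_rng(2))
        assert blanks.iloc[0]["event_class"] == "glare"
        assert blanks.iloc[0]["field"] == "blind"


class TestExtraction:
    def test_constant_trace_baselined_to_zero(self):
        trace = np.full(40000, 123.0)
        ep = extract_epochs(trace, _events([20000]), baseline=True)
        finite = ep.data[0][~np.isnan(ep.data[0])]
        np.testing.assert_allclose(finite, 0.0, atol=1e-12)

    def test_step_response(self):
        trace = np.full(40000, 10.0)
        trace[20000:] += 10.0
        ep = extract_epochs(trace, _events([20000]), baseline=True)
        offs = ep.offsets_ms
        np.testing.assert_allclose(ep.data[0][(offs >= -1000) & (offs < 0)], 0.0, atol=1e-12)
        np.testing.assert_allclose(ep.data[0][offs >= 0], 10.0, atol=1e-12)

    def test_binary_all_ones_passthrough(self):
        tc = BinaryEventTimecourse.from_intervals("blink", [(0, 40000)], 40000)
        ep = extract_epochs(tc, _events([20000]))
        assert np.all(ep.data[0] == 1.0)

    def test_binary_baseline_rejected(self):
        tc = BinaryEventTimecourse.from_intervals("blink", [], 40000)
        with pytest.raises(ValueError, match="never baselined"):
            extract_epochs(tc, _events([20000]), baseline=True)

    def test_empty_event_log(self):
        ep = extract_epochs(np.zeros(1000), _events([]))
        assert ep.n_epochs == 0

    def test_partial_epochs_padded_as_missing(self):
        ep = extract_epochs(np.ones(12000), _events([2000]))
        row = ep.data[0]
        assert np.isnan(row[:7000]).all()  # samples before recording start
        assert np.nansum(row) == 11001  # offsets -7000..+9000 covered

    def test_extraction_commutes_with_joint_time_shift(self):
        rng = np.random.default_rng(6)
        trace = rng.normal(0, 1, 50000)
        ev = _events([25000])
        a = extract_epochs(trace, ev, baseline=True)
        shifted = _events([25000 + 777])
        b = extract_epochs(trace, shifted, baseline=True, t0_ms=777)
        np.testing.assert_array_equal(a.data, b.data)

    def test_baseline_interval_mean_zero_per_epoch(self, high_snr_epoch_sets):
        ep = high_snr_epoch_sets["pupil"]
        offs = ep.offsets_ms
        base = (offs >= -1000) & (offs < 0)
        means = np.nanmean(ep.data[:, base], axis=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)


class TestExclusion:
    def test_extreme_value_boundary(self):
        window = EpochWindow(pre_ms=2000, post_ms=7000)
        trace = np.full(20000, 1000.0)
        trace[10750] = 1751.0  # inside (0, 6000] analysis range
        ep = extract_epochs(trace, _events([10000]), window)
        out = apply_pupil_exclusion(ep)
        assert not out.included[0]
        assert out.exclusion_reason[0] == "extreme"
        # exactly at the threshold: retained (rule is strictly greater)
        trace2 = trace.copy()
        trace2[10750] = 1750.0
        out2 = apply_pupil_exclusion(extract_epochs(trace2, _events([10000]), window))
        assert out2.included[0]

    def test_missing_fraction_boundary(self):
        window = EpochWindow(pre_ms=2000, post_ms=7000)
        trace = np.full(20000, 900.0)
        n_analysis = 7001  # -1000..+6000 inclusive
        missing = np.zeros(20000, dtype=bool)
        # exactly 50% missing: retained
        k = n_analysis // 2
        missing[9000 : 9000 + k] = True
        ep = extract_epochs(trace, _events([10000]), window, missing=missing)
        assert apply_pupil_exclusion(ep).included[0]
        # strictly more than 50%: excluded
        missing[9000 : 9000 + k + 2] = True
        ep2 = extract_epochs(trace, _events([10000]), window, missing=missing)
        out2 = apply_pupil_exclusion(ep2)
        assert not out2.included[0]
        assert out2.exclusion_reason[0] == "missing"

    def test_binary_exclusion_on_tracking_validity(self):
        window = EpochWindow(pre_ms=2000, post_ms=7000)
        tc = np.zeros(20000)
        missing = np.zeros(20000, dtype=bool)
        ep = extract_epochs(tc, _events([10000]), window, missing=missing)
        assert apply_binary_exclusion(ep).included[0]  # tracked throughout
        missing[8000:14000] = True  # 60% of the analysis interval untracked
        ep2 = extract_epochs(tc, _events([10000]), window, missing=missing)
        assert not apply_binary_exclusion(ep2).included[0]

    def test_literal_zero_rule_variant(self):
        window = EpochWindow(pre_ms=2000, post_ms=7000)
        tc = np.zeros(20000)  # no events at all
        ep = extract_epochs(tc, _events([10000]), window)
        out = apply_binary_exclusion(ep, literal_zero_rule=True)
        assert not out.included[0]  # the literal reading excludes event-free epochs

    def test_clean_synthetic_exclusion_below_15pct(self, high_snr_epoch_sets):
        pupil = apply_pupil_exclusion(high_snr_epoch_sets["pupil"])
        blink = apply_binary_exclusion(high_snr_epoch_sets["blink"])
        assert pupil.exclusion_fraction < 0.15
        assert blink.exclusion_fraction < 0.15


class TestPairing:
    def test_pairing_is_bijection_on_included(self, high_snr_epoch_sets):
        ep = enforce_pairing(apply_pupil_exclusion(high_snr_epoch_sets["pupil"]))
        meta = ep.meta[ep.included]
        counts = meta.groupby("pair_id")["is_blank"].agg(["size", "sum"])
        assert (counts["size"] == 2).all()
        assert (counts["sum"] == 1).all()  # one stimulus + one blank per pair

    def test_epoch_count_equals_event_count(self, high_snr_epoch_sets):
        ep = high_snr_epoch_sets["pupil"]
        assert ep.n_epochs == len(ep.meta)
        assert ep.meta["pair_id"].value_counts().eq(2).all()

    def test_partner_dropped_with_excluded_member(self):
        window = EpochWindow(pre_ms=2000, post_ms=7000)
        trace = np.full(60000, 1000.0)
        trace[10500] = 2000.0  # stimulus epoch 0 extreme
        ev = _events([10000, 30000])
        blanks = sample_blank_events(ev, {0: 60000}, np.random.default_rng(0))
        combined = combine_stimulus_and_blanks(ev, blanks)
        ep = enforce_pairing(apply_pupil_exclusion(extract_epochs(trace, combined, window)))
        meta = ep.meta
        pair0 = meta["pair_id"] == 0
        assert not ep.included[pair0.to_numpy()].any()
        assert set(ep.exclusion_reason[pair0.to_numpy()]) == {"extreme", "partner-excluded"}


class TestFractionTrace:
    def test_identical_all_ones(self):
        tc = BinaryEventTimecourse.from_intervals("blink", [(0, 50000)], 50000)
        ep = extract_epochs(tc, _events([20000, 25000]))
        tr = fraction_timecourse(ep, smooth_ms=1)
        np.testing.assert_allclose(tr.mean, 1.0)
        np.testing.assert_allclose(tr.sem, 0.0)

    def test_half_and_half(self):
        window = EpochWindow(
            pre_ms=1000, post_ms=1000, analysis_start_ms=-500,
            analysis_end_ms=500, baseline_ms=500,
        )
        tc = np.concatenate([np.zeros(10000), np.ones(10000)])
        ep = extract_epochs(tc, _events([3000, 15000]), window)
        tr = fraction_timecourse(ep, smooth_ms=1)
        np.testing.assert_allclose(tr.mean, 0.5)

    def test_no_epochs_errors(self):
        ep = extract_epochs(np.zeros(1000), _events([]))
        with pytest.raises(ValueError, match="no epochs"):
            fraction_timecourse(ep)

    def test_suppression_ratio_recovered(self):
        # microsaccades at 1.5 events/s suppressed x0.2 in [0, 0.5] s
        cfg = SynthConfig(
            n_blocks=10,
            trials_per_block=40,
            seed=21,
            blink_base_rate=0.0,
            microsaccade_base_rate=1.5,
            microsaccade_modulation=RateModulation(
                onset_mult=0.2, offset_mult=1.0
            ),
        )
        session = generate_session(cfg)
        truth_tc = BinaryEventTimecourse.from_intervals(
            "microsaccade",
            session.truth.microsaccade_intervals,
            session.recording.n_samples,
        )
        ep = extract_epochs(truth_tc, session.events)
        assert ep.n_epochs == 400
        tr = fraction_timecourse(ep, smooth_ms=1)
        offs = ep.offsets_ms
        pre = tr.mean[(offs >= -2000) & (offs < -500)].mean()
        supp = tr.mean[(offs >= 50) & (offs < 450)].mean()
        ratio = supp / pre
        assert supp < pre
        assert abs(ratio / 0.2 - 1.0) < 0.2  # injected ratio recovered within 20%
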