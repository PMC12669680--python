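"""Synthetic eye-tracking sessions with known evoked structure.

The generator emulates the visual perception task: blocks of trials with a
jittered 3-5 s fixation period, a 3 s peripheral stimulus, and a jittered
3-5 s post-stimulus period, recorded monocularly at 1000 Hz. Targets evoke
a unimodal pupil dilation; nontargets evoke a sustained, luminance-graded
pupil constriction, both only in fields with nonzero evoked gain. Blinks
and microsaccades are inhomogeneous point processes whose rates are
suppressed or enhanced in windows around stimulus onset and offset, and
blinks leave dropouts (missing samples with steep flanking artifacts) in
the pupil trace. All randomness derives from named substreams of one
master seed, so any single component can be reproduced independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import erf

from ._utils import moving_average, substream
from .config import SynthConfig
from .meg import FieldPotentialEpochSet
from .recording import RawRecording, validate_events

_AR_COEF = 0.99  # pupil noise autocorrelation at 1 ms lag
_BLINK_RAMP_MS = 30  # steep artifact on each side of a dropout
_BLINK_RAMP_DEPTH = 400.0  # recorder units
_BLINK_MEDIAN_MS = 150.0
_BLINK_LOG_SD = 0.4
# Fixational drift is slow: white noise smoothed over ~200 ms, plus a small
# white tracker-noise floor. Both chosen so intersaccadic gaze velocity stays
# near ~1 deg/s, as in head-fixed video-oculography.
_DRIFT_INNOV_SD = 0.15  # degrees, pre-smoothing
_DRIFT_SMOOTH_MS = 201
_TRACKER_NOISE_SD = 0.002  # degrees, white
_RECENTER_DEG = 0.5  # microsaccades step back toward fixation beyond this

BRIGHTNESS_STIMULI = ("glare", "nonglare", "isoluminant")
BRIGHTNESS_PAIRINGS = (
    ("glare", "nonglare"),
    ("glare", "isoluminant"),
    ("nonglare", "isoluminant"),
)


@dataclass
class SessionTruth:
    """Ground truth injected by the generator, for detector validation."""

    blink_intervals: list[tuple[int, int]]
    microsaccade_intervals: list[tuple[int, int]]
    perceived: np.ndarray  # per target event, in event-log order
    block_ends_ms: dict[int, int]


@dataclass
class Session:
    recording: RawRecording
    events: pd.DataFrame
    responses: pd.DataFrame
    truth: SessionTruth = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.recording, self.events, self.responses))


# ---------------------------------------------------------------------------
# evoked pupil kernels


def dilation_kernel(n_ms: int = 6000, peak_s: float = 1.2) -> np.ndarray:
    """Unimodal dilation transient, unit peak at ``peak_s``."""
    t = np.arange(n_ms) / 1000.0
    return (t / peak_s) * np.exp(1.0 - t / peak_s)


def constriction_kernel(n_ms: int = 6000, stim_s: float = 3.0) -> np.ndarray:
    """Sustained constriction: fast rise, hold during the stimulus, recovery."""
    t = np.arange(n_ms) / 1000.0
    rise = 1.0 - np.exp(-t / 0.35)
    recovery = np.exp(-np.maximum(t - stim_s, 0.0) / 0.8)
    return rise * recovery


# ---------------------------------------------------------------------------
# point-process helpers


def _rate_multiplier_trace(n: int, onsets: np.ndarray, modulation) -> np.ndarray:
    mult = np.ones(n)
    for t0 in onsets:
        for (w0, w1), m in (
            (modulation.onset_window_ms, modulation.onset_mult),
            (modulation.offset_window_ms, modulation.offset_mult),
        ):
            lo = int(t0 + w0)
            hi = min(int(t0 + w1), n)
            if hi > max(lo, 0):
                mult[max(lo, 0) : hi] = m
    return mult


def _thinned_events(
    rate_per_s: float,
    mult: np.ndarray,
    min_sep_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson event times (ms) by thinning, with refractoriness."""
    n = mult.size
    max_rate = rate_per_s * max(float(mult.max()), 1.0) / 1000.0  # per ms
    if max_rate <= 0:
        return np.array([], dtype=np.int64)
    n_cand = rng.poisson(max_rate * n)
    cand = np.sort(rng.uniform(0, n, size=n_cand)).astype(np.int64)
    accept = rng.uniform(size=n_cand) * max_rate < rate_per_s * mult[cand] / 1000.0
    times = cand[accept]
    kept: list[int] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep_ms:
            kept.append(int(t))
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# session generation


def _schedule(config: SynthConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    rows = []
    block_ends: dict[int, int] = {}
    cursor = 0.0
    classes = list(config.stimulus_mix)
    p_cls = np.array([config.stimulus_mix[c] for c in classes])
    fields = list(config.field_mix)
    p_fld = np.array([config.field_mix[f] for f in fields])
    for block in range(config.n_blocks):
        for _ in range(config.trials_per_block):
            pre = rng.uniform(*config.pre_stim_jitter)
            onset = cursor + pre
            post = rng.uniform(*config.post_stim_jitter)
            rows.append(
                {
                    "onset_ms": int(round(onset * 1000)),
                    "event_class": rng.choice(classes, p=p_cls),
                    "field": rng.choice(fields, p=p_fld),
                    "block": block,
                }
            )
            cursor = onset + config.stim_duration + post
        block_ends[block] = int(round(cursor * 1000))
    events = pd.DataFrame(rows)
    return validate_events(events), block_ends


def generate_session(config: SynthConfig) -> Session:
    """Generate one synthetic session (recording, event log, response log).

    Returns a :class:`Session`; it unpacks as the
    ``(recording, events, responses)`` triple, with injected ground truth
    available as ``session.truth``.
    """
    config.validate()
    events, block_ends = _schedule(config, substream(config.seed, "trials"))
    n = block_ends[config.n_blocks - 1] + 1000  # 1 s tail
    onsets = events["onset_ms"].to_numpy()

    # pupil: baseline + evoked kernels + AR(1) noise
    pupil = np.full(n, config.pupil_baseline, dtype=float)
    dil = dilation_kernel()
    con = constriction_kernel(stim_s=config.stim_duration)
    lag = int(round(config.response_latency * 1000))
    for onset, cls, fld in zip(
        onsets, events["event_class"], events["field"]
    ):
        gain = config.evoked_gain_by_field[fld]
        if gain == 0.0:
            continue
        if cls in config.target_classes:
            kern = gain * config.dilation_amp * dil
        else:
            kern = gain * config.constriction_amp_by_class.get(cls, 0.0) * con
        lo = onset + lag
        hi = min(lo + kern.size, n)
        if hi > lo:
            pupil[lo:hi] += kern[: hi - lo]
    noise_rng = substream(config.seed, "pupil_noise")
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - _AR_COEF**2)
        ar = lfilter([1.0], [1.0, -_AR_COEF], noise_rng.normal(0, innov_sd, n))
        pupil += ar + noise_rng.normal(0, 0.1 * config.noise_sd, n)

    # blinks: dropouts with flanking ramp artifacts
    blink_rng = substream(config.seed, "blinks")
    bmult = _rate_multiplier_trace(n, onsets, config.blink_modulation)
    blink_times = _thinned_events(config.blink_base_rate, bmult, 500.0, blink_rng)
    valid = np.ones(n, dtype=bool)
    blink_intervals: list[tuple[int, int]] = []
    for t in blink_times:
        dur = int(round(_BLINK_MEDIAN_MS * np.exp(blink_rng.normal(0, _BLINK_LOG_SD))))
        s, e = t, min(t + dur, n)
        if e <= s or s < _BLINK_RAMP_MS or e + _BLINK_RAMP_MS >= n:
            continue
        ramp = np.linspace(0.0, _BLINK_RAMP_DEPTH, _BLINK_RAMP_MS)
        pupil[s - _BLINK_RAMP_MS : s] -= ramp
        pupil[e : e + _BLINK_RAMP_MS] -= ramp[::-1]
        valid[s:e] = False
        blink_intervals.append((int(s), int(e)))
    pupil[~valid] = np.nan

    # gaze: smoothed fixation jitter + microsaccade steps
    gaze_rng = substream(config.seed, "gaze")
    ms_rng = substream(config.seed, "microsaccades")
    gx = moving_average(
        gaze_rng.normal(0, _DRIFT_INNOV_SD, n), _DRIFT_SMOOTH_MS
    ) + gaze_rng.normal(0, _TRACKER_NOISE_SD, n)
    gy = moving_average(
        gaze_rng.normal(0, _DRIFT_INNOV_SD, n), _DRIFT_SMOOTH_MS
    ) + gaze_rng.normal(0, _TRACKER_NOISE_SD, n)
    mmult = _rate_multiplier_trace(n, onsets, config.microsaccade_modulation)
    ms_times = _thinned_events(config.microsaccade_base_rate, mmult, 50.0, ms_rng)
    ms_intervals: list[tuple[int, int]] = []
    step_x = np.zeros(n)
    step_y = np.zeros(n)
    pos = np.zeros(2)
    for t in ms_times:
        dur = int(ms_rng.integers(2, 13))
        if t + dur >= n:
            continue
        amp = ms_rng.uniform(0.1, 1.0)
        if np.hypot(*pos) > _RECENTER_DEG:
            angle = np.arctan2(-pos[1], -pos[0]) + ms_rng.normal(0, 0.3)
        else:
            angle = ms_rng.uniform(0, 2 * np.pi)
        vec = amp * np.array([np.cos(angle), np.sin(angle)])
        # raised-cosine step: symmetric velocity profile over 2-12 ms
        profile = 0.5 * (1 - np.cos(np.pi * np.arange(1, dur + 1) / dur))
        step_x[t : t + dur] = pos[0] + vec[0] * profile
        step_y[t : t + dur] = pos[1] + vec[1] * profile
        step_x[t + dur :] = pos[0] + vec[0]
        step_y[t + dur :] = pos[1] + vec[1]
        pos = pos + vec
        ms_intervals.append((int(t), int(t + dur)))
    gx += step_x
    gy += step_y

    # responses to perceived targets
    resp_rng = substream(config.seed, "responses")
    is_target = events["event_class"].isin(config.target_classes).to_numpy()
    perceived = np.zeros(is_target.sum(), dtype=bool)
    presses = []
    for i, (onset, cls, fld) in enumerate(
        zip(
            onsets[is_target],
            events.loc[is_target, "event_class"],
            events.loc[is_target, "field"],
        )
    ):
        if resp_rng.uniform() >= config.perception_prob_by_field[fld]:
            continue
        perceived[i] = True
        rt = resp_rng.normal(config.rt_mean, config.rt_sd)
        while rt <= 0:
            rt = resp_rng.normal(config.rt_mean, config.rt_sd)
        correct_key = "plus" if cls == "target-plus" else "x"
        wrong_key = "x" if correct_key == "plus" else "plus"
        key = correct_key if resp_rng.uniform() < config.orientation_acc else wrong_key
        presses.append({"press_ms": int(onset + round(rt * 1000)), "key": key})
    responses = pd.DataFrame(presses, columns=["press_ms", "key"])
    if len(responses):
        responses = responses.sort_values("press_ms", kind="stable")
        # enforce strictly increasing press times
        t = responses["press_ms"].to_numpy().copy()
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + 1
        responses["press_ms"] = t
        responses = responses.reset_index(drop=True)

    recording = RawRecording(
        t_ms=np.arange(n, dtype=np.int64),
        pupil=pupil,
        gaze_x=gx,
        gaze_y=gy,
        valid=valid,
    )
    truth = SessionTruth(
        blink_intervals=blink_intervals,
        microsaccade_intervals=ms_intervals,
        perceived=perceived,
        block_ends_ms=block_ends,
    )
    return Session(recording, events, responses, truth)


# ---------------------------------------------------------------------------
# brightness-task responses


def generate_brightness_responses(
    weights: dict[str, float],
    n_per_pair: int,
    seed: int,
    margin: float = 0.0,
) -> pd.DataFrame:
    """Simulated two-alternative brightness judgments for the three pairings.

    ``weights`` maps each of glare/nonglare/isoluminant to a perceived
    brightness strength. The choice on each trial follows a softmax over the
    weight difference with temperature ``margin``; at ``margin == 0`` the
    higher-weight stimulus is deterministically chosen brighter (ties report
    "equal").
    """
    unknown = set(weights) - set(BRIGHTNESS_STIMULI)
    if unknown:
        raise ValueError(f"unknown stimulus identity {sorted(unknown)}")
    missing = set(BRIGHTNESS_STIMULI) - set(weights)
    if missing:
        raise ValueError(f"missing stimulus weights {sorted(missing)}")
    if n_per_pair < 1:
        raise ValueError("n_per_pair must be >= 1")
    rng = substream(seed, "brightness")
    rows = []
    for a, b in BRIGHTNESS_PAIRINGS:
        d = weights[a] - weights[b]
        for _ in range(n_per_pair):
            if margin == 0.0:
                choice = (
                    "first-brighter" if d > 0 else "second-brighter" if d < 0 else "equal"
                )
            else:
                logits = np.array([d, -d, 0.0]) / margin
                p = np.exp(logits - logits.max())
                p /= p.sum()
                choice = rng.choice(
                    ["first-brighter", "second-brighter", "equal"], p=p
                )
            rows.append({"stim_a": a, "stim_b": b, "choice": choice})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evoked field potentials


def _fp_waveform(offsets_ms: np.ndarray, amps: dict[str, float]) -> np.ndarray:
    """Evoked waveform: P1 bump near 100 ms, N2 trough in 100-225 ms,
    sustained late negativity after 250 ms. Amplitudes in fT; the N2 and LN
    amplitudes are magnitudes of negative deflections."""
    t = offsets_ms.astype(float)
    p1 = amps.get("P1", 0.0) * np.exp(-0.5 * ((t - 100.0) / 20.0) ** 2)
    n2 = -amps.get("N2", 0.0) * np.exp(-0.5 * ((t - 160.0) / 30.0) ** 2)
    ln = (
        -amps.get("LN", 0.0)
        * 0.5
        * (1.0 + erf((t - 300.0) / 70.0))
        * np.exp(-np.maximum(t - 1000.0, 0.0) / 500.0)
    )
    return p1 + n2 + ln


def generate_field_potential_epochs(
    n_per_condition: int,
    component_amps: dict[str, dict[str, float]],
    noise_sd: float,
    seed: int,
    sampling_rate: int = 1000,
) -> FieldPotentialEpochSet:
    """Pre-epoched single-sensor field potentials on the -4000..+4000 ms grid."""
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    rng = substream(seed, "field_potentials")
    step_ms = 1000.0 / sampling_rate
    offsets = np.arange(
        -4000.0, 4000.0 + 0.5 * step_ms, step_ms
    )
    data = []
    labels = []
    for cond, amps in component_amps.items():
        wave = _fp_waveform(offsets, amps)
        block = wave + rng.normal(0.0, noise_sd, size=(n_per_condition, offsets.size))
        data.append(block)
        labels.extend([cond] * n_per_condition)
    return FieldPotentialEpochSet(
        data=np.vstack(data),
        offsets_ms=offsets,
        condition=np.asarray(labels),
        sampling_rate=sampling_rate,
    )
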