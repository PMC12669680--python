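"""Session-generator configuration.

The defaults describe the trial structure of the visual perception task:
jittered 3-5 s fixation, 3 s peripheral stimulus, jittered 3-5 s
post-stimulus period, ~40 trials per block, an equal mix of two target
orientations and four nontarget stimuli, presented in two fields. Evoked
pupil amplitudes are in recorder units (pixels); rates in events/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .recording import NONTARGET_CLASSES, STIMULUS_CLASSES, TARGET_CLASSES


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


@dataclass
class RateModulation:
    """Piecewise-constant rate multipliers around stimulus onset and offset.

    The base event rate is multiplied by ``onset_mult`` in the window
    ``onset_window_ms`` after stimulus onset and by ``offset_mult`` in
    ``offset_window_ms``; elsewhere the multiplier is 1.
    """

    onset_mult: float = 1.0
    offset_mult: float = 1.0
    onset_window_ms: tuple[float, float] = (0.0, 500.0)
    offset_window_ms: tuple[float, float] = (3000.0, 3500.0)

    def multiplier(self, dt_ms: float) -> float:
        if self.onset_window_ms[0] <= dt_ms < self.onset_window_ms[1]:
            return self.onset_mult
        if self.offset_window_ms[0] <= dt_ms < self.offset_window_ms[1]:
            return self.offset_mult
        return 1.0

    @property
    def max_mult(self) -> float:
        return max(self.onset_mult, self.offset_mult, 1.0)


def _equal_mix(keys) -> dict[str, float]:
    return {k: 1.0 / len(keys) for k in keys}


@dataclass
class SynthConfig:
    """Parameters of a synthetic eye-tracking session."""

    sampling_rate: int = 1000  # samples/s; the analysis assumes a 1-ms grid
    n_blocks: int = 2
    trials_per_block: int = 40
    pre_stim_jitter: tuple[float, float] = (3.0, 5.0)  # s
    stim_duration: float = 3.0  # s
    post_stim_jitter: tuple[float, float] = (3.0, 5.0)  # s
    stimulus_mix: dict[str, float] = field(
        default_factory=lambda: _equal_mix(STIMULUS_CLASSES)
    )
    field_mix: dict[str, float] = field(
        default_factory=lambda: {"sighted": 0.5, "blind": 0.5}
    )
    pupil_baseline: float = 1000.0  # recorder units
    dilation_amp: float = 60.0  # target-evoked, recorder units
    constriction_amp_by_class: dict[str, float] = field(
        default_factory=lambda: {
            "white": -90.0,
            "glare": -60.0,
            "nonglare": -30.0,
            "isoluminant": -10.0,
        }
    )
    # Per-field scaling of every evoked pupil kernel: 1 in a responsive
    # (sighted) field, 0 in a fully unresponsive blind field.
    evoked_gain_by_field: dict[str, float] = field(
        default_factory=lambda: {"sighted": 1.0, "blind": 0.0}
    )
    response_latency: float = 0.2  # s, kernel onset lag
    blink_base_rate: float = 0.25  # events/s
    microsaccade_base_rate: float = 1.5  # events/s
    blink_modulation: RateModulation = field(
        default_factory=lambda: RateModulation(onset_mult=0.2, offset_mult=2.0)
    )
    microsaccade_modulation: RateModulation = field(
        default_factory=lambda: RateModulation(onset_mult=0.2, offset_mult=0.5)
    )
    perception_prob_by_field: dict[str, float] = field(
        default_factory=lambda: {"sighted": 0.95, "blind": 0.05}
    )
    orientation_acc: float = 0.9  # probability a perceived target's key is correct
    rt_mean: float = 0.9  # s
    rt_sd: float = 0.25  # s
    noise_sd: float = 10.0  # stationary SD of the AR(1) pupil noise
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate != 1000:
            raise ConfigError("sampling_rate: only 1000 Hz (1-ms grid) supported")
        for name in ("n_blocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        for name in ("pre_stim_jitter", "post_stim_jitter"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ConfigError(f"{name}: requires 0 <= lower <= upper")
        for name, mix in (
            ("stimulus_mix", self.stimulus_mix),
            ("field_mix", self.field_mix),
        ):
            if any(v < 0 for v in mix.values()):
                raise ConfigError(f"{name}: proportions must be nonnegative")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name}: proportions must sum to 1")
        unknown = set(self.stimulus_mix) - set(STIMULUS_CLASSES)
        if unknown:
            raise ConfigError(f"stimulus_mix: unknown classes {sorted(unknown)}")
        for name in (
            "stim_duration",
            "blink_base_rate",
            "microsaccade_base_rate",
            "rt_mean",
            "rt_sd",
            "noise_sd",
            "response_latency",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be nonnegative")
        for fld, p in self.perception_prob_by_field.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"perception_prob_by_field[{fld}]: not in [0, 1]")
        if not 0.0 <= self.orientation_acc <= 1.0:
            raise ConfigError("orientation_acc: not in [0, 1]")
        for fld in self.field_mix:
            if fld not in self.perception_prob_by_field:
                raise ConfigError(f"perception_prob_by_field: missing field {fld!r}")
            if fld not in self.evoked_gain_by_field:
                raise ConfigError(f"evoked_gain_by_field: missing field {fld!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, RateModulation):
                return {
                    "onset_mult": v.onset_mult,
                    "offset_mult": v.offset_mult,
                    "onset_window_ms": list(v.onset_window_ms),
                    "offset_window_ms": list(v.offset_window_ms),
                }
            if isinstance(v, tuple):
                return list(v)
            return v

        return {k: plain(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        for key in ("pre_stim_jitter", "post_stim_jitter"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("blink_modulation", "microsaccade_modulation"):
            if key in d and isinstance(d[key], Mapping):
                m = dict(d[key])
                for w in ("onset_window_ms", "offset_window_ms"):
                    if w in m:
                        m[w] = tuple(m[w])
                d[key] = RateModulation(**m)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def target_classes(self) -> tuple[str, ...]:
        return TARGET_CLASSES

    @property
    def nontarget_classes(self) -> tuple[str, ...]:
        return NONTARGET_CLASSES
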