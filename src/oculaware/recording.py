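"""Core containers for monocular eye-tracker sessions.

A session is a uniformly sampled (1000 Hz) monocular recording of pupil
diameter (recorder units / pixels) and gaze position (degrees of visual
angle), together with an event log of stimulus presentations and a response
log of keypresses. Pupil samples are missing (NaN) wherever the tracker lost
the eye, typically during blinks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["onset_ms", "event_class", "field", "block"]
RESPONSE_COLUMNS = ["press_ms", "key"]

STIMULUS_CLASSES = (
    "target-plus",
    "target-x",
    "white",
    "glare",
    "nonglare",
    "isoluminant",
)
TARGET_CLASSES = ("target-plus", "target-x")
NONTARGET_CLASSES = ("white", "glare", "nonglare", "isoluminant")


@dataclass
class RawRecording:
    """Uniformly sampled monocular pupil + gaze timeseries.

    Attributes
    ----------
    t_ms : int array, strictly increasing 1-ms grid
    pupil : float array, recorder units; NaN exactly where ``valid`` is False
    gaze_x, gaze_y : float arrays, degrees of visual angle
    valid : bool array, per-sample tracking validity
    """

    t_ms: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.int64)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.size
        for name in ("pupil", "gaze_x", "gaze_y", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match time grid")
        if n >= 2 and not np.all(np.diff(self.t_ms) == 1):
            raise ValueError("time grid must increase in constant 1-ms steps")
        if not np.array_equal(np.isnan(self.pupil), ~self.valid):
            raise ValueError("pupil must be missing exactly where valid is False")

    @property
    def n_samples(self) -> int:
        return int(self.t_ms.size)

    @property
    def t0_ms(self) -> int:
        return int(self.t_ms[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "pupil": self.pupil,
                "gaze_x": self.gaze_x,
                "gaze_y": self.gaze_y,
                "valid": self.valid.astype(int),
            }
        )


def write_samples(recording: RawRecording, path: str | Path) -> None:
    """Write the sample log as tab-separated text with a one-line header."""
    recording.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_samples(path: str | Path) -> RawRecording:
    df = pd.read_csv(path, sep="\t")
    valid = df["valid"].astype(int).to_numpy().astype(bool)
    pupil = df["pupil"].to_numpy(dtype=float)
    pupil[~valid] = np.nan
    return RawRecording(
        t_ms=df["t_ms"].to_numpy(),
        pupil=pupil,
        gaze_x=df["gaze_x"].to_numpy(dtype=float),
        gaze_y=df["gaze_y"].to_numpy(dtype=float),
        valid=valid,
    )


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event log missing columns {missing}")
    for _, grp in events.groupby("block"):
        if not grp["onset_ms"].is_monotonic_increasing:
            raise ValueError("event onsets must increase within a block")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path))


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response log missing columns {missing}")
    return df
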