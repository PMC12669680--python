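"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from oculaware._utils import substream
from oculaware.config import SynthConfig
from oculaware.epochs import (
    combine_stimulus_and_blanks,
    extract_epochs,
    sample_blank_events,
)
from oculaware.preprocess import clean_pupil, detect_blinks, detect_microsaccades
from oculaware.synth import generate_session


@pytest.fixture(scope="session")
def small_session():
    """One 20-trial block with the default (study-shaped) parameters."""
    return generate_session(SynthConfig(n_blocks=1, trials_per_block=20, seed=1))


@pytest.fixture(scope="session")
def high_snr_session():
    """Two 40-trial blocks with doubled evoked amplitudes and a responsive
    single field, for classifier recovery tests."""
    cfg = SynthConfig(
        n_blocks=2,
        trials_per_block=40,
        seed=7,
        dilation_amp=120.0,
        constriction_amp_by_class={
            "white": -180.0,
            "glare": -150.0,
            "nonglare": -120.0,
            "isoluminant": -100.0,
        },
        field_mix={"sighted": 1.0, "blind": 0.0},
        noise_sd=8.0,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def high_snr_epoch_sets(high_snr_session):
    """Pupil/blink/microsaccade epoch sets for the high-SNR session."""
    session = high_snr_session
    rec = session.recording
    blinks = detect_blinks(rec)
    pupil = clean_pupil(rec, blinks)
    msacc = detect_microsaccades(rec, exclude=blinks)
    blanks = sample_blank_events(
        session.events, session.truth.block_ends_ms, substream(7, "blanks")
    )
    combined = combine_stimulus_and_blanks(session.events, blanks)
    missing = ~rec.valid
    return {
        "pupil": extract_epochs(pupil, combined, baseline=True, missing=missing),
        "blink": extract_epochs(blinks, combined, missing=missing),
        "microsaccade": extract_epochs(msacc, combined, missing=missing),
    }


def flat_recording(n=20000, baseline=1000.0):
    """Constant-pupil, constant-gaze recording helper."""
    from oculaware.recording import RawRecording

    return RawRecording(
        t_ms=np.arange(n),
        pupil=np.full(n, baseline),
        gaze_x=np.zeros(n),
        gaze_y=np.zeros(n),
        valid=np.ones(n, dtype=bool),
    )
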