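import numpy as np
import pytest

from pulselock import MusicSpec, build_wavelet_bank, complex_onset_detect, gen_music, run_bank


@pytest.fixture(scope="session")
def click2hz():
    """2 Hz burst train, 60 s, with its onset signal and oscillator run."""
    music = gen_music(MusicSpec(pulse_freq=2.0, duration=60.0, meter=2), seed=1)
    onset = complex_onset_detect(music.audio)
    run = run_bank(onset)
    return {"music": music, "onset": onset, "run": run}


@pytest.fixture(scope="session")
def bank250():
    return build_wavelet_bank(fs=250.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
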