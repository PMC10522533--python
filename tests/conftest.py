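import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

# keep hypothesis scratch (example db, constants cache) out of the repo
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hyp_"))
settings.register_profile("fpas", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("fpas")

from fpas.audio import Waveform, apply_ramps, rms_equalize
from fpas.sequences import SequenceSpec, StimulusSet, synthesize_stimulus_set
from fpas.simulate import SimulationSpec

RATE = 8000


@pytest.fixture(scope="session")
def stimulus_set() -> StimulusSet:
    """The full 84-sound synthetic vocalization set."""
    return synthesize_stimulus_set(seed=0, rate=RATE)


@pytest.fixture(scope="session")
def scrambled_set(stimulus_set) -> StimulusSet:
    return stimulus_set.scrambled(seed=1)


@pytest.fixture(scope="session")
def seq_spec() -> SequenceSpec:
    return SequenceSpec(seed=3)


def harmonic_complex(f0: float = 150.0, n_harmonics: int = 5,
                     rate: int = RATE, duration: float = 0.350,
                     rms: float = 0.1) -> Waveform:
    """Equal-amplitude harmonic stack, RMS-equalized and ramped."""
    t = np.arange(int(round(duration * rate))) / rate
    x = sum(np.sin(2 * np.pi * f0 * k * t) for k in range(1, n_harmonics + 1))
    return apply_ramps(rms_equalize(Waveform(x, rate), rms))


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec(seed=0)
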