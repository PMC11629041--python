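import numpy as np
import pytest

from plantargait import (
    GaitCycle,
    WaveformParams,
    default_layout,
    generate_recording,
)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def zero_noise_params():
    return WaveformParams(cycle_jitter_sd=0.0, left_right_asymmetry=0.0,
                          n_cycles=55, seed=3)


@pytest.fixture(scope="session")
def zero_noise_recording(zero_noise_params, layout):
    return generate_recording(zero_noise_params, layout=layout,
                              body_weight=60.0, participant_id="Z000")


@pytest.fixture(scope="session")
def jittered_recording(layout):
    params = WaveformParams(cycle_jitter_sd=0.04, left_right_asymmetry=0.06,
                            n_cycles=58, seed=11)
    return generate_recording(params, layout=layout, body_weight=65.0,
                              participant_id="J000")


@pytest.fixture
def random_cycle_factory():
    """Random valid gait cycles for brute-force feature oracles."""

    def make(rng: np.random.Generator, n: int = 24) -> GaitCycle:
        stance_end = int(0.7 * n)
        channels = np.zeros((n, 8))
        channels[:stance_end] = rng.uniform(0.01, 0.3, size=(stance_end, 8))
        p1 = rng.integers(2, stance_end // 2 - 1)
        p2 = rng.integers(stance_end // 2 + 1, stance_end - 2)
        valley = rng.integers(p1, p2 + 1)
        return GaitCycle(foot="left", heel_strike=0, peak1=int(p1),
                         valley=int(valley), peak2=int(p2),
                         toe_off=stance_end, cycle_end=n, channels=channels)

    return make
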