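import numpy as np
import pytest

from tapsync import core, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iso_metronome():
    return synth.generate_metronome("isochronous", 500.0, n_beats=100)


@pytest.fixture
def perfect_trial(iso_metronome):
    """Taps exactly on every beat."""
    taps = core.TapSequence(iso_metronome.onsets.copy())
    return core.match_taps_to_beats(iso_metronome, taps)


@pytest.fixture
def noisy_trial(iso_metronome, rng):
    params = synth.TapperParams(
        alpha=0.4, sigma_T=20.0, sigma_M=8.0, mean_asynchrony=-30.0
    )
    taps, _ = synth.simulate_tapper(iso_metronome, params, rng=rng)
    return core.match_taps_to_beats(iso_metronome, taps)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three-group cohort, 3 participants per group, iso + one switch step."""
    spec = synth.default_cohort_spec(
        conditions=("iso", "step90"), master_seed=7, n_con=3, n_dys=3, n_asd=3
    )
    return synth.make_cohort(spec)
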