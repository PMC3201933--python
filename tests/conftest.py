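import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from strepnet.interaction_data import InteractionExperiment, SignedMatrix
from strepnet.synthetic import (
    ExperimentSimParams,
    density_fixture,
    motif_fixture,
    q_asymmetry_fixture,
    synthetic_experiment,
)


@pytest.fixture
def q_fixture() -> SignedMatrix:
    return q_asymmetry_fixture()


@pytest.fixture
def dens_fixture() -> SignedMatrix:
    return density_fixture()


@pytest.fixture
def mot_fixture() -> SignedMatrix:
    return motif_fixture()


def make_experiment(times, control, aerial=None, n_rep=2, grains=None,
                    seqs=None, quals=None):
    """Build a small experiment from per-entry true times (inf = complete)."""
    times = np.asarray(times, dtype=float)
    k = times.shape[0]
    t = np.repeat(times[:, :, None], n_rep, axis=2)
    ctrl = np.repeat(np.asarray(control, dtype=float)[:, None], 2, axis=1)
    aerial = np.zeros((k, k)) if aerial is None else np.asarray(aerial, dtype=float)
    names = [f"i{j}" for j in range(k)]
    return InteractionExperiment(
        isolates=names,
        appearance_time=t,
        control_time=ctrl,
        aerial_inhibited=aerial,
        grain_of=grains or ["g1"] * k,
        seq16s=seqs or [],
        qual_mask=quals or [],
    )


@pytest.fixture(scope="session")
def noisefree_experiment():
    """Deterministic noise-free synthetic experiment with its ground truth."""
    sp = ExperimentSimParams(K=20, G=3, L=20, seq_len=80, clonal_duplicates=2,
                             noise_sd=0.0, missing_rate=0.0, seed=11)
    return synthetic_experiment(sp)


@pytest.fixture(scope="session")
def default_experiment():
    """One synthetic experiment at the default study conditions (K=64)."""
    return synthetic_experiment(ExperimentSimParams(seed=5))
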