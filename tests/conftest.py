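import numpy as np
import pytest

from consfold import (
    BundleSpec,
    PerturbSpec,
    make_bundle,
    make_rapdf_training,
    perturb_ensemble,
    train_rapdf,
)
from consfold.modelbuild import train_torsion_prior


@pytest.fixture(scope="session")
def toy_bundle():
    """Three-helix bundle, 38 residues."""
    return make_bundle(BundleSpec(n_helices=3, residues_per_helix=10,
                                  loop_length=4, packing_radius=8.0,
                                  antiparallel=True, seed=2))


@pytest.fixture(scope="session")
def hairpin():
    """Two-helix hairpin, 29 residues."""
    return make_bundle(BundleSpec(n_helices=2, residues_per_helix=12,
                                  loop_length=5, packing_radius=7.0,
                                  antiparallel=True, seed=0))


@pytest.fixture(scope="session")
def corpus():
    return make_rapdf_training(8, seed=1)


@pytest.fixture(scope="session")
def rapdf_table(corpus):
    return train_rapdf(corpus)


@pytest.fixture(scope="session")
def torsion_prior(corpus):
    return train_torsion_prior(corpus)


@pytest.fixture(scope="session")
def perturbed(toy_bundle):
    """Five server-model stand-ins at ~2 A from the toy bundle."""
    return perturb_ensemble(toy_bundle, PerturbSpec(target_rmsd=2.0,
                                                    n_models=5, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
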