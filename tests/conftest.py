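import numpy as np
import pytest

from potdecomp import (
    DILL,
    ContactMatrix,
    GroundTruth,
    OneBodyScale,
    build_basis,
    datasets,
    generate_matrix,
)


@pytest.fixture(scope="session")
def mj():
    return datasets.mj_matrix()


@pytest.fixture(scope="session")
def dill_basis(mj):
    return build_basis(DILL, mj.labels)


@pytest.fixture(scope="session")
def scales():
    return datasets.table2_scales()


@pytest.fixture(scope="session")
def mj_q_truth(scales):
    """A gauge-satisfying one-body truth taken from the bundled MJ fitted scale."""
    return scales["mj_q"]


def make_truth(q: OneBodyScale, noise_sd=0.0, seed=0, classification=DILL):
    return GroundTruth(
        eta_hh=2.0,
        eta_hp=1.0,
        eta_hb=1.5,
        eta0=0.5,
        q=q,
        classification=classification,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture()
def noiseless_matrix(mj_q_truth):
    truth = make_truth(mj_q_truth)
    matrix, truth = generate_matrix(truth)
    return matrix, truth


@pytest.fixture()
def toy3():
    """A hand-sized 3-residue matrix (A hydrophobic, R/N hydrophilic)."""
    values = np.array(
        [
            [-2.0, -1.0, -0.5],
            [-1.0, 0.5, 1.0],
            [-0.5, 1.0, 1.5],
        ]
    )
    return ContactMatrix(("A", "R", "N"), values, name="toy3")
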