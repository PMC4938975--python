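import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metaregulon.motifs import BindingSiteCollection, ScoreModel, build_matrix
from metaregulon.simulate import background_pool, surrogate_motif


@pytest.fixture(scope="session")
def toy_sites() -> BindingSiteCollection:
    """Tiny hand-checkable site collection (width 4)."""
    return BindingSiteCollection(("ACGT", "ACGA", "ACGT", "TCGT"), "toy")


@pytest.fixture(scope="session")
def toy_matrix(toy_sites):
    return build_matrix(toy_sites, pseudocount=1.0)


@pytest.fixture(scope="session")
def default_motif():
    """The default informative surrogate motif (width 16, cons. 0.85)."""
    return surrogate_motif(random_state=np.random.default_rng(20160708))


@pytest.fixture(scope="session")
def default_pool():
    """Background promoter pool (300 bp, 40% G+C) for model fitting."""
    return background_pool(300, random_state=np.random.default_rng(401))


@pytest.fixture(scope="session")
def fitted_model(default_motif, default_pool):
    from metaregulon.motifs import fit_score_model

    matrix = build_matrix(default_motif)
    return matrix, fit_score_model(matrix, default_motif, default_pool)


@pytest.fixture(scope="session")
def simple_model() -> ScoreModel:
    """Analytically convenient score model."""
    return ScoreModel(mu_g=0.0, sigma_g=1.0, mu_m=10.0, sigma_m=2.0,
                      alpha=1.0 / 300.0)
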