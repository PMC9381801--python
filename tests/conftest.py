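import numpy as np
import pytest

from spmixcopula import (
    CopulaModel,
    FieldSpec,
    MixtureCopula,
    SpatialMixtureCopula,
    fit_marginal,
    simulate_bivariate_field,
)
from spmixcopula.geometry import BinningScheme, Pairs, bin_pairs


@pytest.fixture(scope="session")
def small_field():
    """One modest simulated bivariate field shared across tests."""
    return simulate_bivariate_field(FieldSpec(n=250, seed=11))


def binning_from_distances(distances, cutoff, n_bins) -> BinningScheme:
    """Binning whose per-bin mean distances are exactly the given values
    (one synthetic pair per bin)."""
    distances = np.asarray(distances, dtype=float)
    k = distances.size
    pairs = Pairs(np.arange(k), np.arange(k) + k, distances)
    return bin_pairs(pairs, cutoff, n_bins)


@pytest.fixture
def independence_model():
    """A single-bin spatial model whose copula is pure independence, with
    normal marginals fitted to fixed samples — every prediction quantity
    then has a closed form."""
    rng = np.random.default_rng(5)
    z1 = rng.normal(2.0, 0.7, 200)
    z2 = rng.normal(-1.0, 1.3, 200)
    marg = [fit_marginal(z1, "normal"), fit_marginal(z2, "normal")]
    binning = binning_from_distances([50.0], 100.0, 1)
    mixtures = [MixtureCopula([CopulaModel("independence"), CopulaModel("independence")],
                              [0.5, 0.5])]
    model = SpatialMixtureCopula(binning=binning, bin_mixtures=mixtures, lambdas=[],
                                 marginals=marg, weights=np.array([0.5, 0.5]),
                                 names=["z1", "z2"])
    return model, z1, z2
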