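"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from couplemr import (
    CausalEdge,
    CoupleModelParams,
    TraitNetworkParams,
    TraitParams,
    simulate_couple_cohort,
    simulate_trait_network,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Direct trait assortment only: r_X=0.2, h2=0.2, no violations."""
    params = CoupleModelParams(n_couples=20_000, n_snps=50, r_X=0.2, seed=11)
    return simulate_couple_cohort(params)


@pytest.fixture(scope="session")
def violation_cohort():
    """Moderate environmental assortment plus parental effects."""
    params = CoupleModelParams(
        n_couples=20_000, n_snps=50, r_X=0.15, r_E=0.1, r_G=0.05,
        s_G=0.05, s_E=0.1, s_X=0.1, seed=12,
    )
    return simulate_couple_cohort(params)


@pytest.fixture(scope="session")
def confounder_cohort():
    """Couple similarity in X arising only through an assorted confounder Y."""
    params = TraitNetworkParams(
        n_couples=50_000,
        traits={
            "X": TraitParams(n_snps=60, h2=0.2, r_assort=0.0),
            "Y": TraitParams(n_snps=60, h2=0.2, r_assort=0.4),
        },
        edges=(CausalEdge("Y", "X", 0.5),),
        seed=13,
    )
    return simulate_trait_network(params)


@pytest.fixture(scope="session")
def exposure_assortment_cohort():
    """Cross-trait design: X assorted, within-person X -> Y, no Y assortment."""
    params = TraitNetworkParams(
        n_couples=50_000,
        traits={
            "X": TraitParams(n_snps=60, h2=0.2, r_assort=0.2),
            "Y": TraitParams(n_snps=60, h2=0.2, r_assort=0.0),
        },
        edges=(CausalEdge("X", "Y", 0.3),),
        seed=14,
    )
    return simulate_trait_network(params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
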