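"""Shared fixtures.

The expensive parameter-recovery fits are session-scoped and reused by both
the unit tests and the acceptance tests, so each study condition is simulated
and fitted exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import duelfit as dfit


@pytest.fixture(scope="session")
def small_pedigree() -> dfit.Pedigree:
    """Five animals: two founders, two full sibs, one full-sib-mating offspring."""
    return dfit.Pedigree(
        pd.DataFrame(
            {
                "animal": ["A", "B", "C", "D", "E"],
                "sire": ["0", "0", "A", "A", "C"],
                "dam": ["0", "0", "B", "B", "D"],
                "birth_year": [2000, 2000, 2001, 2001, 2002],
            }
        )
    )


@pytest.fixture(scope="session")
def random_pedigree() -> dfit.Pedigree:
    return dfit.simulate_pedigree(8, 3, offspring_per_pair=2.5, seed=42)


# --------------------------------------------------------------------------
# study conditions: dominance data generated under the exact dyadic-symmetry
# constraint (sigma2_a = 0.15, mirrored Pe = 0.10, no herd variance — the
# constrained-analysis protocol), ~20,000 duels over a ~3,800-animal,
# 14-generation pedigree with ~1,800 contestants
# --------------------------------------------------------------------------
@pytest.fixture(scope="session")
def constrained_study() -> dfit.SimulatedDataset:
    params = dfit.TrueParameters(herd_cov=np.zeros((3, 3)), n_herds=40)
    return dfit.simulate_study(params, seed=11)


@pytest.fixture(scope="session")
def unconstrained_fit(constrained_study) -> dfit.GibbsResults:
    model = dfit.DominanceThresholdModel(
        constrained_study.contests, constrained_study.pedigree, include_herd=False
    )
    return model.fit(iterations=10_000, burn_in=3_000, thin=7, seed=5)


@pytest.fixture(scope="session")
def constrained_fit(constrained_study) -> dfit.GibbsResults:
    model = dfit.DominanceThresholdModel(
        constrained_study.contests, constrained_study.pedigree,
        constrained=True, include_herd=False,
    )
    return model.fit(iterations=6_000, burn_in=2_000, thin=4, seed=5)


# --------------------------------------------------------------------------
# bivariate study: dominance under the constraint plus a milk-yield-like
# linear trait (h2 = 0.224) genetically correlated +0.35 with the direct and
# -0.35 with the indirect dominance component; ~20,000 duels + 5,000 records
# --------------------------------------------------------------------------
@pytest.fixture(scope="session")
def bivariate_study() -> dfit.SimulatedDataset:
    params = dfit.TrueParameters(
        G=dfit.constrained_block(0.15, 0.224, r_trait_direct=0.35)
    )
    return dfit.simulate_study(params, seed=13)


@pytest.fixture(scope="session")
def bivariate_fit(bivariate_study) -> dfit.GibbsResults:
    model = dfit.BivariateThresholdLinearModel(
        bivariate_study.contests, bivariate_study.trait_records,
        bivariate_study.pedigree, trait_model="pe_herd_htd",
    )
    return model.fit(iterations=6_000, burn_in=2_000, thin=4, seed=7)
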