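import numpy as np
import pytest

from trophospec import (
    CovariateTable,
    DietMatrix,
    PreyTaxon,
    load_table1_fixture,
    paper_scenario,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def autumn_scenario():
    """One fixed synthetic autumn population (diet, covariates, availability)."""
    return paper_scenario("autumn", seed=42)


def make_diet(counts, season=None, ids=None, taxa=None):
    counts = np.asarray(counts)
    n, t = counts.shape
    ids = ids or [f"s{i}" for i in range(n)]
    taxa = taxa or [PreyTaxon(f"T{j}") for j in range(t)]
    return DietMatrix(ids, taxa, counts, season=season)


def make_covariates(diet, rng=None, svl=None, mass=None):
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    n = diet.n_individuals
    if svl is None:
        svl = rng.normal(40.0, 3.0, n)
    if mass is None:
        mass = 1.4e-5 * svl**3 * np.exp(rng.normal(0, 0.05, n))
    return CovariateTable(
        pd.DataFrame(
            {
                "id": diet.individuals,
                "sex": np.where(rng.random(n) < 0.6, "M", "F"),
                "season": diet.season or "autumn",
                "site": "site1",
                "svl": svl,
                "total_length": svl * 2.2,
                "body_mass": mass,
            }
        )
    )


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
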