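import numpy as np
import pytest

import rerandsim as rs


@pytest.fixture(scope="session")
def worked_example():
    """The fixed 100-patient, 3-centers-by-smoking example allocation."""
    return rs.example_allocation()


@pytest.fixture()
def two_cov_schema():
    return rs.CovariateSchema(
        (("center", ("1", "2")), ("sex", ("M", "F"))),
    )


def make_population(values, arms=None, schema=None, n_arms=2):
    """Build a small population from a list of per-patient covariate dicts."""
    if schema is None:
        names = list(values[0])
        levels = {n: tuple(sorted({v[n] for v in values})) for n in names}
        schema = rs.CovariateSchema(tuple((n, levels[n]) for n in names))
    patients = tuple(
        (f"p{i}", v, None, arms[i] if arms else None) for i, v in enumerate(values)
    )
    return rs.TrialPopulation(schema, patients, n_arms)


def allocation_from_arms(population, arms):
    return rs.AllocationResult(
        arm_of={pid: arm for pid, arm in zip(population.ids, arms)},
        method="SPBR",
        parameters={},
        seed=0,
        inclusion_order=population.ids,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
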