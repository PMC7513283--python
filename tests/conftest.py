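import numpy as np
import pytest

from psnet.ontology import compute_ic
from psnet.synthetic import SyntheticConfig, make_three_series_example, simulate_cohort


@pytest.fixture(scope="session")
def worked_example():
    """The three-series worked example: (hpo_dag, go_dag, corpus)."""
    return make_three_series_example()


@pytest.fixture(scope="session")
def example_ic(worked_example):
    """Clinical IC table computed from the worked example's disease corpus."""
    hpo, _, corpus = worked_example
    return compute_ic(hpo, {d.omim_id: d.hpo_terms for d in corpus.diseases.values()})


@pytest.fixture(scope="session")
def cohort():
    """A default-condition synthetic cohort, fixed seed."""
    return simulate_cohort(SyntheticConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
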