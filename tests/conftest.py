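import numpy as np
import pytest

from bimodalseed import expression, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.small()


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A 300-gene synthetic cohort with planted sites and its truth."""
    utrs, truth = simulate.gen_utrs(small_config, seed=42)
    return utrs, truth


@pytest.fixture(scope="session")
def small_records(small_config, small_cohort):
    """Differential-expression records for the small cohort."""
    _, truth = small_cohort
    matrix = simulate.gen_expression(truth, small_config, seed=42)
    return expression.per_gene_stats(matrix, simulate.group_labels(small_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
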