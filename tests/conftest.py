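import numpy as np
import pytest

from methconcord import SimulationConfig
from methconcord.synthetic_data import (simulate_expression_study,
                                        simulate_interactome,
                                        simulate_methylation_study)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same design (8 subjects, 3 cell types + ES,
    2 iPS clones, triplicate passages), fewer probes."""
    return SimulationConfig(n_probes=2000, interactome_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_methylation_study(small_config)


@pytest.fixture(scope="session")
def small_full_fixture(small_config, small_study):
    beta, sheet, truth = small_study
    expr, expr_sheet, truth = simulate_expression_study(small_config, truth)
    graph, seeds = simulate_interactome(small_config, truth)
    return {"beta": beta, "sheet": sheet, "truth": truth, "expr": expr,
            "expr_sheet": expr_sheet, "graph": graph, "seeds": seeds,
            "config": small_config}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
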