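import numpy as np
import pytest

from mspkit import ParamRegistry
from mspkit import simulate as sim


@pytest.fixture
def registry() -> ParamRegistry:
    return ParamRegistry()


@pytest.fixture
def wt_counts(registry):
    return sim.gen_ts_counts(registry.p_wt, registry.K, registry.n_wt, seed=11,
                             genotype="wild_type")


@pytest.fixture
def expression_table(registry):
    mis = [f"gene{i:05d}" for i in range(registry.n_misregulated)]
    return sim.gen_expression_table(2000, mis, registry.effect_log2fc,
                                    registry.log2fc_sd, seed=11), mis


@pytest.fixture
def planted_gene_map():
    return sim.gen_gene_map(20_000_000, 400, 120,
                            [(14_900_000, 15_100_000, 40)], seed=11)
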