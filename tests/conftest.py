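import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from mitocomp import (  # noqa: E402
    MitoSimSpec,
    default_feature_table,
    mutate_genotype_pair,
    simulate_mitogenome,
)


@pytest.fixture(scope="session")
def sim_genome():
    """Default synthetic mitogenome and its feature table (seed 1)."""
    return simulate_mitogenome(MitoSimSpec(seed=1))


@pytest.fixture(scope="session")
def genotype_pair(sim_genome):
    """The default genome plus a derived genotype: 10 coding substitutions,
    6 control-region substitutions, 9 control-region indels."""
    g1, t1 = sim_genome
    g2, t2 = mutate_genotype_pair(
        g1, t1, n_cds_subs=10, n_cr_subs=6, n_cr_indels=9, seed=7
    )
    return (g1, t1), (g2, t2)


@pytest.fixture(scope="session")
def template_table():
    return default_feature_table()
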