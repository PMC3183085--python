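import numpy as np
import pytest

from teflank import (
    GenomicInterval,
    PlantedGene,
    SimulationConfig,
    TEInsertion,
    simulate_cohort,
)


def make_insertion(
    chrom="chr1",
    start=100_000,
    end=105_000,
    strand="+",
    copy_id="copyX",
    status="polymorphic",
    present_in=("lineA",),
    family="IAP",
):
    return TEInsertion(
        interval=GenomicInterval(chrom, start, end, strand),
        family=family,
        copy_id=copy_id,
        status=status,
        present_in=frozenset(present_in),
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_len_bp=600_000,
        n_common_copies=8,
        n_polymorphic_copies=8,
        n_genes=10,
        planted_impact_genes=(PlantedGene(tss_distance=368, silencing_fold=4.0),),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
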