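import numpy as np
import pytest

from tesim.genome import GenomeArchitecture


@pytest.fixture
def small_arch():
    """Two 50-kb chromosomes, 5-kb clusters, 10% paramutable, 3% trigger sites."""
    return GenomeArchitecture(
        chrom_lengths=(50_000, 50_000),
        cluster_lengths=(5_000, 5_000),
        recomb_rates=(4.0, 4.0),
        para_period=10,
        para_count=1,
        trig_period=100,
        trig_count=3,
    )


@pytest.fixture
def clusterless_arch():
    """One chromosome, no clusters, 10% paramutable loci."""
    return GenomeArchitecture(
        chrom_lengths=(100_000,),
        cluster_lengths=(0,),
        recomb_rates=(4.0,),
        para_period=10,
        para_count=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
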