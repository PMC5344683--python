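import pytest

from crackit.align import Aligner
from crackit.synthetic import SimConfig, make_genome


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=7, n_transcripts=24, reads_per_sample=800)


@pytest.fixture(scope="session")
def sim(sim_cfg):
    return make_genome(sim_cfg)


@pytest.fixture(scope="session")
def aligner(sim):
    return Aligner(sim.seqs)
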