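import pytest

from postkit.config import PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_sim():
    """A small simulated dataset shared across integration-style tests."""
    from postkit import simdata

    contigs, links, truth = simdata.simulate_transcriptome(n_genes=12, rng_seed=11)
    return contigs, links, truth
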