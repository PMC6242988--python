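import pytest

from euglenakit.simulate import SimParams, generate_transcriptome


@pytest.fixture(scope="session")
def default_sim_1000():
    """Default-condition simulation (n=1000, seed=42), shared across tests."""
    params = SimParams(seed=42, n_transcripts=1000)
    contigs, truths = generate_transcriptome(params)
    return params, contigs, truths


@pytest.fixture(scope="session")
def untruncated_sim_300():
    """Noiseless, untruncated simulation for CDS-recovery checks."""
    params = SimParams(seed=7, n_transcripts=300, truncation_prob=0.0)
    contigs, truths = generate_transcriptome(params)
    return params, contigs, truths
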