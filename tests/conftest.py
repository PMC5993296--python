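import numpy as np
import pytest

from aims_architect.synthetic import AimsPlant, GenomeSpec, generate_genome

PLANTED_PATTERNS = ["ACGGTCAT", "TTGCAACG"]


@pytest.fixture(scope="session")
def planted_genome():
    """A 300 kb synthetic genome with two planted gradient octamers."""
    spec = GenomeSpec(
        length=300_000,
        n_genes=300,
        mean_codons=150,
        aims_plants=[
            AimsPlant(p, copies=150, p_ter=0.95, p_ori=0.75, density_ratio=2.0)
            for p in PLANTED_PATTERNS
        ],
        genome_id="fix",
    )
    return generate_genome(spec, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
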