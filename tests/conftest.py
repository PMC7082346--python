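import numpy as np
import pandas as pd
import pytest

from virocell import synthetic


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">g\nATGC\n")
    return p


@pytest.fixture
def two_contig_fasta(tmp_path):
    p = tmp_path / "two.fasta"
    p.write_text(">c1 first\nATGAAATAG\n>c2 second\nGGCC\n")
    return p


@pytest.fixture
def synth_genome_pair():
    """A host and a diverged phage with known shifted codons (seeded)."""
    spec = synthetic.GenomeSimSpec(seed=11)
    host = synthetic.synth_host(spec)[:2]
    phage, cds, truth = synthetic.synth_phage_from_host(
        spec, delta=0.3, seed=1011, host=host
    )
    return host, (phage, cds), truth


@pytest.fixture
def small_counts():
    """A tiny two-stratum count matrix with complete metadata."""
    genes = ["h1", "h2", "p1"]
    samples = ["u_t0_r1", "u_t0_r2", "i_t0_r1", "i_t0_r2"]
    values = pd.DataFrame(
        [[100, 200, 50, 60], [300, 400, 70, 80], [0, 0, 500, 600]],
        index=genes,
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "treatment": ["uninfected", "uninfected", "HP1", "HP1"],
            "time_min": [0, 0, 0, 0],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    ann = pd.DataFrame(
        {"length_bp": [1000, 2000, 500], "stratum": ["host", "host", "phage"]},
        index=pd.Index(genes, name="gene_id"),
    )
    return values, meta, ann


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
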