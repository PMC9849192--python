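import textwrap
from pathlib import Path

import numpy as np
import pytest

from macnv.genome_model import GenomeIndex, load_genome
from macnv.synthetic_data import GenomeConfig, generate_genome


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a FASTA from {name: sequence} and return its path."""

    def _write(records: dict[str, str], wrap: int = 60, name: str = "test.fa") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_name, seq in records.items():
                fh.write(f">{rec_name}\n")
                fh.write(textwrap.fill(seq, wrap) + "\n")
        return path

    return _write


@pytest.fixture
def small_genome(fasta_factory):
    """Deterministic random two-chromosome genome (20 kb + 10 kb)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = {
        "chrA": "".join(rng.choice(bases, 20_000)),
        "chrB": "".join(rng.choice(bases, 10_000)),
    }
    return load_genome(fasta_factory(seqs)), seqs


@pytest.fixture(scope="session")
def toy_experiment_genome(tmp_path_factory):
    """Session-scoped synthetic genome used by the heavier pipeline tests."""
    outdir = tmp_path_factory.mktemp("toygenome")
    cfg = GenomeConfig(n_chroms=4, chrom_length=150_000)
    genome, genes = generate_genome(cfg, outdir, seed=11)
    return cfg, genome, genes
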