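import numpy as np
import pytest

from cisgram.core_io import GeneModel, Genome, Peak
from cisgram.synthetic import (
    SyntheticConfig,
    generate_genome,
    plant_peaks,
    simulate_expression,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-config synthetic bundle (genome, genes, peaks, truth)."""
    cfg = SyntheticConfig(seed=42)
    genome, genes = generate_genome(cfg)
    peaks, genome, truth = plant_peaks(cfg, genome, genes)
    return cfg, genome, genes, peaks, truth


@pytest.fixture(scope="session")
def expression_bundle():
    """Standalone 2000-gene expression simulation (counts, design, truth)."""
    cfg = SyntheticConfig(seed=42, n_genes=2000)
    counts, design, truth = simulate_expression(cfg)
    return cfg, counts, design, truth


def random_instance(rng, n_peaks, n_genes, n_contigs=3, contig_len=300_000):
    """A random peaks/genes instance for oracle-equivalence checks."""
    contigs = [f"c{i}" for i in range(n_contigs)]
    genes = []
    for j in range(n_genes):
        contig = contigs[int(rng.integers(n_contigs))]
        start = int(rng.integers(0, contig_len - 5000))
        end = start + int(rng.integers(500, 5000))
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(GeneModel(f"g{j:04d}", contig, strand, start, end))
    peaks = []
    for i in range(n_peaks):
        contig = contigs[int(rng.integers(n_contigs))]
        start = int(rng.integers(0, contig_len + 4000))
        width = int(rng.integers(100, 500))
        summit = start + int(rng.integers(width))
        peaks.append(
            Peak(f"p{i:04d}", "TF", contig, start, start + width, summit,
                 float(rng.random()))
        )
    return peaks, genes
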