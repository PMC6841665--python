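import numpy as np
import pytest

from tic.genome_model import GeneModel


@pytest.fixture
def plus_pair():
    """Tandem + strand pair: A terminates 2 kb upstream of B's TSS."""
    a = GeneModel("A", "chr1", "+", tss=2000, tts=10000)
    b = GeneModel("B", "chr1", "+", tss=12000, tts=20000)
    return [a, b]


@pytest.fixture
def minus_pair():
    """Tandem - strand pair: C terminates 2 kb upstream of D's TSS."""
    c = GeneModel("C", "chr1", "-", tss=40000, tts=30000)
    d = GeneModel("D", "chr1", "-", tss=28000, tts=20000)
    return [c, d]


def random_gene_layout(rng: np.random.Generator, n: int, n_chrom: int = 2,
                       span: int = 2_000_000) -> list[GeneModel]:
    """Non-overlapping random genes on both strands for oracle tests."""
    genes = []
    per_chrom = n // n_chrom + 1
    gi = 0
    for ci in range(n_chrom):
        cursor = int(rng.integers(0, 5000))
        for _ in range(per_chrom):
            if gi >= n:
                break
            L = int(rng.integers(500, 8000))
            gap = int(rng.integers(0, 6000))
            strand = "+" if rng.random() < 0.5 else "-"
            x = cursor + gap
            if strand == "+":
                g = GeneModel(f"g{gi:04d}", f"chr{ci+1}", "+", x, x + L)
            else:
                g = GeneModel(f"g{gi:04d}", f"chr{ci+1}", "-", tss=x + L - 1, tts=x)
            genes.append(g)
            cursor = x + L
            gi += 1
    return genes
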