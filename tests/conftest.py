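import io

import numpy as np
import pytest

from bdgcoex import ExpressionMatrix, GeneModel


def make_gene(gene_id, strand, tss, chrom="chr1", length=1000):
    """GeneModel helper with a span consistent with strand and TSS."""
    if strand == "+":
        start, end = tss, tss + length - 1
    else:
        start, end = tss - length + 1, tss
    return GeneModel(
        gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand,
        tss=tss, span_start=start, span_end=end,
    )


def random_genes(rng, n, n_chroms=3, span=200_000):
    """Random gene set for brute-force comparisons."""
    genes = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(5_000, span))
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        genes.append(make_gene(f"G{i:04d}", strand, tss, chrom=chrom))
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_counts(rng):
    """A small random counts matrix (20 genes x 15 cells, no zero cells)."""
    values = rng.poisson(5.0, size=(20, 15)).astype(float)
    values[0] += 1  # guarantee no zero-total cell
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{j}" for j in range(15)],
    )


def gtf_stream(text):
    return io.StringIO(text)
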