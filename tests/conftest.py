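import numpy as np
import pytest

from cretarget.genomic_core import GeneModel, GenomicInterval
from cretarget.synthetic_data import StudyConfig, generate


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study shared by read-only tests."""
    return generate(StudyConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id, chrom, strand, start, exon_spans):
    """Gene model from (start,end) exon pairs; TSS derived from strand."""
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans)
    lo = min(s for s, _ in exon_spans)
    hi = max(e for _, e in exon_spans)
    tss = lo if strand == "+" else hi - 1
    return GeneModel(gene_id, chrom, strand, tss, exons)


@pytest.fixture()
def simple_genes():
    """Two genes on chr1: g_plus TSS 10000 (+), g_minus TSS 29999 (-)."""
    return [
        make_gene("g_plus", "chr1", "+", 10_000, [(10_000, 10_500), (12_000, 13_000)]),
        make_gene("g_minus", "chr1", "-", 27_000, [(27_000, 27_800), (29_000, 30_000)]),
    ]


# ---------------------------------------------------------------------------
# brute-force per-base interval oracle
# ---------------------------------------------------------------------------


def base_mask(ivs, chrom, length):
    mask = np.zeros(length, dtype=bool)
    for iv in ivs:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def mask_to_runs(mask, chrom):
    """Maximal True runs of a boolean mask as (chrom, start, end) tuples."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(chrom, int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def oracle_intersect(a, b, chroms, length):
    runs = []
    for chrom in sorted(chroms):
        runs.extend(
            mask_to_runs(
                base_mask(a, chrom, length) & base_mask(b, chrom, length), chrom
            )
        )
    return runs


def random_intervals(rng, n, chroms, length, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, length - 1))
        end = start + 1 + int(rng.integers(0, max_len))
        out.append(GenomicInterval(chrom, start, min(end, length)))
    return out
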