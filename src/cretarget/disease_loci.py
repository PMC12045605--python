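"""Disease-locus cross-referencing and enrichment.

Disease loci (e.g. OMIM-derived deafness loci) arrive as coordinate spans
with an optional causative gene. Loci are split into resolved (causative
gene known) and unresolved; unresolved loci are extended by a small flank,
all genes overlapping the extended loci form the in-locus gene set, and
candidate target genes are cross-referenced against it. Enrichment is the
upper-tail hypergeometric probability (Fisher's exact one-tailed test):
with N universe genes of which K lie in unresolved loci, drawing the n
targets, P(X >= k) for the k targets observed in loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .genomic_core import ChromSizes, GeneModel, GenomicInterval, overlaps, slop

logger = logging.getLogger(__name__)

DEFAULT_LOCUS_FLANK = 100
DEFAULT_ENRICH_ALPHA = 0.1


@dataclass(frozen=True)
class DiseaseLocus:
    """A named genomic span linked to a phenotype; resolved iff a causative
    gene is recorded."""

    locus_id: str
    interval: GenomicInterval
    causative_gene: str | None = None
    phenotype: str = ""

    @property
    def resolved(self) -> bool:
        return self.causative_gene is not None


@dataclass(frozen=True)
class EnrichmentResult:
    k: int  # targets in unresolved loci
    n: int  # total targets
    K: int  # universe genes in unresolved loci
    N: int  # universe size
    p_value: float
    alpha: float
    significant: bool


@dataclass(frozen=True)
class CrossrefReport:
    targets_in_loci: tuple[str, ...]
    k: int
    n: int
    percent: int  # round(100 k / n) to nearest integer


def partition_loci(
    loci: Iterable[DiseaseLocus],
) -> tuple[list[DiseaseLocus], list[DiseaseLocus]]:
    """Split into (resolved, unresolved) by causative-gene presence."""
    resolved = [l for l in loci if l.resolved]
    unresolved = [l for l in loci if not l.resolved]
    logger.info(
        "partition_loci: %d resolved / %d unresolved", len(resolved), len(unresolved)
    )
    return resolved, unresolved


def genes_in_loci(
    genes: Sequence[GeneModel],
    loci: Sequence[DiseaseLocus],
    flank: int = DEFAULT_LOCUS_FLANK,
    sizes: ChromSizes | None = None,
) -> set[str]:
    """Gene ids whose span overlaps (>= 1 bp) any flank-extended locus."""
    if sizes is None:
        # clamp only at the origin when no size table is supplied
        bound = max(
            [l.interval.end + flank for l in loci]
            + [g.gene_span.end for g in genes],
            default=1,
        )
        chroms = {l.interval.chrom for l in loci} | {g.chrom for g in genes}
        sizes = ChromSizes({c: bound for c in chroms})
    extended = slop([l.interval for l in loci], flank, sizes)
    return {
        g.gene_id
        for g in genes
        if any(overlaps(g.gene_span, iv) for iv in extended)
    }


def map_orthologs(source_genes: Iterable[str], mapping: pd.DataFrame) -> set[str]:
    """Map gene ids through a (source_id, target_id) ortholog table.

    Returns the unique target ids of mapped sources; sources with no mapping
    row are logged by id (dropping some is expected) and omitted.
    """
    for col in ("source_id", "target_id"):
        if col not in mapping.columns:
            raise ValueError(f"ortholog table lacks column {col!r}")
    by_source: dict[str, set[str]] = {}
    for src, tgt in zip(mapping["source_id"], mapping["target_id"]):
        by_source.setdefault(str(src), set()).add(str(tgt))
    out: set[str] = set()
    unmapped = []
    for g in sorted(set(source_genes)):
        if g in by_source:
            out |= by_source[g]
        else:
            unmapped.append(g)
    if unmapped:
        logger.info(
            "map_orthologs: %d source genes without ortholog: %s",
            len(unmapped),
            ",".join(unmapped),
        )
    return out


def fisher_enrichment(
    k: int, n: int, K: int, N: int, alpha: float = DEFAULT_ENRICH_ALPHA
) -> EnrichmentResult:
    """One-tailed enrichment p-value, X ~ Hypergeometric(N, K, n), P(X >= k)."""
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent counts k={k}, n={n}, K={K}, N={N}: "
            "require 0 <= k <= min(n, K), n <= N, K <= N"
        )
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, math.ulp(0.0)), 1.0)
    return EnrichmentResult(k, n, K, N, p, alpha, significant=p <= alpha)


def crossref_targets(
    targets: Iterable[str], in_loci: Iterable[str]
) -> CrossrefReport:
    """Which targets fall in (unresolved) disease loci, with count and
    nearest-integer percentage."""
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    hit = tuple(sorted(targets & set(in_loci)))
    k, n = len(hit), len(targets)
    percent = math.floor(100 * k / n + 0.5)  # round half up, matches reporting
    return CrossrefReport(hit, k, n, percent)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_disease_loci(path: str | Path) -> list[DiseaseLocus]:
    """Read the locus TSV (locus_id, chrom, start, end, causative_gene,
    phenotype); empty/'.' causative_gene means unresolved."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("locus_id", "chrom", "start", "end")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: locus table lacks column {col!r}")
    loci = []
    for row in df.itertuples(index=False):
        causative = getattr(row, "causative_gene", "")
        loci.append(
            DiseaseLocus(
                locus_id=row.locus_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                causative_gene=causative if causative not in ("", ".") else None,
                phenotype=getattr(row, "phenotype", ""),
            )
        )
    return loci


def write_disease_loci(loci: Iterable[DiseaseLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tcausative_gene\tphenotype\n")
        for l in sorted(loci, key=lambda l: (l.interval.chrom, l.interval.start)):
            causative = l.causative_gene if l.causative_gene else "."
            fh.write(
                f"{l.locus_id}\t{l.interval.chrom}\t{l.interval.start}\t"
                f"{l.interval.end}\t{causative}\t{l.phenotype}\n"
            )


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source_id", "target_id"]:
        df.columns = ["source_id", "target_id"] + list(df.columns[2:])
    return df


def write_enrichment_report(
    report: CrossrefReport, enrichment: EnrichmentResult, path: str | Path
) -> None:
    """JSON summary of the cross-reference and the enrichment test."""
    import json

    payload = {
        "k": enrichment.k,
        "n": enrichment.n,
        "K": enrichment.K,
        "N": enrichment.N,
        "p_value": enrichment.p_value,
        "alpha": enrichment.alpha,
        "significant": enrichment.significant,
        "percent_targets_in_loci": report.percent,
        "targets_in_loci": list(report.targets_in_loci),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
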