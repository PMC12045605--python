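"""Putative transcription-factor target identification.

Composes the upstream stages into the full pipeline:

1. active enhancers = ATAC peaks intersected with H3K27Ac peaks, with
   promoter- and exon-overlapping fragments removed;
2. expression-enriched genes by fold-change and FPKM thresholds;
3. each active enhancer is scanned for motif occurrences (any of the
   supplied matrices, exact-p-value threshold) and soft-assigned to every
   TSS within a distance window;
4. a gene is called a putative target iff it is expression-enriched and
   receives at least one motif-bearing enhancer.

Intersection fragments are the countable cis-regulatory-element (CRE) unit;
each gets a stable id ``chrom:start-end``. A CRE assigned to several
enriched genes supports all of them but is counted once in ``n_cres``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enhancer_annotation import (
    DEFAULT_ASSIGNMENT_WINDOW,
    DEFAULT_PROMOTER_WINDOW,
    CREAssignment,
    assign_to_tss,
    filter_enhancers,
)
from .genomic_core import (
    GeneModel,
    GenomicInterval,
    fetch_sequence,
    intersect,
    read_fasta,
)
from .motif_scan import DEFAULT_P_THRESHOLD, PWM, scan_multi

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetCall:
    """One putative target gene with its supporting enhancers."""

    gene_id: str
    supporting_cres: tuple[tuple[GenomicInterval, int, int], ...]  # (cre, dist, n hits)
    n_motif_hits: int


def active_enhancers(
    atac: Iterable[GenomicInterval],
    h3k27ac: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[GenomicInterval]:
    """ATAC/H3K27Ac intersection fragments that are not promoter/exon peaks.

    Intersection precedes classification, so a fragment falling inside an
    exon is removed even if its parent peaks extend beyond it. Surviving
    fragments carry a stable ``chrom:start-end`` id in ``name``.
    """
    atac = list(atac)
    h3k27ac = list(h3k27ac)
    if not atac or not h3k27ac:
        logger.warning("active_enhancers: empty input peak set; no active enhancers")
        return []
    fragments = intersect(atac, h3k27ac)
    kept = filter_enhancers(fragments, genes, promoter_window)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=str(iv)) for iv in kept
    ]


def enriched_genes(
    expr: pd.DataFrame, fc_min: float = 2.0, fpkm_min: float = 10.0
) -> set[str]:
    """Genes with fold_change > fc_min AND fpkm > fpkm_min (both strict).

    ``expr`` needs columns gene_id, fold_change, fpkm, one row per gene.
    """
    for col in ("gene_id", "fold_change", "fpkm"):
        if col not in expr.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if expr["gene_id"].duplicated().any():
        dup = expr.loc[expr["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in expression table: {dup!r}")
    mask = (expr["fold_change"] > fc_min) & (expr["fpkm"] > fpkm_min)
    return set(expr.loc[mask, "gene_id"])


def call_targets(
    cres: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expr: pd.DataFrame,
    pwms: Sequence[PWM],
    genome_fasta: str | Path | Mapping[str, str],
    window: int = DEFAULT_ASSIGNMENT_WINDOW,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_min: float = 2.0,
    fpkm_min: float = 10.0,
) -> tuple[list[TargetCall], list[CREAssignment], dict]:
    """Call putative target genes from active enhancers.

    Returns (target calls sorted by gene_id, motif-bearing CRE assignments,
    summary dict with n_genes and n_cres). ``genome_fasta`` may be a FASTA
    path or an in-memory {chrom: sequence} mapping. A CRE outside the FASTA
    bounds is an error naming the CRE.
    """
    genome = (
        genome_fasta
        if isinstance(genome_fasta, Mapping)
        else read_fasta(genome_fasta)
    )
    enriched = enriched_genes(expr, fc_min, fpkm_min)

    motif_cres: list[CREAssignment] = []
    for cre in sorted(cres, key=lambda c: (c.chrom, c.start, c.end)):
        seq = fetch_sequence(genome, cre)
        hits = scan_multi(
            seq, pwms, p_threshold, sequence_id=cre.name or str(cre)
        )
        if not hits:
            continue
        assignment = assign_to_tss(cre, genes, window)
        if assignment is None:
            continue
        assignment.motif_hits = hits
        motif_cres.append(assignment)

    per_gene: dict[str, list[tuple[GenomicInterval, int, int]]] = {}
    supporting_ids: set[str] = set()
    for asn in motif_cres:
        for gene_id, dist in asn.assigned_genes:
            if gene_id in enriched:
                per_gene.setdefault(gene_id, []).append(
                    (asn.cre, dist, len(asn.motif_hits))
                )
                supporting_ids.add(str(asn.cre))

    calls = [
        TargetCall(
            gene_id=g,
            supporting_cres=tuple(sorted(sup, key=lambda s: (s[0], s[1]))),
            n_motif_hits=sum(n for _, _, n in sup),
        )
        for g, sup in sorted(per_gene.items())
    ]
    summary = {"n_genes": len(calls), "n_cres": len(supporting_ids)}
    return calls, motif_cres, summary


def run_target_pipeline(
    atac: Iterable[GenomicInterval],
    h3k27ac: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    expr: pd.DataFrame,
    pwms: Sequence[PWM],
    genome_fasta: str | Path | Mapping[str, str],
    window: int = DEFAULT_ASSIGNMENT_WINDOW,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    fc_min: float = 2.0,
    fpkm_min: float = 10.0,
) -> tuple[list[TargetCall], list[CREAssignment], dict]:
    """End-to-end: peak intersection -> filtering -> scanning -> calling."""
    cres = active_enhancers(atac, h3k27ac, genes, promoter_window)
    calls, motif_cres, summary = call_targets(
        cres, genes, expr, pwms, genome_fasta, window, p_threshold, fc_min, fpkm_min
    )
    summary["n_active_enhancers"] = len(cres)
    return calls, motif_cres, summary


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_targets_table(calls: Iterable[TargetCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_cres\tn_hits\tcres\n")
        for call in sorted(calls, key=lambda c: c.gene_id):
            cre_list = ",".join(str(cre) for cre, _, _ in call.supporting_cres)
            fh.write(
                f"{call.gene_id}\t{len(call.supporting_cres)}\t"
                f"{call.n_motif_hits}\t{cre_list}\n"
            )


def write_cre_table(assignments: Iterable[CREAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cre_id\tgene_id\tdistance\tn_hits\n")
        for asn in sorted(assignments, key=lambda a: a.cre):
            cre_id = asn.cre.name or str(asn.cre)
            for gene_id, dist in asn.assigned_genes:
                fh.write(f"{cre_id}\t{gene_id}\t{dist}\t{len(asn.motif_hits)}\n")
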