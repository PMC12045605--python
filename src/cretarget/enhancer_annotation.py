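"""Peak classification against gene models and soft enhancer-to-TSS assignment.

Peaks are classified into a single category by the fixed priority
promoter > exon > intron > intergenic, where "promoter" means overlap with
[TSS - promoter_window, TSS + promoter_window). Candidate enhancers (intron
or intergenic peaks) are then soft-assigned to *every* gene whose TSS lies
within a distance window of the peak midpoint, allowing many-to-many
enhancer-gene links.

Distances are signed: positive when the TSS lies downstream (at a greater
genome coordinate) of the peak midpoint, independent of gene strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .genomic_core import GeneModel, GenomicInterval, overlaps

logger = logging.getLogger(__name__)

CATEGORIES = ("promoter", "exon", "intron", "intergenic")

DEFAULT_PROMOTER_WINDOW = 1000
DEFAULT_ASSIGNMENT_WINDOW = 35_000


@dataclass(frozen=True)
class PeakAnnotation:
    peak: GenomicInterval
    category: str
    nearest_tss_gene: str | None
    nearest_tss_distance: int | None


@dataclass
class CREAssignment:
    """A candidate enhancer linked to >= 1 gene, plus its motif hits."""

    cre: GenomicInterval
    assigned_genes: list[tuple[str, int]]  # (gene_id, signed distance bp)
    motif_hits: list = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.assigned_genes]


def _promoter_span(gene: GeneModel, promoter_window: int) -> GenomicInterval:
    return GenomicInterval(
        gene.chrom,
        max(0, gene.tss - promoter_window),
        gene.tss + promoter_window,
    )


def signed_tss_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    """TSS position minus peak midpoint (positive = TSS downstream)."""
    return gene.tss - peak.midpoint


def classify_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> PeakAnnotation:
    """Classify one peak by the priority promoter > exon > intron > intergenic.

    The nearest-TSS gene (minimal absolute midpoint distance, ties broken by
    gene_id) is reported regardless of category. An empty gene set yields
    category "intergenic" with a logged warning.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be positive")
    if not genes:
        logger.warning("classify_peak: empty gene set; peak %s -> intergenic", peak)
        return PeakAnnotation(peak, "intergenic", None, None)
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    category = "intergenic"
    if any(overlaps(peak, _promoter_span(g, promoter_window)) for g in same_chrom):
        category = "promoter"
    elif any(overlaps(peak, ex) for g in same_chrom for ex in g.exons):
        category = "exon"
    elif any(overlaps(peak, g.gene_span) for g in same_chrom):
        category = "intron"
    candidates = same_chrom if same_chrom else None
    if candidates is None:
        return PeakAnnotation(peak, category, None, None)
    nearest = min(
        candidates, key=lambda g: (abs(signed_tss_distance(peak, g)), g.gene_id)
    )
    return PeakAnnotation(
        peak, category, nearest.gene_id, signed_tss_distance(peak, nearest)
    )


def filter_enhancers(
    peaks: Iterable[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[GenomicInterval]:
    """Keep only peaks classified intron or intergenic (candidate enhancers)."""
    return [
        p
        for p in peaks
        if classify_peak(p, genes, promoter_window).category in ("intron", "intergenic")
    ]


def assign_to_tss(
    cre: GenomicInterval,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_ASSIGNMENT_WINDOW,
) -> CREAssignment | None:
    """Soft-assign a candidate enhancer to all TSSs within ``window`` bp.

    Distance is measured from the CRE midpoint to each TSS and the window is
    inclusive (|distance| <= window). Returns None when no TSS qualifies.
    Assigned genes are sorted by (|distance|, gene_id).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    assigned = []
    for g in genes:
        if g.chrom != cre.chrom:
            continue
        d = signed_tss_distance(cre, g)
        if abs(d) <= window:
            assigned.append((g.gene_id, d))
    if not assigned:
        return None
    assigned.sort(key=lambda gd: (abs(gd[1]), gd[0]))
    return CREAssignment(cre=cre, assigned_genes=assigned)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_annotation_table(
    annotations: Iterable[PeakAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tnearest_tss_gene\tnearest_tss_distance\n")
        for a in sorted(annotations, key=lambda a: a.peak):
            gene = a.nearest_tss_gene if a.nearest_tss_gene is not None else "."
            dist = a.nearest_tss_distance if a.nearest_tss_distance is not None else "."
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
                f"{a.category}\t{gene}\t{dist}\n"
            )


def write_assignment_table(
    assignments: Iterable[CREAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cre_id\tgene_id\tdistance\n")
        for asn in sorted(assignments, key=lambda a: a.cre):
            cre_id = asn.cre.name or str(asn.cre)
            for gene_id, dist in asn.assigned_genes:
                fh.write(f"{cre_id}\t{gene_id}\t{dist}\n")
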