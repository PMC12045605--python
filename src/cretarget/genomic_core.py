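"""Coordinate conventions, interval algebra and flat-file I/O.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted on read. Strand is one of ``+``, ``-``, ``.`` and
is ignored by all overlap logic. Outputs are sorted by
(chromosome lexicographic, start, end) so runs are diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A non-empty half-open span [start, end) on a named chromosome.

    Sort order is (chrom, start, end), i.e. the deterministic output order
    used throughout the package.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("interval coordinates must be integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (empty intervals are rejected)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # stable id used for CREs
        return f"{self.chrom}:{self.start}-{self.end}"


class ChromSizes(dict):
    """Mapping chromosome name -> length (bp); lengths strictly positive."""

    def __init__(self, sizes: Mapping[str, int] = ()):
        super().__init__()
        for chrom, length in dict(sizes).items():
            self[chrom] = length

    def __setitem__(self, chrom: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__setitem__(chrom, int(length))

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self[iv.chrom]:
            raise ValueError(
                f"interval {iv} exceeds chromosome length {self[iv.chrom]}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS, exon structure and overall span.

    The TSS sits at gene_span.start on the + strand and at gene_span.end - 1
    on the - strand; exons must be non-overlapping and on the gene's
    chromosome.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exs = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exs)
        for ex in exs:
            if ex.chrom != self.chrom:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} not on chromosome {self.chrom}"
                )
        for a, b in zip(exs, exs[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons {a} / {b}")
        span = self.gene_span
        expected = span.start if self.strand == "+" else span.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} inconsistent with "
                f"{self.strand} strand span {span} (expected {expected})"
            )

    @property
    def gene_span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
            name=self.gene_id,
        )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 base (same chromosome, strand-blind)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def sort_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse a set into maximal non-overlapping runs per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(ivs):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base overlap of two interval sets, as maximal half-open runs.

    Both sets are first merged per chromosome, then swept jointly; the result
    is sorted by (chrom, start, end). Each output interval is contained in at
    least one interval of ``a`` and one of ``b``. If the two sets share no
    chromosome names a diagnostic is logged and the result is empty.
    """
    a_merged = merge_intervals(a)
    b_merged = merge_intervals(b)
    a_chroms = {iv.chrom for iv in a_merged}
    b_chroms = {iv.chrom for iv in b_merged}
    if a_merged and b_merged and not (a_chroms & b_chroms):
        logger.warning(
            "intersect: no shared chromosome names between inputs "
            "(a: %s; b: %s) -- returning empty result",
            sorted(a_chroms),
            sorted(b_chroms),
        )
        return []
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(a_chroms & b_chroms):
        xs = [iv for iv in a_merged if iv.chrom == chrom]
        ys = by_chrom_b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def slop(
    loci: Iterable[GenomicInterval], flank: int, sizes: ChromSizes
) -> list[GenomicInterval]:
    """Extend every interval by ``flank`` bp on both sides, clamped to
    [0, chromosome length]."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    out = []
    for iv in loci:
        if iv.chrom not in sizes:
            raise KeyError(f"unknown chromosome {iv.chrom!r} in chromosome sizes")
        out.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - flank),
                min(sizes[iv.chrom], iv.end + flank),
                iv.strand,
                iv.name,
                iv.score,
            )
        )
    return sort_intervals(out)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; track/browser/comment lines are skipped.

    Malformed lines (non-integer or empty coordinates, < 3 columns) raise
    with the offending line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = (
                float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            )
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(ivs: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name/score as '.' when unset), sorted."""
    with open(path, "w") as fh:
        for iv in sort_intervals(ivs):
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome sizes and FASTA
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    sizes = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load an entire FASTA into memory as {name: uppercase sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    """Extract the interval's sequence; errors if it falls outside the FASTA."""
    if iv.chrom not in genome:
        raise KeyError(f"interval {iv}: chromosome not in genome FASTA")
    seq = genome[iv.chrom]
    if iv.end > len(seq):
        raise ValueError(
            f"interval {iv} extends past end of {iv.chrom} (length {len(seq)})"
        )
    return seq[iv.start : iv.end]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def _model_from_exons(
    gene_id: str, chrom: str, strand: str, exons: Sequence[GenomicInterval]
) -> GeneModel:
    start = min(e.start for e in exons)
    end = max(e.end for e in exons)
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id, chrom, strand, tss, tuple(exons))


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF or the minimal 6-column TSV dialect.

    The TSV dialect has columns (gene_id, chrom, strand, tss, exon_starts,
    exon_ends) with comma-separated exon coordinate lists; files whose name
    ends in .gtf or .gff are parsed as GTF (1-based closed, converted).
    Duplicate gene ids and exons outside the gene span are errors.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path)
    return _read_gene_tsv(path)


def _read_gene_tsv(path: Path) -> list[GeneModel]:
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "gene_id":
                continue  # header
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            gene_id, chrom, strand, tss_s, starts_s, ends_s = fields[:6]
            if gene_id in models:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
            starts = [int(x) for x in starts_s.split(",") if x]
            ends = [int(x) for x in ends_s.split(",") if x]
            if len(starts) != len(ends):
                raise ValueError(
                    f"{path}: line {lineno}: exon_starts/exon_ends length mismatch"
                )
            exons = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            )
            model = _model_from_exons(gene_id, chrom, strand, exons)
            if tss_s not in ("", "."):
                tss = int(tss_s)
                if tss != model.tss:
                    raise ValueError(
                        f"{path}: line {lineno}: stated TSS {tss} inconsistent "
                        f"with strand/exon span (expected {model.tss})"
                    )
            models[gene_id] = model
    return list(models.values())


def _read_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    seen: set[str] = set()
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        exon_spans: list[GenomicInterval] = []
        for exon in db.features_of_type("exon"):
            if exon.attributes.get("gene_id", [None])[0] == gene_id:
                # GTF is 1-based closed; convert to 0-based half-open
                exon_spans.append(
                    GenomicInterval(exon.seqid, exon.start - 1, exon.end, gene.strand)
                )
        if not exon_spans:
            raise ValueError(f"{path}: gene {gene_id!r} has no exon features")
        gene_start, gene_end = gene.start - 1, gene.end
        for ex in exon_spans:
            if ex.start < gene_start or ex.end > gene_end:
                raise ValueError(
                    f"{path}: gene {gene_id!r}: exon {ex} outside gene span"
                )
        merged = merge_intervals(exon_spans)
        exons = tuple(
            GenomicInterval(e.chrom, e.start, e.end, gene.strand) for e in merged
        )
        models.append(_model_from_exons(gene_id, gene.seqid, gene.strand, exons))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write the minimal 6-column TSV gene-model dialect, with header."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texon_starts\texon_ends\n")
        for m in sorted(models, key=lambda m: (m.chrom, m.gene_span.start, m.gene_id)):
            starts = ",".join(str(e.start) for e in m.exons)
            ends = ",".join(str(e.end) for e in m.exons)
            fh.write(f"{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.tss}\t{starts}\t{ends}\n")
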