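"""Deterministic seeded generator of a complete toy regulatory-genomics study.

The generator emulates the statistical structure of the pipeline's inputs —
a small multi-chromosome genome with i.i.d. uniform background sequence,
gene models, overlapping ATAC/H3K27Ac peak pairs with consensus motif sites
planted in a chosen subset, an expression table making chosen genes
enriched, an ortholog map and disease loci overlapping chosen genes — with
full ground truth recorded, so every pipeline stage and the end-to-end run
are verifiable offline.

Layout is anchored: each chromosome carries two isolated "target" slots,
a cluster of enriched non-target genes, and dedicated decoy zones, with
per-seed jitter on every anchor. The slot geometry guarantees that each
planted enhancer lies within the assignment window of exactly one enriched
gene and outside the window of every other enriched gene, so end-to-end
recovery of the planted targets is a deterministic property of the
construction. Planted sites are verified (and decoy enhancers verified
motif-free) by scanning at generation time, with rejection resampling of
the local background sequence under a retry cap.

Decoy classes emitted alongside the planted targets:

1. ATAC-only peaks (no H3K27Ac support);
2. H3K27Ac-only peaks;
3. ATAC+H3K27Ac pairs whose intersection overlaps a promoter;
4. ATAC+H3K27Ac pairs whose intersection falls inside an exon;
5. motif-free active enhancers assigned to enriched genes;
6. motif-bearing active enhancers assigned only to non-enriched genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enhancer_annotation import DEFAULT_ASSIGNMENT_WINDOW, DEFAULT_PROMOTER_WINDOW
from .disease_loci import DiseaseLocus, write_disease_loci
from .genomic_core import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    overlaps,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gene_models,
)
from .motif_scan import (
    ALPHABET,
    DEFAULT_P_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    PWM,
    pwm_distribution,
    scan_multi,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# consensus seeds for the shipped synthetic "Six1-like" matrices
# (non-palindromic, mutually distinct words; stand-ins, not real motifs)
_CONSENSUS_SEEDS = ("TGACAG", "CAGGTG", "GGATTA")


def make_pwm(
    consensus: str,
    information: float = 0.97,
    name: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Build a PWM giving the consensus base probability ``information`` at
    every position, the remainder split evenly over the other three bases.

    ``information`` must exceed the background 0.25, otherwise the motif is
    indistinguishable from background.
    """
    consensus = consensus.upper()
    if not consensus or any(b not in ALPHABET for b in consensus):
        raise ValueError(f"consensus must be a non-empty string over {ALPHABET}")
    if not (0.25 < information < 1.0):
        raise ValueError(
            f"consensus probability must be in (0.25, 1), got {information}"
        )
    off = (1.0 - information) / 3.0
    rows = []
    for b in consensus:
        row = [off] * 4
        row[ALPHABET.index(b)] = information
        rows.append(tuple(row))
    return PWM(name or f"pwm_{consensus}", tuple(rows), pseudocount)


@dataclass
class StudyConfig:
    """Sizes and counts of the toy study; defaults are the study conditions
    used throughout the test-suite and acceptance runs."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 100_000
    n_genes: int = 30
    n_enriched: int = 12
    n_targets: int = 5
    n_motif_free_cres: int = 3
    n_nonenriched_motif_cres: int = 3
    n_atac_only: int = 3
    n_h3k27ac_only: int = 3
    n_promoter_pairs: int = 3
    n_exon_pairs: int = 3
    n_resolved_loci: int = 5
    n_unresolved_loci: int = 3
    n_unmapped_orthologs: int = 2
    promoter_window: int = DEFAULT_PROMOTER_WINDOW
    assignment_window: int = DEFAULT_ASSIGNMENT_WINDOW
    p_threshold: float = DEFAULT_P_THRESHOLD
    motif_width: int = 6
    consensus_probability: float = 0.97
    cre_length: int = 400
    max_retries: int = 200


@dataclass
class SyntheticStudy:
    config: StudyConfig
    genome: dict[str, str]
    sizes: ChromSizes
    genes: list[GeneModel]
    atac: list[GenomicInterval]
    h3k27ac: list[GenomicInterval]
    pwms: list[PWM]
    expression: pd.DataFrame
    ortholog_map: pd.DataFrame
    loci: list[DiseaseLocus]
    truth: dict
    files: dict[str, Path] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit all study files plus truth.json; returns {role: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .motif_scan import write_meme

        paths = {
            "genome": out / "genome.fa",
            "chrom_sizes": out / "genome.chrom.sizes",
            "genes": out / "genes.tsv",
            "atac": out / "atac.bed",
            "h3k27ac": out / "h3k27ac.bed",
            "motifs": out / "motifs.meme",
            "expression": out / "expression.tsv",
            "orthologs": out / "orthologs.tsv",
            "loci": out / "loci.tsv",
            "truth": out / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_chrom_sizes(self.sizes, paths["chrom_sizes"])
        write_gene_models(self.genes, paths["genes"])
        write_bed(self.atac, paths["atac"])
        write_bed(self.h3k27ac, paths["h3k27ac"])
        write_meme(self.pwms, paths["motifs"])
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\tfold_change\tfpkm\n")
            for row in self.expression.itertuples(index=False):
                fh.write(f"{row.gene_id}\t{row.fold_change:.3f}\t{row.fpkm:.3f}\n")
        with open(paths["orthologs"], "w") as fh:
            fh.write("source_id\ttarget_id\n")
            for row in self.ortholog_map.itertuples(index=False):
                fh.write(f"{row.source_id}\t{row.target_id}\n")
        write_disease_loci(self.loci, paths["loci"])
        paths["truth"].write_text(
            json.dumps(self.truth, indent=2, sort_keys=True) + "\n"
        )
        self.files = paths
        return paths


class _PlacementError(ValueError):
    pass


class _Chrom:
    """Bookkeeping for one chromosome during construction."""

    def __init__(self, name: str, seq: np.ndarray):
        self.name = name
        self.seq = seq  # mutable uint8 ascii array
        self.reserved: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.reserved.append((start, end))

    def collides(self, start: int, end: int, margin: int = 0) -> bool:
        return any(
            max(start - margin, s) < min(end + margin, e) for s, e in self.reserved
        )


def _jitter(rng: np.random.Generator, width: int = 300) -> int:
    return int(rng.integers(-width, width + 1))


def generate(
    config: StudyConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Build a complete synthetic study; write its files when ``out_dir`` is
    given. Regenerating with the same config reproduces byte-identical files.
    """
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length
    if L < 60_000:
        raise _PlacementError(
            "chromosome length too small for the anchored layout; "
            "use chrom_length >= 60000 or fewer elements (larger genome advised)"
        )

    # ---- capacity checks -------------------------------------------------
    if cfg.n_targets > 2 * cfg.n_chroms:
        raise _PlacementError(
            f"{cfg.n_targets} targets exceed {2 * cfg.n_chroms} target slots; "
            "increase n_chroms (larger genome advised)"
        )
    free_t2 = 2 * cfg.n_chroms - cfg.n_targets  # unoccupied isolated slots
    if cfg.n_nonenriched_motif_cres > 0 and free_t2 == 0:
        raise _PlacementError(
            "no isolated slot left for non-enriched motif-CRE decoys; "
            "reduce n_targets or increase n_chroms (larger genome advised)"
        )
    n_cluster_total = cfg.n_enriched - cfg.n_targets
    if n_cluster_total < 0:
        raise _PlacementError("n_enriched must be >= n_targets")
    if cfg.n_motif_free_cres > cfg.n_chroms:
        raise _PlacementError(
            "at most one motif-free enhancer decoy per chromosome; "
            "increase n_chroms"
        )

    # ---- shipped matrices ------------------------------------------------
    w = cfg.motif_width
    pwms = []
    for i, seed_word in enumerate(_CONSENSUS_SEEDS):
        word = (seed_word * ((w + len(seed_word) - 1) // len(seed_word)))[:w]
        pwms.append(
            make_pwm(word, cfg.consensus_probability, name=f"Six1like_{'ABC'[i]}")
        )
    for pwm in pwms:
        dist = pwm_distribution(pwm)
        consensus_score = int(dist.int_matrix.max(axis=1).sum())
        if dist.pvalue_units(consensus_score) > cfg.p_threshold:
            raise _PlacementError(
                "planted consensus would not pass the scan threshold; increase "
                "consensus_probability or motif width"
            )

    # ---- genome ----------------------------------------------------------
    chroms = [
        _Chrom(f"chr{i + 1}", _BASES[rng.integers(0, 4, size=L)].copy())
        for i in range(cfg.n_chroms)
    ]

    genes: list[GeneModel] = []
    expression_rows: list[tuple[str, float, float]] = []
    truth: dict = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "target_genes": [],
        "enriched_genes": [],
        "planted_cres": {},
        "motif_free_cres": [],
        "nonenriched_motif_cres": {},
        "decoys": {
            "atac_only": [],
            "h3k27ac_only": [],
            "promoter_pairs": [],
            "exon_pairs": [],
        },
    }
    atac: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    gene_n = 0

    def add_gene(
        ch: _Chrom, tss_anchor: int, strand: str, enriched: bool, label: str
    ) -> GeneModel:
        nonlocal gene_n
        gene_n += 1
        gene_id = f"g{gene_n:03d}"
        # exon template relative to the span start; span length 2700
        rel = [(0, 300), (1200, 1700), (2200, 2700)]
        if strand == "+":
            start = tss_anchor
        else:
            start = tss_anchor - 2699
        if start < 0 or start + 2700 > L:
            raise _PlacementError(f"gene slot for {label} out of bounds")
        if ch.collides(start, start + 2700, margin=1200):
            raise _PlacementError(f"gene slot collision for {label}")
        exons = tuple(
            GenomicInterval(ch.name, start + a, start + b, strand) for a, b in rel
        )
        tss = start if strand == "+" else start + 2699
        model = GeneModel(gene_id, ch.name, strand, tss, exons)
        ch.reserve(start, start + 2700)
        genes.append(model)
        if enriched:
            fc = float(rng.uniform(2.5, 8.0))
            fpkm = float(rng.uniform(15.0, 100.0))
            truth["enriched_genes"].append(gene_id)
        else:
            fc = float(rng.uniform(0.2, 1.8))
            fpkm = float(rng.uniform(0.5, 80.0))
        expression_rows.append((gene_id, fc, fpkm))
        return model

    def add_peak_pair(ch: _Chrom, s: int, e: int) -> GenomicInterval:
        """ATAC and H3K27Ac peaks whose intersection is exactly [s, e)."""
        atac.append(GenomicInterval(ch.name, s - 80, e))
        h3k27ac.append(GenomicInterval(ch.name, s, e + 80))
        ch.reserve(s - 80, e + 80)
        return GenomicInterval(ch.name, s, e, name=f"{ch.name}:{s}-{e}")

    def plant_site(ch: _Chrom, cre: GenomicInterval, pwm: PWM) -> int:
        lo = cre.start + 10
        hi = cre.end - w - 10
        pos = int(rng.integers(lo, hi + 1))
        ch.seq[pos : pos + w] = np.frombuffer(
            pwm.consensus.encode("ascii"), dtype=np.uint8
        )
        return pos

    def cre_seq(ch: _Chrom, cre: GenomicInterval) -> str:
        return ch.seq[cre.start : cre.end].tobytes().decode("ascii")

    def redraw(ch: _Chrom, start: int, end: int, keep: tuple[int, int] | None) -> None:
        """Resample background bases of [start, end), preserving ``keep``."""
        fresh = _BASES[rng.integers(0, 4, size=end - start)]
        if keep is not None:
            ka, kb = keep
            fresh[ka - start : kb - start] = ch.seq[ka:kb]
        ch.seq[start:end] = fresh

    def verify_planted(ch: _Chrom, cre: GenomicInterval, pwm: PWM, pos: int) -> None:
        """Rejection-resample the CRE background until the planted site is the
        unique hit of any shipped matrix within the fragment."""
        for _ in range(cfg.max_retries):
            hits = scan_multi(cre_seq(ch, cre), pwms, cfg.p_threshold)
            if (
                len(hits) == 1
                and hits[0].start == pos - cre.start
                and hits[0].pwm_name == pwm.name
            ):
                return
            redraw(ch, cre.start, cre.end, keep=(pos, pos + w))
        raise _PlacementError(
            "could not isolate a planted motif site after retries; "
            "larger genome or longer CREs advised"
        )

    def verify_motif_free(ch: _Chrom, cre: GenomicInterval) -> None:
        for _ in range(cfg.max_retries):
            if not scan_multi(cre_seq(ch, cre), pwms, cfg.p_threshold):
                return
            redraw(ch, cre.start, cre.end, keep=None)
        raise _PlacementError(
            "could not generate a motif-free enhancer after retries; "
            "larger genome advised"
        )

    # ---- anchored layout -------------------------------------------------
    clen = cfg.cre_length
    t_slots = [
        (ci, anchor)
        for anchor in (int(0.08 * L), int(0.52 * L))
        for ci in range(cfg.n_chroms)
    ]  # fill first anchors across chromosomes, then second
    cluster_anchors = [int(0.88 * L), int(0.925 * L), int(0.97 * L)]

    # targets with planted enhancers
    for i in range(cfg.n_targets):
        ci, anchor = t_slots[i]
        ch = chroms[ci]
        a = anchor + _jitter(rng)
        gene = add_gene(ch, a, str(rng.choice(["+", "-"])), enriched=True, label="target")
        s = a - 4400 + _jitter(rng, 100)
        cre = add_peak_pair(ch, s, s + clen)
        pwm = pwms[i % len(pwms)]
        pos = plant_site(ch, cre, pwm)
        verify_planted(ch, cre, pwm, pos)
        truth["target_genes"].append(gene.gene_id)
        truth["planted_cres"][cre.name] = {
            "gene": gene.gene_id,
            "pwm": pwm.name,
            "site_start": pos,
        }

    # non-enriched genes with motif-bearing enhancers (decoy class 6),
    # hosted in the remaining isolated slots
    free_slots = t_slots[cfg.n_targets :]
    n_c6_slots = min(len(free_slots), cfg.n_nonenriched_motif_cres)
    c6_slots = free_slots[:n_c6_slots]
    overflow_slots = free_slots[n_c6_slots:]  # spare capacity for enriched genes
    n_cluster = min(n_cluster_total, 3 * cfg.n_chroms)
    n_overflow = n_cluster_total - n_cluster
    if n_overflow > len(overflow_slots):
        raise _PlacementError(
            f"{n_cluster_total} enriched non-target genes exceed cluster "
            f"capacity {3 * cfg.n_chroms} plus {len(overflow_slots)} spare "
            "slots; increase n_chroms (larger genome advised)"
        )
    slot_anchor: dict[int, int] = {}
    slot_host: dict[int, GeneModel] = {}
    for j in range(cfg.n_nonenriched_motif_cres):
        si = j % n_c6_slots
        ci, anchor = c6_slots[si]
        ch = chroms[ci]
        if si not in slot_anchor:
            slot_anchor[si] = anchor + _jitter(rng)
            slot_host[si] = add_gene(
                ch, slot_anchor[si], "+", enriched=False,
                label="nonenriched-motif host",
            )
        offset = 4400 + 800 * (j // len(free_slots))
        s = slot_anchor[si] - offset + _jitter(rng, 50)
        if s < 100:
            raise _PlacementError(
                "non-enriched motif-CRE decoys exhaust their slot; fewer "
                "decoys or a larger genome advised"
            )
        cre = add_peak_pair(ch, s, s + clen)
        pwm = pwms[j % len(pwms)]
        pos = plant_site(ch, cre, pwm)
        verify_planted(ch, cre, pwm, pos)
        truth["nonenriched_motif_cres"][cre.name] = {
            "gene": slot_host[si].gene_id,
            "pwm": pwm.name,
            "site_start": pos,
        }

    # enriched non-target cluster genes (all + strand so spans stack rightward)
    for j in range(n_cluster):
        ch = chroms[j % cfg.n_chroms]
        anchor = cluster_anchors[j // cfg.n_chroms] + _jitter(rng, 200)
        add_gene(ch, anchor, "+", enriched=True, label="cluster")
    # overflow enriched genes take leftover isolated slots
    for j in range(n_overflow):
        ci, anchor = overflow_slots[j]
        add_gene(
            chroms[ci], anchor + _jitter(rng), "+", enriched=True, label="overflow"
        )

    # motif-free active enhancers just upstream of the enriched cluster
    # (decoy class 5): intergenic, > promoter_window from every TSS, within
    # the assignment window of the cluster genes
    for j in range(cfg.n_motif_free_cres):
        ch = chroms[j % cfg.n_chroms]
        s = int(0.86 * L) + _jitter(rng, 100)
        cre = add_peak_pair(ch, s, s + clen)
        verify_motif_free(ch, cre)
        truth["motif_free_cres"].append(cre.name)

    # filler (non-enriched) genes in free zones; hosts for promoter/exon decoys
    filler_needed = cfg.n_genes - gene_n
    if filler_needed < cfg.n_promoter_pairs + cfg.n_exon_pairs:
        raise _PlacementError(
            "not enough filler genes to host promoter/exon decoy peaks; "
            "increase n_genes"
        )
    fillers: list[GeneModel] = []
    zones = [(int(0.15 * L), int(0.42 * L)), (int(0.60 * L), int(0.82 * L))]
    for j in range(filler_needed):
        placed = False
        for _ in range(cfg.max_retries):
            ch = chroms[int(rng.integers(0, cfg.n_chroms))]
            zlo, zhi = zones[int(rng.integers(0, 2))]
            a = int(rng.integers(zlo, zhi - 2700))
            if ch.collides(a, a + 2700, margin=1500):
                continue
            fillers.append(add_gene(ch, a, "+", enriched=False, label="filler"))
            placed = True
            break
        if not placed:
            raise _PlacementError(
                "filler gene placement infeasible after retries; larger genome "
                "advised"
            )

    # promoter-overlapping peak pairs (decoy class 3)
    for j in range(cfg.n_promoter_pairs):
        host = fillers[j]
        ch = next(c for c in chroms if c.name == host.chrom)
        cre = add_peak_pair(ch, host.tss - clen // 2, host.tss + clen // 2)
        truth["decoys"]["promoter_pairs"].append(cre.name)

    # exon-overlapping peak pairs (decoy class 4): inside the third exon,
    # > promoter_window away from the host TSS
    for j in range(cfg.n_exon_pairs):
        host = fillers[cfg.n_promoter_pairs + j]
        ch = next(c for c in chroms if c.name == host.chrom)
        exon = host.exons[-1]
        s, e = exon.start + 100, exon.start + 400
        cre = add_peak_pair(ch, s, e)
        truth["decoys"]["exon_pairs"].append(cre.name)

    # unsupported single-assay peaks (decoy classes 1 and 2)
    def place_single(track: list[GenomicInterval], label: str) -> str:
        for _ in range(cfg.max_retries):
            ch = chroms[int(rng.integers(0, cfg.n_chroms))]
            zlo, zhi = zones[int(rng.integers(0, 2))]
            s = int(rng.integers(zlo, zhi - 600))
            if ch.collides(s, s + 500, margin=300):
                continue
            iv = GenomicInterval(ch.name, s, s + 500)
            track.append(iv)
            ch.reserve(s, s + 500)
            return str(iv)
        raise _PlacementError(
            f"{label} decoy placement infeasible after retries; larger genome "
            "advised"
        )

    for _ in range(cfg.n_atac_only):
        truth["decoys"]["atac_only"].append(place_single(atac, "ATAC-only"))
    for _ in range(cfg.n_h3k27ac_only):
        truth["decoys"]["h3k27ac_only"].append(place_single(h3k27ac, "H3K27Ac-only"))

    # ---- geometry invariants --------------------------------------------
    gene_by_id = {g.gene_id: g for g in genes}
    enriched_set = set(truth["enriched_genes"])
    win = cfg.assignment_window
    for cre_id, rec in truth["planted_cres"].items():
        chrom, span = cre_id.split(":")
        s, e = map(int, span.split("-"))
        mid = (s + e) // 2
        for gid in enriched_set:
            g = gene_by_id[gid]
            d = abs(g.tss - mid) if g.chrom == chrom else win + 1
            if gid == rec["gene"]:
                assert d <= win, f"planted CRE {cre_id} outside window of {gid}"
            else:
                assert d > win, (
                    f"planted CRE {cre_id} within window of unintended enriched "
                    f"gene {gid}; layout infeasible (larger genome advised)"
                )
    for cre_id in truth["nonenriched_motif_cres"]:
        chrom, span = cre_id.split(":")
        s, e = map(int, span.split("-"))
        mid = (s + e) // 2
        for gid in enriched_set:
            g = gene_by_id[gid]
            if g.chrom == chrom:
                assert abs(g.tss - mid) > win, (
                    f"non-enriched decoy CRE {cre_id} within window of enriched "
                    f"gene {gid}"
                )

    # ---- expression, orthologs, disease loci -----------------------------
    expression = pd.DataFrame(
        expression_rows, columns=["gene_id", "fold_change", "fpkm"]
    ).sort_values("gene_id", ignore_index=True)

    non_enriched_ids = sorted(set(g.gene_id for g in genes) - enriched_set)
    unmapped = set(non_enriched_ids[: cfg.n_unmapped_orthologs])
    ortho_rows = [
        (g.gene_id, f"HS_{g.gene_id.upper()}")
        for g in sorted(genes, key=lambda g: g.gene_id)
        if g.gene_id not in unmapped
    ]
    ortholog_map = pd.DataFrame(ortho_rows, columns=["source_id", "target_id"])

    sizes = ChromSizes({ch.name: L for ch in chroms})
    loci: list[DiseaseLocus] = []
    # unresolved loci: cover target genes (and cluster genes) in turn
    unresolved_hosts = (
        truth["target_genes"] + [g for g in truth["enriched_genes"] if g not in truth["target_genes"]]
        + non_enriched_ids
    )
    for j in range(cfg.n_unresolved_loci):
        host = gene_by_id[unresolved_hosts[j % len(unresolved_hosts)]]
        span = host.gene_span
        lo = max(0, span.start - 2000)
        hi = min(L, span.end + 2000)
        loci.append(
            DiseaseLocus(
                f"LOCUS_U{j + 1:02d}",
                GenomicInterval(host.chrom, lo, hi),
                None,
                "synthetic unresolved deafness locus",
            )
        )
    resolved_hosts = [g for g in unresolved_hosts[cfg.n_unresolved_loci :]]
    for j in range(cfg.n_resolved_loci):
        host = gene_by_id[resolved_hosts[j % len(resolved_hosts)]]
        span = host.gene_span
        lo = max(0, span.start - 1000)
        hi = min(L, span.end + 1000)
        loci.append(
            DiseaseLocus(
                f"LOCUS_R{j + 1:02d}",
                GenomicInterval(host.chrom, lo, hi),
                f"HS_{host.gene_id.upper()}",
                "synthetic resolved deafness locus",
            )
        )

    # ground-truth in-locus gene set: genes overlapping extended unresolved loci
    flank = 100
    in_locus = sorted(
        g.gene_id
        for g in genes
        if any(
            overlaps(
                g.gene_span,
                GenomicInterval(
                    l.interval.chrom,
                    max(0, l.interval.start - flank),
                    min(L, l.interval.end + flank),
                ),
            )
            for l in loci
            if not l.resolved
        )
    )
    truth["in_locus_genes"] = in_locus
    truth["unresolved_loci"] = [l.locus_id for l in loci if not l.resolved]
    truth["resolved_loci"] = [l.locus_id for l in loci if l.resolved]
    truth["target_genes"].sort()
    truth["enriched_genes"].sort()
    truth["n_planted_sites"] = len(truth["planted_cres"]) + len(
        truth["nonenriched_motif_cres"]
    )

    study = SyntheticStudy(
        config=cfg,
        genome={ch.name: ch.seq.tobytes().decode("ascii") for ch in chroms},
        sizes=sizes,
        genes=genes,
        atac=atac,
        h3k27ac=h3k27ac,
        pwms=pwms,
        expression=expression,
        ortholog_map=ortholog_map,
        loci=loci,
        truth=truth,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
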