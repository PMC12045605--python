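"""PWM motif scanning with exact p-values.

A motif is a position weight matrix of per-position base probabilities.
Windows are scored by the log-odds (base 2) of the motif model against an
order-0 background, and each score is converted to an exact p-value: the
probability that a random background-distributed word of motif width scores
at least as high. The null score distribution is computed by dynamic
programming over positions on a discretised score lattice, so p-values are
exact up to the chosen granularity — the same lattice is used for scoring
windows, which makes the DP survival function and a brute-force enumeration
over all 4^w words agree *exactly* for small widths.

Scanning covers both strands by default: the minus strand is handled by
scanning the reverse-complemented matrix (with its own null distribution)
across the forward sequence, so minus-strand hits carry plus-strand
coordinates. Windows containing N are skipped. All hits with
p-value <= threshold are reported; overlapping hits are not masked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.001
DEFAULT_GRANULARITY = 1.0 / 1000  # bits
DEFAULT_P_THRESHOLD = 0.001
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)

# Hard cap on the discretised support of the null distribution; exceeding it
# means the granularity is too fine for the motif width/score range.
MAX_SUPPORT = 20_000_000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: width x 4 base probabilities (A,C,G,T order).

    ``probs`` rows must sum to 1; the pseudocount is applied (and rows
    renormalised) when scores are computed, never stored.
    """

    name: str
    probs: tuple[tuple[float, ...], ...]
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, ...] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        mat = np.asarray(self.probs, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: probs must be width x 4, width >= 1")
        if np.any(mat < 0):
            raise ValueError(f"PWM {self.name}: negative probabilities")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(mat.sum(axis=1) - 1.0)))
            raise ValueError(f"PWM {self.name}: row {bad} does not sum to 1")
        if self.pseudocount < 0:
            raise ValueError(f"PWM {self.name}: pseudocount must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError(
                f"PWM {self.name}: background must be 4 positive values summing to 1"
            )
        object.__setattr__(self, "probs", tuple(tuple(map(float, row)) for row in mat))
        object.__setattr__(self, "background", tuple(map(float, bg)))

    @property
    def width(self) -> int:
        return len(self.probs)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[int(np.argmax(row))] for row in self.probs)

    def reverse_complement(self) -> "PWM":
        mat = np.asarray(self.probs)[::-1, ::-1]  # reverse positions, A<->T C<->G
        return PWM(self.name, tuple(map(tuple, mat)), self.pseudocount, self.background)


def log_odds(pwm: PWM) -> np.ndarray:
    """Width x 4 log-odds score matrix in bits.

    Entry (i, b) = log2(p'[i,b] / background[b]) where p' is the
    pseudocount-regularised probability (p + c) / (1 + 4c).
    """
    mat = np.asarray(pwm.probs, dtype=float)
    c = pwm.pseudocount
    reg = (mat + c) / (1.0 + 4.0 * c)
    if np.any(reg <= 0):
        raise ValueError(
            f"PWM {pwm.name}: zero probability with zero pseudocount; "
            "set pseudocount > 0"
        )
    bg = np.asarray(pwm.background, dtype=float)
    return np.log2(reg / bg)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretised log-odds score.

    Scores are mapped to an integer lattice (units of ``granularity`` bits);
    ``pmf[k]`` is the probability that a random background word scores
    ``(min_units + k) * granularity``. The survival function gives
    p-value(s) = P(score >= s).
    """

    granularity: float
    int_matrix: np.ndarray  # width x 4 lattice scores
    min_units: int
    pmf: np.ndarray
    sf: np.ndarray  # same support as pmf; sf[k] = P(S >= min_units + k)

    @property
    def max_units(self) -> int:
        return self.min_units + len(self.pmf) - 1

    def pvalue_units(self, units: int) -> float:
        """p-value of an integer lattice score."""
        if units <= self.min_units:
            return 1.0
        if units > self.max_units:
            return 0.0
        return float(self.sf[units - self.min_units])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_units(int(round(score_bits / self.granularity)))


def score_distribution(
    score_matrix: np.ndarray,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreDistribution:
    """Exact null distribution of the discretised PWM score by DP convolution.

    Each per-position score is rounded to the nearest multiple of
    ``granularity``; the distribution of the sum over independent
    background-distributed positions is then built position by position.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    mat = np.asarray(score_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("score matrix must be width x 4")
    bg = np.asarray(background, dtype=float)
    int_matrix = np.rint(mat / granularity).astype(np.int64)
    lo = int(int_matrix.min(axis=1).sum())
    hi = int(int_matrix.max(axis=1).sum())
    if hi - lo + 1 > MAX_SUPPORT:
        raise ValueError(
            f"discretised score support {hi - lo + 1} exceeds cap {MAX_SUPPORT}; "
            "use a coarser granularity"
        )
    pmf = np.array([1.0])
    offset = 0  # lattice value of pmf[0]
    for row in int_matrix:
        row_lo = int(row.min())
        new = np.zeros(len(pmf) + int(row.max()) - row_lo)
        for b in range(4):
            shift = int(row[b]) - row_lo
            new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        offset += row_lo
    # numerical guard: renormalise the tiny drift from repeated addition
    pmf /= pmf.sum()
    sf = np.cumsum(pmf[::-1])[::-1]
    np.minimum(sf, 1.0, out=sf)
    return ScoreDistribution(granularity, int_matrix, offset, pmf, sf)


@lru_cache(maxsize=64)
def pwm_distribution(
    pwm: PWM, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    return score_distribution(log_odds(pwm), pwm.background, granularity)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence; minus-strand hits carry plus-strand coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str
    pwm_name: str
    score: float  # log-odds, bits (discretised lattice value)
    p_value: float


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to indices 0-3; anything else (incl. N) -> -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


def _window_scores(code: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Lattice score of every window; windows containing N get INT64_MIN."""
    w = len(int_matrix)
    n = len(code) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    if valid.any():
        idx = windows[valid]
        scores[valid] = int_matrix[np.arange(w), idx].sum(axis=1)
    return scores


def scan(
    seq: str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    sequence_id: str = "seq",
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """All windows with p-value <= ``p_threshold``, sorted by (start, strand).

    A sequence shorter than the motif yields an empty list. Windows
    containing N are skipped.
    """
    code = encode(seq)
    hits: list[MotifHit] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat_pwm in strands:
        dist = pwm_distribution(mat_pwm, granularity)
        scores = _window_scores(code, dist.int_matrix)
        for pos in np.nonzero(scores > np.iinfo(np.int64).min)[0]:
            p = dist.pvalue_units(int(scores[pos]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        sequence_id=sequence_id,
                        start=int(pos),
                        end=int(pos) + pwm.width,
                        strand=strand,
                        pwm_name=pwm.name,
                        score=float(scores[pos]) * granularity,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_multi(
    seq: str,
    pwms: Sequence[PWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    sequence_id: str = "seq",
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Union of per-PWM hits (OR semantics across matrices)."""
    if not pwms:
        raise ValueError("at least one PWM is required")
    hits: list[MotifHit] = []
    for pwm in pwms:
        hits.extend(
            scan(seq, pwm, p_threshold, both_strands, sequence_id, granularity)
        )
    hits.sort(key=lambda h: (h.start, h.strand, h.pwm_name))
    return hits


def delete_motif(
    seq: str, hits: Sequence[MotifHit], selection: str = "lowest_p"
) -> tuple[str, MotifHit]:
    """Excise one motif hit from the sequence (reporter deletion-construct design).

    ``selection="lowest_p"`` removes the hit with the smallest p-value, ties
    broken by leftmost start. Returns (edited sequence, removed hit).
    """
    if not hits:
        raise ValueError("no motif to delete")
    if selection != "lowest_p":
        raise ValueError(f"unknown selection rule {selection!r}")
    hit = min(hits, key=lambda h: (h.p_value, h.start))
    if hit.end > len(seq) or hit.start < 0:
        raise ValueError(f"hit [{hit.start},{hit.end}) outside sequence bounds")
    return seq[: hit.start] + seq[hit.end :], hit


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

_LPM_RE = re.compile(
    r"letter-probability matrix:(?:\s+alength=\s*(\d+))?(?:\s+w=\s*(\d+))?"
)


def read_meme(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read motifs from a MEME minimal-format file.

    Background frequencies are taken from the file when present, else
    uniform. Rows not summing to 1 (tolerance 1e-3) raise an error naming
    the motif and row; a width header disagreeing with the number of matrix
    rows is an error.
    """
    lines = Path(path).read_text().splitlines()
    background = list(UNIFORM_BACKGROUND)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = [freq[b] for b in ALPHABET]
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(
                        f"{path}: motif {name!r} has no letter-probability matrix"
                    )
                i += 1
            if i >= len(lines):
                raise ValueError(
                    f"{path}: motif {name!r} has no letter-probability matrix"
                )
            m = _LPM_RE.search(lines[i])
            declared_w = int(m.group(2)) if m and m.group(2) else None
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in stripped.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}: motif {name!r} row {len(rows)}: expected 4 values"
                    )
                rows.append(vals)
                i += 1
            if declared_w is not None and declared_w != len(rows):
                raise ValueError(
                    f"{path}: motif {name!r}: header width {declared_w} != "
                    f"{len(rows)} matrix rows"
                )
            for r, vals in enumerate(rows):
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise ValueError(
                        f"{path}: motif {name!r} row {r} does not sum to 1"
                    )
            norm = [[v / sum(vals) for v in vals] for vals in rows]
            pwms.append(
                PWM(name, tuple(map(tuple, norm)), pseudocount, tuple(background))
            )
            continue
        i += 1
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (8-decimal probabilities)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)) + "\n\n"
            )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.8f}" for v in row) + "\n")
            fh.write("\n")


def write_hits_table(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\tstrand\tmotif\tscore\tp_value\n")
        for h in sorted(hits, key=lambda h: (h.sequence_id, h.start, h.strand, h.pwm_name)):
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.pwm_name}\t{h.score:.4f}\t{h.p_value:.3e}\n"
            )
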