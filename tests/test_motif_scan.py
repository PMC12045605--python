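"""PWM scoring, exact p-value DP vs exhaustive enumeration, scanning, MEME I/O."""

import itertools

import numpy as np
import pytest

from cretarget.motif_scan import (
    PWM,
    delete_motif,
    log_odds,
    pwm_distribution,
    read_meme,
    reverse_complement,
    scan,
    scan_multi,
    score_distribution,
    write_meme,
)
from cretarget.synthetic_data import make_pwm

GRAN = 1.0 / 1000


def uniform_pwm(width, name="u"):
    return PWM(name, tuple((0.25,) * 4 for _ in range(width)), pseudocount=0.0)


def enumeration_pmf(int_matrix, background):
    """Mass of each lattice score by brute-force enumeration of all 4^w
    words, on the same discretised lattice as the DP."""
    w = len(int_matrix)
    scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(int_matrix[i, b] for i, b in enumerate(word)))
        p = float(np.prod([background[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    return scores


def enumeration_sf(int_matrix, background):
    pmf = enumeration_pmf(int_matrix, background)
    sf = {}
    acc = 0.0
    for s in sorted(pmf, reverse=True):
        acc += pmf[s]
        sf[s] = acc
    return sf


class TestLogOdds:
    def test_background_equal_rows_score_zero(self):
        assert np.allclose(log_odds(uniform_pwm(3)), 0.0)

    def test_direct_log2_ratios(self):
        pwm = PWM("t", ((0.5, 0.25, 0.125, 0.125),), pseudocount=0.0)
        assert np.allclose(log_odds(pwm), [[1.0, 0.0, -1.0, -1.0]])

    def test_nonuniform_background_ratio(self):
        bg = (0.4, 0.1, 0.1, 0.4)
        pwm = PWM("t", ((0.4, 0.1, 0.1, 0.4),), pseudocount=0.0, background=bg)
        assert np.allclose(log_odds(pwm), 0.0)

    def test_pseudocount_regularises_zeros(self):
        pwm = PWM("t", ((1.0, 0.0, 0.0, 0.0),), pseudocount=0.001)
        scores = log_odds(pwm)
        assert np.all(np.isfinite(scores))
        with pytest.raises(ValueError, match="pseudocount"):
            log_odds(PWM("t", ((1.0, 0.0, 0.0, 0.0),), pseudocount=0.0))


class TestScoreDistribution:
    def test_width_one_enumeration(self):
        # scores (1, 0, -1, -1) bits, uniform background
        dist = score_distribution(np.array([[1.0, 0.0, -1.0, -1.0]]), granularity=GRAN)
        assert dist.pvalue(1.0) == pytest.approx(0.25)
        assert dist.pvalue(0.0) == pytest.approx(0.5)
        assert dist.pvalue(-1.0) == pytest.approx(1.0)

    def test_degenerate_background_pwm(self):
        dist = pwm_distribution(uniform_pwm(4))
        assert len(dist.pmf) == 1
        assert dist.pvalue(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_dp_equals_enumeration(self, width, rng):
        probs = rng.dirichlet(np.ones(4), size=width)
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PWM("r", tuple(map(tuple, probs)), 0.001, tuple(bg))
        dist = pwm_distribution(pwm)
        sf = enumeration_sf(dist.int_matrix, bg)
        for s, p in sf.items():
            assert dist.pvalue_units(s) == pytest.approx(p, abs=1e-9)

    def test_survival_monotone_and_pmf_normalised(self, rng):
        probs = rng.dirichlet(np.ones(4), size=7)
        dist = pwm_distribution(PWM("m", tuple(map(tuple, probs))))
        assert dist.pmf.sum() == pytest.approx(1.0)
        assert np.all(np.diff(dist.sf) <= 1e-15)
        assert dist.sf[0] == pytest.approx(1.0)

    def test_granularity_halving_converges(self, rng):
        """Refining the lattice moves a p-value by no more than the mass of
        words whose score lies within one per-position rounding error (at
        most width coarse units) of the threshold."""
        probs = rng.dirichlet(np.ones(4), size=5)
        pwm = PWM("m", tuple(map(tuple, probs)))
        coarse = pwm_distribution(pwm, GRAN)
        fine = pwm_distribution(pwm, GRAN / 2)
        mat = log_odds(pwm)
        word = [int(np.argmax(row)) for row in mat]  # consensus word
        exact = float(sum(mat[i, b] for i, b in enumerate(word)))
        p_coarse = coarse.pvalue(exact)
        p_fine = fine.pvalue(exact)
        units = int(round(exact / GRAN))
        pmf = enumeration_pmf(coarse.int_matrix, pwm.background)
        bound = sum(p for s, p in pmf.items() if abs(s - units) <= pwm.width)
        assert abs(p_coarse - p_fine) <= bound + 1e-12

    def test_support_cap_advises_coarser_granularity(self):
        pwm = make_pwm("ACGTAC" * 10, 0.97)
        with pytest.raises(ValueError, match="coarser granularity"):
            pwm_distribution(pwm, granularity=1e-9)


class TestScan:
    @pytest.fixture()
    def planted(self, rng):
        pwm = make_pwm("TGACAG", 0.97, name="m6")
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=200))
        seq = seq[:20] + "TGACAG" + seq[26:]
        return seq, pwm

    def test_empty_sequence(self):
        assert scan("", make_pwm("TGACAG", 0.97)) == []

    def test_shorter_than_width(self):
        assert scan("ACG", make_pwm("TGACAG", 0.97)) == []

    def test_planted_consensus_unique_hit(self, planted):
        seq, pwm = planted
        # brute-force check against enumeration-based p-values
        dist = pwm_distribution(pwm)
        sf = enumeration_sf(dist.int_matrix, pwm.background)
        rc = pwm.reverse_complement()
        dist_rc = pwm_distribution(rc)
        sf_rc = enumeration_sf(dist_rc.int_matrix, rc.background)
        expected = []
        for i in range(len(seq) - 5):
            word = [("ACGT".index(b)) for b in seq[i : i + 6]]
            s = int(sum(dist.int_matrix[j, b] for j, b in enumerate(word)))
            if sf[s] <= 0.001:
                expected.append((i, "+"))
            s2 = int(sum(dist_rc.int_matrix[j, b] for j, b in enumerate(word)))
            if sf_rc[s2] <= 0.001:
                expected.append((i, "-"))
        hits = scan(seq, pwm, 0.001)
        assert [(h.start, h.strand) for h in hits] == sorted(expected)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (20, 26)

    def test_windows_with_n_skipped(self):
        pwm = make_pwm("TGACAG", 0.97)
        assert scan("ANTGACAGN", pwm) == [h for h in scan("ANTGACAGN", pwm)]
        hits = scan("NNTGACAG", pwm)
        assert [(h.start, h.end) for h in hits] == [(2, 8)]

    def test_reverse_complement_symmetry(self, planted):
        seq, pwm = planted
        fwd = scan(seq, pwm, 0.01)
        rev = scan(reverse_complement(seq), pwm, 0.01)
        n = len(seq)
        mirrored = sorted(
            (n - h.end, "+" if h.strand == "-" else "-", round(h.score, 6))
            for h in rev
        )
        assert mirrored == sorted((h.start, h.strand, round(h.score, 6)) for h in fwd)

    def test_hit_count_monotone_in_threshold(self, planted):
        seq, pwm = planted
        counts = [len(scan(seq, pwm, p)) for p in (1e-4, 1e-3, 1e-2, 1e-1)]
        assert counts == sorted(counts)

    def test_every_hit_below_threshold(self, planted):
        seq, pwm = planted
        for p_t in (0.001, 0.05):
            assert all(h.p_value <= p_t for h in scan(seq, pwm, p_t))


class TestScanMulti:
    def test_single_pwm_identical_to_scan(self, rng):
        pwm = make_pwm("CAGGTG", 0.97)
        seq = "".join(rng.choice(list("ACGT"), size=300)) + "CAGGTG"
        assert scan_multi(seq, [pwm]) == scan(seq, pwm)

    def test_duplicate_pwms_distinguished_by_name(self):
        a = make_pwm("TGACAG", 0.97, name="a")
        b = make_pwm("TGACAG", 0.97, name="b")
        hits = scan_multi("AATGACAGTT", [a, b])
        assert [h.pwm_name for h in hits] == ["a", "b"]

    def test_union_of_three_scans(self, default_study):
        seq = default_study.genome["chr1"][:5000]
        pwms = default_study.pwms
        union = {
            (h.start, h.strand, h.pwm_name)
            for pwm in pwms
            for h in scan(seq, pwm)
        }
        multi = {(h.start, h.strand, h.pwm_name) for h in scan_multi(seq, pwms)}
        assert multi == union

    def test_empty_pwm_list_rejected(self):
        with pytest.raises(ValueError):
            scan_multi("ACGT", [])


class TestDeleteMotif:
    def _hit(self, start, end, p):
        from cretarget.motif_scan import MotifHit

        return MotifHit("s", start, end, "+", "m", 5.0, p)

    def test_splice(self):
        edited, removed = delete_motif("AAATGATACCCC", [self._hit(3, 9, 1e-4)])
        assert edited == "AAACCC"
        assert removed.start == 3

    def test_lowest_p_selected(self):
        hits = [self._hit(0, 6, 1e-4), self._hit(7, 13, 1e-5)]
        edited, removed = delete_motif("A" * 20, hits)
        assert removed.p_value == 1e-5

    def test_tie_broken_leftmost(self):
        hits = [self._hit(7, 13, 1e-5), self._hit(0, 6, 1e-5)]
        _, removed = delete_motif("A" * 20, hits)
        assert removed.start == 0

    def test_deletion_at_origin(self):
        edited, _ = delete_motif("TGACAGCCC", [self._hit(0, 6, 1e-4)])
        assert edited == "CCC"

    def test_empty_hits_error(self):
        with pytest.raises(ValueError, match="no motif to delete"):
            delete_motif("ACGT", [])


class TestMemeIO:
    def test_uniform_single_motif(self, tmp_path):
        p = tmp_path / "u.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF uni\nletter-probability matrix: alength= 4 w= 2\n"
            " 0.25 0.25 0.25 0.25\n 0.25 0.25 0.25 0.25\n"
        )
        [pwm] = read_meme(p)
        assert pwm.width == 2
        assert np.allclose(pwm.probs, 0.25)
        assert pwm.background == (0.25, 0.25, 0.25, 0.25)

    def test_round_trip_three_random(self, rng, tmp_path):
        pwms = [
            PWM(f"m{i}", tuple(map(tuple, rng.dirichlet(np.ones(4), size=5))))
            for i in range(3)
        ]
        p = tmp_path / "rt.meme"
        write_meme(pwms, p)
        back = read_meme(p)
        assert [b.name for b in back] == ["m0", "m1", "m2"]
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.probs, rt.probs, atol=1e-6)

    def test_background_round_trip(self, tmp_path):
        bg = (0.3, 0.2, 0.2, 0.3)
        pwm = PWM("b", ((0.3, 0.2, 0.2, 0.3),), background=bg)
        p = tmp_path / "bg.meme"
        write_meme([pwm], p)
        [back] = read_meme(p)
        assert np.allclose(back.background, bg, atol=1e-6)

    def test_width_header_mismatch_error(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(
            "MEME version 4\n\nMOTIF bad\n"
            "letter-probability matrix: alength= 4 w= 3\n"
            " 0.25 0.25 0.25 0.25\n 0.25 0.25 0.25 0.25\n"
        )
        with pytest.raises(ValueError, match="width"):
            read_meme(p)

    def test_row_sum_error_names_motif_and_row(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(
            "MEME version 4\n\nMOTIF lop\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            " 0.5 0.4 0.2 0.2\n"
        )
        with pytest.raises(ValueError, match="lop.*row 0|row 0"):
            read_meme(p)
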