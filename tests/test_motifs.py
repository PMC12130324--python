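"""PWM log-odds construction, exact p-values and sequence scanning."""

import itertools

import numpy as np
import pytest

from sescout.core import ValidationError
from sescout.motifs import (
    Pwm,
    exact_score_pvalues,
    pwm_to_logodds,
    read_jaspar,
    reverse_complement,
    scan_sequence,
    write_jaspar,
)


def uniform_pwm(counts, pseudocount=0.0):
    return Pwm("m", np.array(counts, dtype=float), pseudocount=pseudocount)


class TestLogOdds:
    def test_pure_column_closed_form(self):
        pwm = uniform_pwm([[10], [0], [0], [0]])
        lo = pwm_to_logodds(pwm)
        assert lo[0, 0] == pytest.approx(2.0)  # log2(1 / 0.25)
        assert np.isneginf(lo[1, 0])

    def test_flat_column_scores_zero(self):
        pwm = uniform_pwm([[5], [5], [5], [5]])
        assert np.allclose(pwm_to_logodds(pwm), 0.0)

    def test_zero_column_with_zero_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            pwm_to_logodds(uniform_pwm([[0], [0], [0], [0]]))

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 50, (4, 6)).astype(float)
        pwm = Pwm("m", counts, pseudocount=0.25)
        lo = pwm_to_logodds(pwm)
        bg = 0.25
        for b in range(4):
            for j in range(6):
                expected = np.log2(
                    (counts[b, j] + 0.25 * bg) / (counts[:, j].sum() + 0.25) / bg
                )
                assert lo[b, j] == pytest.approx(expected)


class TestExactPvalues:
    def test_dinucleotide_enumeration(self):
        rng = np.random.default_rng(3)
        pwm = Pwm("m", rng.integers(1, 30, (4, 2)).astype(float), pseudocount=0.1)
        lo = pwm_to_logodds(pwm)
        null = exact_score_pvalues(lo, pwm.background)
        for b1 in range(4):
            for b2 in range(4):
                k = int(null.int_matrix[b1, 0] + null.int_matrix[b2, 1])
                p = null.pvalue_from_int(k)
                # oracle: fraction of the 16 dinucleotides with int score >= k
                count = sum(
                    1
                    for c1 in range(4)
                    for c2 in range(4)
                    if null.int_matrix[c1, 0] + null.int_matrix[c2, 1] >= k
                )
                assert p == pytest.approx(count / 16)

    def test_consensus_pvalue_is_background_product(self):
        pwm = uniform_pwm([[98, 98], [1, 1], [1, 1], [0, 0]], pseudocount=0.5)
        lo = pwm_to_logodds(pwm)
        null = exact_score_pvalues(lo, pwm.background)
        k = int(null.int_matrix[0, 0] + null.int_matrix[0, 1])
        assert null.pvalue_from_int(k) == pytest.approx(0.25**2)

    def test_minimum_score_has_p_one(self):
        rng = np.random.default_rng(5)
        pwm = Pwm("m", rng.integers(1, 20, (4, 4)).astype(float))
        null = exact_score_pvalues(pwm_to_logodds(pwm), pwm.background)
        assert null.pvalue_from_int(0) == pytest.approx(1.0)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(8)
        pwm = Pwm("m", rng.integers(0, 40, (4, 5)).astype(float))
        null = exact_score_pvalues(pwm_to_logodds(pwm), pwm.background)
        assert np.all(np.diff(null.sf) <= 1e-15)

    def test_length_guard(self):
        pwm = Pwm("m", np.ones((4, 26)))
        with pytest.raises(ValidationError, match="25"):
            exact_score_pvalues(pwm_to_logodds(pwm), pwm.background)

    @pytest.mark.parametrize("L", [1, 2, 3, 4])
    def test_dp_equals_kmer_enumeration(self, L):
        # exhaustive oracle over all 4^L words on the same integer grid
        rng = np.random.default_rng(10 + L)
        pwm = Pwm("m", rng.integers(0, 25, (4, L)).astype(float))
        null = exact_score_pvalues(pwm_to_logodds(pwm), pwm.background)
        scores = [
            sum(int(null.int_matrix[b, j]) for j, b in enumerate(word))
            for word in itertools.product(range(4), repeat=L)
        ]
        total = 4**L
        for k in sorted(set(scores)):
            expected = sum(1 for s in scores if s >= k) / total
            assert null.pvalue_from_int(k) == pytest.approx(expected, abs=1e-12)


class TestScanSequence:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        counts = np.full((4, 8), 2.0)
        consensus = "CAGTTGGT"
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 90.0
        pwm = Pwm("planted", counts)
        seq = "".join(rng.choice(list("ACGT"), 200))
        seq = seq[:7] + consensus + seq[7 + 8 :]
        return seq, pwm

    def test_planted_consensus_recovered_at_offset(self):
        seq, pwm = self._planted()
        hits = scan_sequence(seq, pwm)
        assert any(h.offset == 7 and h.strand == "+" for h in hits)
        best = min(hits, key=lambda h: h.p_value)
        assert best.offset == 7

    def test_palindromic_pwm_mirrors_strands(self):
        counts = np.zeros((4, 4))
        for j, b in enumerate("ACGT"):  # ACGT is its own reverse complement
            counts["ACGT".index(b), j] = 20.0
        counts += 1.0
        pwm = Pwm("pal", counts)
        hits = scan_sequence("GGACGTGG", pwm, p_max=1.0)
        by_strand = {s: {h.offset: h.score_bits for h in hits if h.strand == s} for s in "+-"}
        assert by_strand["+"].keys() == by_strand["-"].keys()
        for off in by_strand["+"]:
            assert by_strand["+"][off] == pytest.approx(by_strand["-"][off])

    def test_p_max_one_reports_every_window_twice(self):
        seq, pwm = self._planted(3)
        hits = scan_sequence(seq, pwm, p_max=1.0)
        assert len(hits) == 2 * (len(seq) - pwm.length + 1)

    def test_windows_with_n_skipped(self):
        seq, pwm = self._planted(4)
        seq = seq[:50] + "N" + seq[51:]
        hits = scan_sequence(seq, pwm, p_max=1.0)
        skipped = {off for off in range(50 - 7, 51)}
        assert all(h.offset not in skipped for h in hits)

    def test_empty_sequence(self):
        _, pwm = self._planted(5)
        assert scan_sequence("", pwm) == []

    def test_reverse_complement_reflects_hits(self):
        seq, pwm = self._planted(6)
        fwd = scan_sequence(seq, pwm, p_max=1.0)
        rev = scan_sequence(reverse_complement(seq), pwm, p_max=1.0)
        L = pwm.length
        flip = {"+": "-", "-": "+"}
        mapped = sorted(
            (len(seq) - h.offset - L, flip[h.strand], round(h.score_bits, 9))
            for h in rev
        )
        orig = sorted((h.offset, h.strand, round(h.score_bits, 9)) for h in fwd)
        assert mapped == orig


class TestJasparIO:
    def test_bracket_dialect(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0001.1 TEST\nA [ 10 2 ]\nC [ 0 8 ]\nG [ 5 5 ]\nT [ 1 1 ]\n")
        (pwm,) = read_jaspar(p)
        assert pwm.motif_id == "MA0001.1"
        assert pwm.counts[0, 0] == 10 and pwm.counts[3, 1] == 1

    def test_bare_dialect(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">m1\n10 2\n0 8\n5 5\n1 1\n")
        (pwm,) = read_jaspar(p)
        assert pwm.counts.shape == (4, 2) and pwm.counts[2, 0] == 5

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        pwm = Pwm("roundtrip", rng.integers(0, 99, (4, 7)).astype(float))
        path = tmp_path / "out.jaspar"
        write_jaspar([pwm], path)
        (back,) = read_jaspar(path)
        assert back.motif_id == "roundtrip"
        assert np.array_equal(back.counts, pwm.counts)
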