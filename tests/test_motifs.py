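"""PWM scanning and hypergeometric motif enrichment against exact oracles."""

import math

import numpy as np
import pytest

from atacatlas.motifs import (
    PWM,
    motif_enrichment,
    read_jaspar,
    reverse_complement,
    scan_sequence,
    select_background,
    top_motifs,
)

ACGT_POINT_MASS = PWM("acgt", np.eye(4))


def window_oracle_hits(seq, pwm, threshold):
    """Brute-force: score every window on both strands in pure Python."""
    L = len(pwm)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = set()
    for strand_seq, strand in ((seq, "+"), (reverse_complement(seq), "-")):
        for i in range(len(strand_seq) - L + 1):
            window = strand_seq[i : i + L]
            if "N" in window:
                continue
            score = 0.0
            for j, base in enumerate(window):
                p = pwm.probs[j, idx[base]]
                score += math.log2(p / 0.25) if p > 0 else -math.inf
            if score >= threshold:
                pos = i if strand == "+" else len(seq) - L - i
                hits.add(pos)
    return hits


def hypergeom_tail_oracle(k, M, K, n):
    """Exhaustive enumeration: P(X >= k) for X ~ Hypergeom(M, K, n)."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, x) * math.comb(M - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


class TestPWM:
    def test_position_probabilities_must_sum_to_one(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("bad", bad)

    def test_minimum_length(self):
        with pytest.raises(ValueError, match=">= 4"):
            PWM("short", np.full((3, 4), 0.25))

    def test_consensus_and_max_score(self):
        assert ACGT_POINT_MASS.consensus == "ACGT"
        assert ACGT_POINT_MASS.max_score() == pytest.approx(8.0)  # 4*log2(4)
        assert ACGT_POINT_MASS.threshold() == pytest.approx(4.8)

    def test_from_counts_pseudocount(self):
        counts = np.array([[10, 0, 0, 0]] * 4)
        pwm = PWM.from_counts("m", counts, pseudocount=0.5)
        assert pwm.probs[0, 0] == pytest.approx(10.5 / 12.0)


class TestScanSequence:
    def test_exact_match_plus_strand(self):
        hits = scan_sequence("AAACGTAA", ACGT_POINT_MASS, threshold=0.0)
        assert hits == [(2, "+")]

    def test_reverse_complement_hit(self):
        # ACGT on the minus strand: plus-strand sequence shows ACGT too
        # (palindrome), so use a non-palindromic motif
        probs = np.zeros((4, 4))
        for i, b in enumerate("AACG"):
            probs[i, "ACGT".index(b)] = 1.0
        pwm = PWM("aacg", probs)
        seq = "TT" + reverse_complement("AACG") + "TT"  # CGTT at offset 2
        hits = scan_sequence(seq, pwm, threshold=0.0)
        assert hits == [(2, "-")]

    def test_sequence_shorter_than_motif(self):
        assert scan_sequence("ACG", ACGT_POINT_MASS, threshold=0.0) == []

    def test_window_with_n_skipped(self):
        assert scan_sequence("AANGTAA", ACGT_POINT_MASS, threshold=0.0) == []

    def test_duplicate_position_reported_once_as_plus(self):
        # palindromic motif hits both strands at the same offset
        probs = np.zeros((4, 4))
        for i, b in enumerate("ACGT"):
            probs[i, "ACGT".index(b)] = 1.0
        hits = scan_sequence("AACGTA", PWM("pal", probs), threshold=0.0)
        assert hits == [(1, "+")]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_window_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        probs = rng.dirichlet([0.4] * 4, size=6)
        pwm = PWM(f"m{seed}", probs)
        thr = 0.5 * pwm.max_score()
        got = {pos for pos, _ in scan_sequence(seq, pwm, threshold=thr)}
        assert got == window_oracle_hits(seq, pwm, thr)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(20)]
        probs = rng.dirichlet([0.3] * 4, size=8)
        pwm = PWM("m", probs)
        thr = 0.55 * pwm.max_score()
        counts = [len(scan_sequence(s, pwm, threshold=thr)) for s in seqs]
        rc_counts = [
            len(scan_sequence(reverse_complement(s), pwm, threshold=thr))
            for s in seqs
        ]
        assert counts == rc_counts


class TestMotifEnrichment:
    def _hit_seq(self):
        return "AAACGTAA"  # contains ACGT

    def _miss_seq(self):
        return "AAAAAAAA"

    def test_null_case_not_significant(self):
        fg = {"liver": [self._hit_seq()] * 2 + [self._miss_seq()] * 2}
        bg = [self._hit_seq()] * 5 + [self._miss_seq()] * 5
        mat = motif_enrichment(fg, bg, [ACGT_POINT_MASS])
        assert mat.pvalues.loc["acgt", "liver"] > 0.3

    def test_exact_hypergeometric_tail(self):
        # 4 of 5 foreground positive vs 1 of 20 background positive
        fg = {"t": [self._hit_seq()] * 4 + [self._miss_seq()]}
        bg = [self._hit_seq()] + [self._miss_seq()] * 19
        mat = motif_enrichment(fg, bg, [ACGT_POINT_MASS])
        expected = hypergeom_tail_oracle(4, 25, 5, 5)
        assert mat.pvalues.loc["acgt", "t"] == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pools_match_enumeration(self, seed):
        rng = np.random.default_rng(300 + seed)
        n_fg = int(rng.integers(2, 10))
        n_bg = int(rng.integers(5, 21))
        fg_pos = int(rng.integers(0, n_fg + 1))
        bg_pos = int(rng.integers(0, n_bg + 1))
        fg = {"t": [self._hit_seq()] * fg_pos + [self._miss_seq()] * (n_fg - fg_pos)}
        bg = [self._hit_seq()] * bg_pos + [self._miss_seq()] * (n_bg - bg_pos)
        mat = motif_enrichment(fg, bg, [ACGT_POINT_MASS])
        expected = hypergeom_tail_oracle(
            fg_pos, n_fg + n_bg, fg_pos + bg_pos, n_fg
        )
        assert mat.pvalues.loc["acgt", "t"] == pytest.approx(expected, rel=1e-9)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        fg_seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(8)]
        bg_seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(20)]
        m1 = motif_enrichment({"t": fg_seqs}, bg_seqs, [ACGT_POINT_MASS])
        m2 = motif_enrichment(
            {"t": fg_seqs[::-1]}, bg_seqs[::-1], [ACGT_POINT_MASS]
        )
        assert m1.pvalues.equals(m2.pvalues)

    def test_empty_foreground_column_warns_nan(self):
        with pytest.warns(UserWarning, match="empty foreground"):
            mat = motif_enrichment(
                {"t": [self._hit_seq()], "empty": []},
                [self._miss_seq()] * 3,
                [ACGT_POINT_MASS],
            )
        assert np.isnan(mat.pvalues.loc["acgt", "empty"])
        assert not np.isnan(mat.pvalues.loc["acgt", "t"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment({}, ["A" * 8], [ACGT_POINT_MASS])
        with pytest.raises(ValueError):
            motif_enrichment({"t": ["A" * 8]}, [], [ACGT_POINT_MASS])


class TestTopMotifs:
    def _matrix(self, pvals):
        import pandas as pd

        from atacatlas.motifs import MotifEnrichmentMatrix

        df = pd.DataFrame(pvals)
        zeros = df * 0
        return MotifEnrichmentMatrix(
            df, zeros.astype(int), df.iloc[0] * 0 + 5, df.iloc[:, 0] * 0, 10
        )

    def test_unique_minimum(self):
        mat = self._matrix({"t": {"m1": 0.5, "m2": 0.01, "m3": 0.9}})
        assert top_motifs(mat, k=1) == {"t": ["m2"]}

    def test_tie_broken_lexicographically(self):
        mat = self._matrix({"t": {"mB": 0.5, "mA": 0.5, "mC": 0.1}})
        assert top_motifs(mat, k=2) == {"t": ["mC", "mA"]}

    def test_k_exceeding_count_returns_all(self):
        mat = self._matrix({"t": {"m1": 0.5, "m2": 0.2}})
        assert top_motifs(mat, k=15) == {"t": ["m2", "m1"]}

    def test_k_nonpositive_rejected(self):
        mat = self._matrix({"t": {"m1": 0.5}})
        with pytest.raises(ValueError):
            top_motifs(mat, k=0)


class TestJasparIO:
    JASPAR_TEXT = """\
>MA0001.1 TEST1
A [ 10  0  0 90 ]
C [ 80 10  0  0 ]
G [  5 80  0  5 ]
T [  5 10 100  5 ]
"""

    def test_read_counts_normalized(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(self.JASPAR_TEXT)
        (pwm,) = read_jaspar(p, pseudocount=0.0)
        assert len(pwm) == 4
        assert pwm.motif_id == "MA0001.1"
        assert pwm.probs[0].tolist() == pytest.approx([0.1, 0.8, 0.05, 0.05])
        assert pwm.consensus == "CGTA"

    def test_roundtrip_with_simulator_writer(self, tmp_path):
        from atacatlas.simulate import write_jaspar_pwms

        probs = np.full((6, 4), 0.01)
        probs[np.arange(6), [0, 1, 2, 3, 0, 1]] = 0.97
        write_jaspar_pwms([("M1", probs, "liver")], tmp_path / "m.jaspar")
        (pwm,) = read_jaspar(tmp_path / "m.jaspar")
        assert pwm.consensus == "ACGTAC"
        assert np.allclose(pwm.probs, probs, atol=1e-3)


class TestSelectBackground:
    def test_subsample_size_and_determinism(self):
        cands = [f"seq{i}" for i in range(100)]
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(1)
        s1 = select_background(cands, 4, multiple=5.0, rng=rng1)
        s2 = select_background(cands, 4, multiple=5.0, rng=rng2)
        assert s1 == s2 and len(s1) == 20

    def test_small_candidate_pool_returned_whole(self):
        cands = ["a", "b", "c"]
        assert select_background(cands, 10) == cands
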