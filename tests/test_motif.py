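import itertools
import math

import numpy as np
import pytest

from tratelis.motif import (
    PositionWeightMatrix,
    PromoterWindow,
    count_motif_hits,
    extract_promoters,
    information_weights,
    matsim_score,
    parse_motif_matrix,
    parse_motif_matrices,
    reverse_complement,
    scan_scores,
)

from conftest import write_bed

BASES = "ACGT"


def brute_force_matsim(freqs, window):
    """Direct evaluation of the matrix-similarity formula, independent of
    the vectorized scanner."""
    ci = []
    for row in freqs:
        h = sum(f * math.log(f) for f in row if f > 0)
        ci.append((100.0 / math.log(4)) * (h + math.log(4)))
    num = 0.0
    den = 0.0
    for i, base in enumerate(window):
        f = dict(zip(BASES, freqs[i])).get(base, 0.0)
        num += ci[i] * f
        den += ci[i] * max(freqs[i])
    return num / den


class TestParsing:
    def test_transfac_counts_normalized(self, transfac_file):
        m = parse_motif_matrix(transfac_file)
        assert m.motif_id == "V$TOY_01" and len(m) == 3
        np.testing.assert_allclose(m.freqs[0], [0.7, 0.1, 0.1, 0.1])
        np.testing.assert_allclose(m.freqs.sum(axis=1), 1.0)

    def test_jaspar_pfm(self, jaspar_file):
        m = parse_motif_matrix(jaspar_file)
        assert len(m) == 3
        np.testing.assert_allclose(m.freqs[2], [0.0, 0.0, 1.0, 0.0])

    def test_zero_count_row_is_an_error(self):
        with pytest.raises(ValueError, match="sum to 0"):
            PositionWeightMatrix.from_counts("bad", [[1, 1, 1, 1], [0, 0, 0, 0]])

    def test_malformed_file_is_an_error(self, tmp_path):
        path = tmp_path / "junk.transfac"
        path.write_text("ID broken\nP0 A C G T\n01 x y z w\n//\n")
        with pytest.raises(ValueError):
            parse_motif_matrices(path)

    def test_pseudocount_fills_zeros(self, transfac_file):
        m = parse_motif_matrix(transfac_file, pseudocount=1.0)
        assert (m.freqs > 0).all()


class TestInformationWeights:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1, 0, 0, 0], 100.0),           # invariant position
            ([0.25, 0.25, 0.25, 0.25], 0.0),  # maximum entropy
            ([0.5, 0.5, 0, 0], 50.0),         # (100/ln4)(ln4 − ln2)
        ],
    )
    def test_hand_computed_values(self, row, expected):
        assert information_weights([row])[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_iff_uniform(self):
        rng = np.random.default_rng(5)
        f = rng.dirichlet([1, 1, 1, 1], size=20)
        ci = information_weights(f)
        assert (ci > 0).all()  # dirichlet draws are never exactly uniform
        assert (ci <= 100).all()


class TestMatsimScore:
    def test_toy_examples(self):
        pwm = PositionWeightMatrix.from_frequencies(
            "toy", [[1, 0, 0, 0], [0.5, 0.5, 0, 0]])
        assert matsim_score(pwm, "AG") == pytest.approx(0.8)
        assert matsim_score(pwm, "AC") == pytest.approx(1.0)
        assert matsim_score(pwm, "AA") == pytest.approx(1.0)

    def test_consensus_scores_one(self):
        rng = np.random.default_rng(9)
        f = rng.dirichlet([0.5] * 4, size=5)
        pwm = PositionWeightMatrix.from_frequencies("r", f)
        consensus = "".join(BASES[i] for i in f.argmax(axis=1))
        assert matsim_score(pwm, consensus) == pytest.approx(1.0)

    def test_n_contributes_zero_frequency(self):
        pwm = PositionWeightMatrix.from_frequencies(
            "toy", [[1, 0, 0, 0], [0.5, 0.5, 0, 0]])
        assert matsim_score(pwm, "NG") == pytest.approx(0.0)
        assert matsim_score(pwm, "AN") == pytest.approx(0.8)

    def test_uniform_matrix_is_undefined(self):
        pwm = PositionWeightMatrix.from_frequencies("u", [[0.25] * 4] * 3)
        with pytest.raises(ValueError, match="undefined"):
            matsim_score(pwm, "ACG")

    def test_matches_brute_force_over_all_windows(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            L = int(rng.integers(2, 5))
            f = rng.dirichlet([0.7] * 4, size=L)
            pwm = PositionWeightMatrix.from_frequencies("r", f)
            for window in itertools.product(BASES, repeat=L):
                w = "".join(window)
                assert matsim_score(pwm, w) == pytest.approx(
                    brute_force_matsim(f, w), abs=1e-12)


class TestCountMotifHits:
    @pytest.fixture
    def aa_pwm(self):
        return PositionWeightMatrix.from_consensus("AA", "AA")

    def test_forward_hits_only(self, aa_pwm):
        # "AAA" has two forward AA windows; reverse complement TTT has none
        assert count_motif_hits(aa_pwm, "AAA", 1.0) == 2

    def test_reverse_strand_hits(self, aa_pwm):
        assert count_motif_hits(aa_pwm, "CC", 1.0) == 0
        assert count_motif_hits(aa_pwm, "TT", 1.0) == 1   # the revcomp window AA
        assert count_motif_hits(aa_pwm, "TTT", 1.0) == 2  # revcomp AAA, two windows

    def test_sequence_shorter_than_motif(self, aa_pwm):
        assert count_motif_hits(aa_pwm, "A", 1.0) == 0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(21)
        pwm = PositionWeightMatrix.from_frequencies(
            "r", rng.dirichlet([0.6] * 4, size=4))
        for _ in range(20):
            seq = "".join(rng.choice(list(BASES), size=30))
            for thr in (0.8, 0.9, 0.95):
                assert (count_motif_hits(pwm, seq, thr)
                        == count_motif_hits(pwm, reverse_complement(seq), thr))

    def test_hits_non_increasing_in_threshold(self):
        rng = np.random.default_rng(22)
        pwm = PositionWeightMatrix.from_frequencies(
            "r", rng.dirichlet([0.6] * 4, size=4))
        seq = "".join(rng.choice(list(BASES), size=200))
        counts = [count_motif_hits(pwm, seq, t)
                  for t in (0.5, 0.7, 0.8, 0.9, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_scan_matches_per_window_scoring(self):
        rng = np.random.default_rng(23)
        pwm = PositionWeightMatrix.from_frequencies(
            "r", rng.dirichlet([0.6] * 4, size=3))
        seq = "".join(rng.choice(list(BASES), size=40))
        scores = scan_scores(pwm, seq)
        expected = [matsim_score(pwm, seq[i:i + 3]) for i in range(len(seq) - 2)]
        np.testing.assert_allclose(scores, expected, atol=1e-12)


class TestExtractPromoters:
    def test_plus_strand_hand_indexed(self, tmp_path, tiny_genome):
        # chrA = ACGTACGTACGTACGTACGT; TSS at 10, window (3,0) → positions 7..9
        bed = write_bed(tmp_path, [("chrA", 10, 15, "gA", 0, "+")])
        pset = extract_promoters(bed, tiny_genome, PromoterWindow(3, 0))
        assert pset.records["gA"].sequence == "TAC"

    def test_minus_strand_reverse_complement(self, tmp_path, tiny_genome):
        # chrB = AAAACCCGGT; − strand TSS base at index 3 (BED end 4);
        # upstream window is genomic [4,6) = "CC" → reverse-complemented "GG"
        bed = write_bed(tmp_path, [("chrB", 0, 4, "gB", 0, "-")])
        pset = extract_promoters(bed, tiny_genome, PromoterWindow(2, 0))
        assert pset.records["gB"].sequence == "GG"

    def test_truncation_at_contig_edge(self, tmp_path, tiny_genome):
        bed = write_bed(tmp_path, [("chrA", 1, 5, "gA", 0, "+")])
        pset = extract_promoters(bed, tiny_genome, PromoterWindow(300, 0))
        rec = pset.records["gA"]
        assert rec.truncated and rec.sequence == "A"

    def test_unknown_contig_is_an_error(self, tmp_path, tiny_genome):
        bed = write_bed(tmp_path, [("chrZ", 0, 5, "gZ", 0, "+")])
        with pytest.raises(ValueError, match="chrZ"):
            extract_promoters(bed, tiny_genome, PromoterWindow(3, 0))

    def test_missing_strand_is_an_error(self, tmp_path, tiny_genome):
        bed = write_bed(tmp_path, [("chrA", 0, 5, "gA", 0, ".")])
        with pytest.raises(ValueError, match="strand"):
            extract_promoters(bed, tiny_genome, PromoterWindow(3, 0))

    def test_multiple_tss_keeps_most_upstream(self, tmp_path, tiny_genome):
        bed = write_bed(tmp_path, [("chrA", 10, 15, "gA", 0, "+"),
                                   ("chrA", 6, 15, "gA", 0, "+")])
        pset = extract_promoters(bed, tiny_genome, PromoterWindow(3, 0))
        # 5'-most TSS on + strand is position 6 → window [3,6) = "TAC"
        assert pset.records["gA"].start == 3

    def test_trimmed_window_slices_at_tss(self, tmp_path, tiny_genome):
        bed = write_bed(tmp_path, [("chrA", 10, 15, "gA", 0, "+")])
        full = extract_promoters(bed, tiny_genome, PromoterWindow(6, 2))
        small = full.trimmed(PromoterWindow(3, 0))
        assert small.records["gA"].sequence == "TAC"
        with pytest.raises(ValueError):
            full.trimmed(PromoterWindow(1000, 0))
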