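"""Matrix parsing, information-weighted scoring, calibration and scanning."""

import io

import numpy as np
import pandas as pd
import pytest

from adipodiff import pwm
from adipodiff.pwm import (PwmModel, calibrate_threshold, core_similarity,
                           dr1_annotate, extract_promoter_regions,
                           information_weights, matrix_similarity, parse_pfm,
                           pfm_to_frequencies, read_pfms, reverse_complement,
                           scan_region, scan_sequence)

from conftest import matrix_from_columns, planted_matrix, uniform_background

TRANSFAC_TEXT = """\
ID M_TEST
NA TestFactor
P0      A      C      G      T
01      4      0      0      0
02      0      4      0      0
03      3      1      0      0
XX
//
"""

JASPAR_TEXT = """\
>M_TEST TestFactor
A [ 4 0 3 ]
C [ 0 4 1 ]
G [ 0 0 0 ]
T [ 0 0 0 ]
"""


class TestParsing:
    def test_jaspar_single_position(self):
        m = parse_pfm(io.StringIO(">M1\nA [4]\nC [0]\nG [0]\nT [0]\n"), "JASPAR")
        assert m.counts.shape == (4, 1)
        np.testing.assert_array_equal(m.counts[:, 0], [4, 0, 0, 0])

    def test_transfac_and_jaspar_encode_same_matrix(self):
        mt = parse_pfm(io.StringIO(TRANSFAC_TEXT), "TRANSFAC")
        mj = parse_pfm(io.StringIO(JASPAR_TEXT), "JASPAR")
        np.testing.assert_array_equal(mt.counts, mj.counts)
        np.testing.assert_allclose(mt.freqs, mj.freqs)
        assert mt.matrix_id == mj.matrix_id == "M_TEST"

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError):
            read_pfms(io.StringIO(""), "JASPAR")

    def test_ragged_jaspar_rejected(self):
        text = ">M1\nA [4 1]\nC [0]\nG [0 0]\nT [0 0]\n"
        with pytest.raises(ValueError, match="ragged"):
            read_pfms(io.StringIO(text), "JASPAR")

    def test_unknown_base_row_rejected_with_line(self):
        text = ">M1\nA [4]\nC [0]\nG [0]\nX [0]\n"
        with pytest.raises(ValueError, match="line 5"):
            read_pfms(io.StringIO(text), "JASPAR")


class TestFrequenciesAndWeights:
    @pytest.mark.parametrize("column, pc, expected", [
        ([4, 0, 0, 0], 0.0, [1, 0, 0, 0]),
        ([1, 1, 1, 1], 0.0, [0.25, 0.25, 0.25, 0.25]),
        ([3, 1, 0, 0], 1.0, [0.5, 0.25, 0.125, 0.125]),
    ])
    def test_frequency_arithmetic(self, column, pc, expected):
        counts = np.array(column, dtype=float)[:, None]
        np.testing.assert_allclose(pfm_to_frequencies(counts, pc)[:, 0], expected)

    def test_zero_column_needs_pseudocount(self):
        with pytest.raises(ValueError):
            pfm_to_frequencies(np.zeros((4, 1)), 0.0)

    def test_conservation_weight_closed_forms(self):
        f = np.array([[1.0, 0.25, 0.5],
                      [0.0, 0.25, 0.5],
                      [0.0, 0.25, 0.0],
                      [0.0, 0.25, 0.0]])
        np.testing.assert_allclose(information_weights(f), [100.0, 0.0, 50.0])


class TestSimilarity:
    def make_hand_model(self):
        # f columns (1,0,0,0), (.5,.5,0,0), uniform -> ci = (100, 50, 0)
        m = matrix_from_columns("HAND", [[100, 0, 0, 0], [50, 50, 0, 0],
                                         [25, 25, 25, 25]])
        m.freqs = np.array([[1.0, 0.5, 0.25], [0.0, 0.5, 0.25],
                            [0.0, 0.0, 0.25], [0.0, 0.0, 0.25]])
        m.ci = information_weights(m.freqs)
        return m

    def test_hand_computed_scores(self):
        m = self.make_hand_model()
        np.testing.assert_allclose(m.ci, [100.0, 50.0, 0.0])
        assert matrix_similarity(m, "ACA") == pytest.approx(1.0)
        assert matrix_similarity(m, "AGA") == pytest.approx(0.8)

    def test_consensus_scores_one(self, kink8):
        assert matrix_similarity(kink8, kink8.consensus()) == pytest.approx(1.0)

    def test_all_mismatch_scores_zero(self):
        m = matrix_from_columns("M", [[100, 0, 0, 0]] * 4)
        # pseudocounts keep the score slightly above 0
        assert matrix_similarity(m, "TTTT") < 0.005

    def test_n_contributes_zero(self, strong8):
        full = matrix_similarity(strong8, strong8.consensus())
        with_n = matrix_similarity(strong8, "N" + strong8.consensus()[1:])
        assert with_n < full

    def test_length_mismatch_rejected(self, strong8):
        with pytest.raises(ValueError):
            matrix_similarity(strong8, "ACG")

    def test_score_bounds_on_random_windows(self, kink8):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = "".join(rng.choice(list("ACGT"), size=kink8.length))
            assert 0.0 <= matrix_similarity(kink8, w) <= 1.0


class TestCoreSimilarity:
    def test_consensus_core_is_one(self, kink8):
        assert core_similarity(kink8, kink8.consensus()) == pytest.approx(1.0)

    def test_short_matrix_core_equals_full(self):
        m = matrix_from_columns("M", [[90, 4, 3, 3]] * 3)
        w = "ACA"
        assert core_similarity(m, w) == pytest.approx(matrix_similarity(m, w))

    def test_mismatch_outside_core_only(self):
        # conserved first 4 positions form the core; position 5 is weak
        m = matrix_from_columns("M", [[97, 1, 1, 1]] * 4 + [[40, 30, 20, 10]])
        assert set(m.core) == {0, 1, 2, 3}
        w = "AAAA" + "T"
        assert core_similarity(m, w) == pytest.approx(1.0)
        assert matrix_similarity(m, w) < 1.0


class TestScanning:
    def test_planted_consensus_hit(self, strong8):
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("ACGT"), size=300)))
        cons = strong8.consensus()
        seq[100:108] = cons
        hits = scan_sequence(strong8, "".join(seq), threshold=0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.start == 100 and h.end == 108 and
                   h.score == pytest.approx(1.0) for h in plus)

    def test_minus_strand_hit_same_interval(self, strong8):
        rng = np.random.default_rng(2)
        seq = list("".join(rng.choice(list("ACGT"), size=300)))
        seq[100:108] = reverse_complement(strong8.consensus())
        hits = scan_sequence(strong8, "".join(seq), threshold=0.99)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.start == 100 and h.end == 108 for h in minus)

    def test_strand_symmetry(self, kink8):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = scan_sequence(kink8, seq, threshold=0.6)
        rev = scan_sequence(kink8, reverse_complement(seq), threshold=0.6)
        n = len(seq)
        mirrored = sorted((n - h.end, n - h.start, "-" if h.strand == "+" else "+",
                           round(h.score, 12)) for h in rev)
        original = sorted((h.start, h.end, h.strand, round(h.score, 12)) for h in fwd)
        assert mirrored == original

    def test_threshold_required(self, strong8):
        strong8.threshold = None
        with pytest.raises(ValueError, match="threshold"):
            scan_sequence(strong8, "ACGTACGTACGT")


class TestCalibration:
    def test_cap_with_warning_for_weak_matrix(self, weak6):
        rng = np.random.default_rng(7)
        bg = uniform_background(rng, 50_000)
        with pytest.warns(UserWarning, match="capped"):
            threshold, achieved = calibrate_threshold(weak6, bg)
        assert threshold == 1.0

    def test_doubling_rate_never_increases_threshold(self, kink8):
        rng = np.random.default_rng(8)
        bg = uniform_background(rng, 200_000)
        t1, _ = calibrate_threshold(kink8, bg, rate=1e-4)
        t2, _ = calibrate_threshold(kink8, bg, rate=2e-4)
        assert t2 <= t1

    def test_achieved_rate_below_target(self, strong8):
        rng = np.random.default_rng(9)
        bg = uniform_background(rng, 300_000)
        threshold, achieved = calibrate_threshold(strong8, bg, rate=1e-4)
        assert achieved <= 1e-4
        assert 0.0 < threshold <= 1.0

    def test_short_background_rejected(self, strong8):
        with pytest.raises(ValueError, match="too short"):
            calibrate_threshold(strong8, ["ACGT" * 10])

    def test_per_strand_rate_lowers_threshold_or_equal(self, kink8):
        rng = np.random.default_rng(10)
        bg = uniform_background(rng, 200_000)
        t_base, _ = calibrate_threshold(kink8, bg, rate=1e-4, per_strand=False)
        t_strand, _ = calibrate_threshold(kink8, bg, rate=1e-4, per_strand=True)
        assert t_strand <= t_base


class TestPromoterRegions:
    def make_genome(self, n=1_000_000):
        rng = np.random.default_rng(12)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}

    def test_plus_strand_interval(self):
        genome = self.make_genome(20_000)
        tss = pd.DataFrame([("g1", "chr1", 10_000, "+")],
                           columns=["gene", "chrom", "tss", "strand"])
        (r,) = extract_promoter_regions(tss, genome)
        assert (r.start, r.end) == (7000, 12_000)
        assert r.sequence == genome["chr1"][7000:12_000]
        assert not r.clipped

    def test_minus_strand_mirror(self):
        genome = self.make_genome(20_000)
        tss = pd.DataFrame([("g1", "chr1", 10_000, "-")],
                           columns=["gene", "chrom", "tss", "strand"])
        (r,) = extract_promoter_regions(tss, genome)
        assert (r.start, r.end) == (8000, 13_000)
        assert r.sequence == reverse_complement(genome["chr1"][8000:13_000])

    def test_clipping_flagged(self):
        genome = self.make_genome(20_000)
        tss = pd.DataFrame([("g1", "chr1", 1000, "+")],
                           columns=["gene", "chrom", "tss", "strand"])
        (r,) = extract_promoter_regions(tss, genome)
        assert r.clipped and len(r) == 3000 and r.start == 0

    def test_unknown_chromosome(self):
        tss = pd.DataFrame([("g1", "chrX", 10, "+")],
                           columns=["gene", "chrom", "tss", "strand"])
        with pytest.raises(KeyError, match="chrX"):
            extract_promoter_regions(tss, {"chr1": "ACGT" * 100})

    def test_genomic_projection_minus_strand(self, strong8):
        # plant the consensus on the gene-oriented (region) sequence and
        # check the genomic interval maps back through the projection
        genome = self.make_genome(30_000)
        tss = pd.DataFrame([("g1", "chr1", 10_000, "-")],
                           columns=["gene", "chrom", "tss", "strand"])
        (r,) = extract_promoter_regions(tss, genome)
        seq = list(r.sequence)
        seq[200:208] = strong8.consensus()
        r.sequence = "".join(seq)
        hits = [h for h in scan_region(strong8, r, threshold=0.99)
                if h.start == 200 and h.strand == "+"]
        assert hits
        h = hits[0]
        # region coord 200 on a '-' gene lies near the downstream (genomic
        # high) end of [8000, 13000)
        assert (h.genomic_start, h.genomic_end) == (13_000 - 208, 13_000 - 200)


class TestDr1Annotation:
    def test_strictly_above_cutoff(self, kink8):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        region = pwm.PromoterRegion("g1", "chr1", 0, "+", 0, len(seq), seq)
        hits = dr1_annotate([region], kink8, min_score=0.90)
        assert all(h.score > 0.90 for h in hits)

    def test_score_exactly_at_cutoff_excluded(self):
        m = matrix_from_columns("DR1", [[100, 0, 0, 0]] * 4)
        seq = m.consensus() * 3
        region = pwm.PromoterRegion("g1", "chr1", 0, "+", 0, len(seq), seq)
        cons_hits = dr1_annotate([region], m, min_score=0.90)
        assert cons_hits  # consensus included
        at_one = dr1_annotate([region], m, min_score=1.0)
        assert not [h for h in at_one if h.score == 1.0]

    def test_counts_match_brute_force_rescore(self, kink8):
        rng = np.random.default_rng(14)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        region = pwm.PromoterRegion("g1", "chr1", 0, "+", 0, len(seq), seq)
        hits = dr1_annotate([region], kink8, min_score=0.75)
        L = kink8.length
        brute = 0
        for p in range(len(seq) - L + 1):
            win = seq[p:p + L]
            brute += matrix_similarity(kink8, win) > 0.75
            brute += matrix_similarity(kink8, reverse_complement(win)) > 0.75
        assert len(hits) == brute
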