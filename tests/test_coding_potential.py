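import numpy as np
import pytest

from scnovel import coding_potential as cp
from scnovel import synthetic_fixtures as sf

from _oracles import oracle_longest_orf
from conftest import make_transcript


class TestExtractSequence:
    GENOME = {"chr1": "ACGTTTGGCCAATTCCGG"}

    def test_plus_strand_single_exon(self):
        t = make_transcript("t", "chr1", "+", [(0, 4)])
        assert cp.extract_sequence(t, self.GENOME) == "ACGT"

    def test_minus_strand_palindrome(self):
        t = make_transcript("t", "chr1", "-", [(0, 4)])
        # revcomp("ACGT") is itself
        assert cp.extract_sequence(t, self.GENOME) == "ACGT"

    def test_minus_strand_equals_revcomp_of_plus_splice(self):
        rng = np.random.default_rng(2)
        genome = {"chrX": sf.random_sequence(rng, 3000)}
        exons = [(100, 400), (900, 1400)]
        plus = make_transcript("p", "chrX", "+", exons)
        minus = make_transcript("m", "chrX", "-", exons)
        assert cp.extract_sequence(minus, genome) == cp.reverse_complement(
            cp.extract_sequence(plus, genome)
        )

    def test_exon_beyond_chrom_end_errors(self):
        t = make_transcript("t", "chr1", "+", [(10, 100)])
        with pytest.raises(ValueError, match="beyond"):
            cp.extract_sequence(t, self.GENOME)


class TestOrfFinder:
    def test_no_atg_gives_zero(self):
        orf = cp.find_longest_orf("CCCCCC")
        assert orf.orf_length == 0 and not orf.has_stop

    def test_simple_orf(self):
        orf = cp.find_longest_orf("ATGAAATGA")
        assert orf.orf_length == 9
        assert orf.orf_coverage == pytest.approx(1.0)
        assert orf.has_stop and orf.frame == 0

    def test_frame_shifted_orf(self):
        orf = cp.find_longest_orf("NATGAAATGA")
        assert orf.orf_length == 9
        assert orf.frame == 1
        assert orf.orf_coverage == pytest.approx(0.9)

    def test_orf_length_multiple_of_three_when_stopped(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            orf = cp.find_longest_orf(sf.random_sequence(rng, 600))
            if orf.has_stop:
                assert orf.orf_length % 3 == 0

    def test_agrees_with_enumeration_oracle(self):
        """Exhaustive (start, frame) enumeration on 1,000 random
        sequences of length 50-2,000."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            seq = sf.random_sequence(rng, int(rng.integers(50, 2000)))
            got = cp.find_longest_orf(seq)
            want_len, want_start = oracle_longest_orf(seq)
            assert (got.orf_length, got.start if got.orf_length else -1) == (
                want_len,
                want_start,
            )

    def test_open_ended_option(self):
        seq = "ATGAAAAAAAA"  # no stop
        assert cp.find_longest_orf(seq).orf_length == 0
        orf = cp.find_longest_orf(seq, allow_open_ended=True)
        assert orf.orf_length == 9 and not orf.has_stop


class TestFickett:
    def test_polya_position_parameter(self):
        seq = "A" * 60
        assert cp.fickett_position_parameter(seq, "A") == pytest.approx(20 / 21)
        score = cp.fickett_score(seq + "A" * 140)  # length >= 200, no warning path
        # independent table lookup: max/(min+1) = 66/67 < 1.1 -> last bin
        expected = sum(
            cp._POSITION_WEIGHT[b] * cp._POSITION_PROB[b][-1] for b in "ACGT"
        )
        expected += cp._CONTENT_WEIGHT["A"] * cp._CONTENT_PROB["A"][0]
        expected += sum(cp._CONTENT_WEIGHT[b] * cp._CONTENT_PROB[b][-1] for b in "CGT")
        assert score == pytest.approx(expected)

    def test_duplication_preserves_content_percentages(self):
        rng = np.random.default_rng(9)
        seq = sf.random_sequence(rng, 300)
        for base in "ACGT":
            assert cp.fickett_content_parameter(seq, base) == pytest.approx(
                cp.fickett_content_parameter(seq + seq, base)
            )

    def test_case_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            seq = sf.random_sequence(rng, 300)
            assert cp.fickett_score(seq) == cp.fickett_score(seq.lower())

    def test_parameters_match_direct_counting(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            seq = sf.random_sequence(rng, int(rng.integers(200, 600)))
            for base in "ACGT":
                counts = [seq[i::3].count(base) for i in range(3)]
                assert cp.fickett_position_parameter(seq, base) == pytest.approx(
                    max(counts) / (min(counts) + 1)
                )
                assert cp.fickett_content_parameter(seq, base) == pytest.approx(
                    seq.count(base) / len(seq)
                )

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            cp.fickett_score("ACGU" * 100)


class TestHexamer:
    def test_zero_table_scores_zero(self):
        table = np.zeros(4096)
        assert cp.hexamer_bias_score("ATGAAAAAATGA", table) == 0.0

    def test_no_orf_scores_zero(self):
        table = np.ones(4096)
        assert cp.hexamer_bias_score("CCCCCCCCCC", table) == 0.0

    def test_trained_table_separates_classes(self):
        coding, noncoding = sf.make_training_set(60, seed=21)
        table = cp.train_hexamer_table(coding, noncoding)
        c_test, n_test = sf.make_training_set(60, seed=22)
        c_scores = [cp.hexamer_bias_score(s, table) for s in c_test]
        n_scores = [cp.hexamer_bias_score(s, table) for s in n_test]
        assert np.mean(c_scores) > np.mean(n_scores)


class TestCombiner:
    def test_zero_weights_give_half(self):
        orf = cp.find_longest_orf("ATGAAATGA")
        call = cp.combine_coding_features(orf, 0.9, 1.2, np.zeros(5))
        assert call.score == pytest.approx(0.5)
        assert call.label == "coding"  # score >= default cutoff 0.5

    def test_monotone_in_orf_coverage(self):
        weights = np.array([-1.0, 2.0, 0.5, 1.0, 1.0])
        scores = [
            cp.combine_coding_features(
                cp.OrfResult(300, cov, 0, True, 0), 0.8, 0.5, weights
            ).score
            for cov in np.linspace(0, 1, 11)
        ]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_fixture_trained_predictors_separate_classes(self):
        """>= 90% accuracy on held-out planted coding/noncoding."""
        coding, noncoding = sf.make_training_set(250, seed=31)
        predictors = cp.train_predictors(coding, noncoding)
        c_test, n_test = sf.make_training_set(250, seed=32)
        for p in predictors:
            correct = sum(p(s).label == "coding" for s in c_test) + sum(
                p(s).label == "noncoding" for s in n_test
            )
            assert correct / (len(c_test) + len(n_test)) >= 0.9


class TestConsensusGate:
    EXPRESSED = cp.ExpressionStats(max_cpm=5.0, n_cells_detected=10)
    SILENT = cp.ExpressionStats(max_cpm=0.2, n_cells_detected=1)

    @staticmethod
    def calls(*labels):
        return [
            cp.CodingCall(f"p{i}", lab, 0.9 if lab == "coding" else 0.1)
            for i, lab in enumerate(labels)
        ]

    def test_unanimous_coding_expressed(self):
        v = cp.consensus_gate("t", self.calls("coding", "coding", "coding"), 800, self.EXPRESSED)
        assert v.verdict == "unannotated_coding"

    def test_unanimous_noncoding_long_expressed_is_lncrna(self):
        v = cp.consensus_gate(
            "t", self.calls("noncoding", "noncoding", "noncoding"), 250, self.EXPRESSED
        )
        assert v.verdict == "unannotated_lncRNA"

    def test_mixed_votes_ambiguous(self):
        v = cp.consensus_gate(
            "t", self.calls("coding", "noncoding", "noncoding"), 800, self.EXPRESSED
        )
        assert v.verdict == "ambiguous"

    @pytest.mark.parametrize("length,verdict", [(150, "excluded_short"), (200, "excluded_short"), (201, "unannotated_lncRNA")])
    def test_length_boundary_strictly_greater_than_200(self, length, verdict):
        v = cp.consensus_gate("t", self.calls("noncoding",) * 3, length, self.EXPRESSED)
        assert v.verdict == verdict

    def test_low_expression_excluded(self):
        v = cp.consensus_gate("t", self.calls("noncoding",) * 3, 500, self.SILENT)
        assert v.verdict == "excluded_low_expression"

    def test_empty_calls_error(self):
        with pytest.raises(ValueError, match="empty"):
            cp.consensus_gate("t", [], 500, self.EXPRESSED)

    def test_verdicts_partition_fixture(self, small_fixture):
        from scnovel import classifier as cl

        index = cl.build_annotation_index(small_fixture.reference)
        records = cl.classify_assembly(small_fixture.assembly, index)
        parts = cl.partition_assembly(records)
        unann = [t for t in small_fixture.assembly if t.transcript_id in parts["unannotated"]]
        table = cp.gate_assembly(unann, small_fixture.genome, matrix=small_fixture.matrix)
        assert len(table) == len(unann)
        assert table["verdict"].isin(cp.VERDICTS).all()
        # unanimity consistency: verdicts vs vote counts
        unanimous_non = table[table["n_coding_votes"] == 0]
        long_expressed = unanimous_non[
            (unanimous_non["length"] > 200)
            & (unanimous_non["max_cpm"] >= 1.0)
            & (unanimous_non["n_cells_detected"] >= 3)
        ]
        assert (long_expressed["verdict"] == "unannotated_lncRNA").all()
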