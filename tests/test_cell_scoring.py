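import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnovel import cell_scoring as cs

from _oracles import oracle_pair_auc
from conftest import make_matrix


def single_cell_matrix(values, features=None):
    return make_matrix(np.asarray(values, dtype=float)[:, None], features=features)


def gene_set(*members):
    return cs.GeneSet("G", frozenset(members))


class TestNovelScoreFullIntegral:
    def test_set_at_top_gives_one(self):
        mat = single_cell_matrix([10, 9, 1, 0.5, 0.1])
        (res,) = cs.novel_score(mat, gene_set("T1", "T2"))
        assert res.auc == pytest.approx(1.0)

    def test_single_member_ranked_last_gives_zero(self):
        mat = single_cell_matrix([10, 9, 8, 7, 0.0])
        (res,) = cs.novel_score(mat, gene_set("T5"))
        assert res.auc == pytest.approx(0.0)

    def test_five_gene_worked_example(self):
        # ranking best->worst g1..g5, G = {g1, g3} -> 5/6
        mat = single_cell_matrix([50, 40, 30, 20, 10])
        (res,) = cs.novel_score(mat, gene_set("T1", "T3"))
        assert res.auc == pytest.approx(5 / 6)

    def test_all_ties_give_half(self):
        mat = single_cell_matrix([3, 3, 3, 3, 3, 3])
        (res,) = cs.novel_score(mat, gene_set("T2", "T5"))
        assert res.auc == pytest.approx(0.5)

    def test_equals_pair_counting_oracle(self):
        """Exact (1e-12) agreement with concordant-pair counting on
        1,000 random expression vectors with random member sets."""
        rng = np.random.default_rng(19)
        for _ in range(1000):
            n = int(rng.integers(5, 60))
            vals = np.round(rng.random(n) * 10, 1)  # ties likely
            n_g = int(rng.integers(1, n))
            members = rng.choice(n, size=n_g, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[members] = True
            mat = single_cell_matrix(vals)
            gs = cs.GeneSet("G", frozenset(f"T{i + 1}" for i in members))
            (res,) = cs.novel_score(mat, gs)
            assert res.auc == pytest.approx(oracle_pair_auc(vals, mask), abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(20)
        vals = rng.random(30)
        members = [f"T{i + 1}" for i in range(30) if rng.random() < 0.4] or ["T1"]
        comp = [f"T{i + 1}" for i in range(30) if f"T{i + 1}" not in members]
        mat = single_cell_matrix(vals)
        (a,) = cs.novel_score(mat, cs.GeneSet("G", frozenset(members)))
        (b,) = cs.novel_score(mat, cs.GeneSet("Gc", frozenset(comp)))
        assert a.auc + b.auc == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(21)
        vals = rng.random(40) * 5
        mat1 = single_cell_matrix(vals)
        mat2 = single_cell_matrix(np.expm1(vals) + 2)  # strictly monotone
        gs = gene_set("T3", "T7", "T22")
        (a,) = cs.novel_score(mat1, gs)
        (b,) = cs.novel_score(mat2, gs)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        mat = single_cell_matrix([1, 2, 3])
        with pytest.raises(ValueError, match="none or all"):
            cs.novel_score(mat, gene_set("T1", "T2", "T3"))
        with pytest.raises(ValueError, match="none or all"):
            with pytest.warns(UserWarning, match="absent"):
                cs.novel_score(mat, gene_set("missing"))

    def test_missing_members_dropped_with_warning(self):
        mat = single_cell_matrix([5, 1, 0.5])
        with pytest.warns(UserWarning, match="1 member"):
            (res,) = cs.novel_score(mat, gene_set("T1", "nope"))
        assert res.auc == pytest.approx(1.0)


class TestTopFractionMode:
    def test_f_one_equals_full_integral(self):
        rng = np.random.default_rng(22)
        for _ in range(200):
            n = int(rng.integers(6, 80))
            vals = rng.permutation(n).astype(float)
            n_g = int(rng.integers(1, n))
            members = [f"T{i + 1}" for i in rng.choice(n, size=n_g, replace=False)]
            mat = single_cell_matrix(vals)
            gs = cs.GeneSet("G", frozenset(members))
            (full,) = cs.novel_score(mat, gs, mode="full_integral")
            (top,) = cs.novel_score(mat, gs, mode="top_fraction", top_fraction=1.0)
            assert top.auc == pytest.approx(full.auc, abs=1e-12)

    def test_top_fraction_bounds_and_extremes(self):
        mat = single_cell_matrix(np.arange(100, 0, -1))
        top_set = gene_set(*[f"T{i + 1}" for i in range(5)])
        (res,) = cs.novel_score(mat, top_set, mode="top_fraction", top_fraction=0.05)
        assert res.auc == pytest.approx(1.0)
        bottom_set = gene_set(*[f"T{i + 1}" for i in range(95, 100)])
        (res2,) = cs.novel_score(mat, bottom_set, mode="top_fraction", top_fraction=0.05)
        assert res2.auc == pytest.approx(0.0)
        assert res2.mode == "top_fraction(0.05)"


class TestExploreThresholds:
    def test_bimodal_mixture_crossing(self):
        """Two planted modes N(0.2, 0.02) and N(0.8, 0.02), 200 cells
        each: crossing in (0.4, 0.6), assignment accuracy >= 0.99."""
        rng = np.random.default_rng(30)
        low = rng.normal(0.2, 0.02, 200)
        high = rng.normal(0.8, 0.02, 200)
        scores = np.concatenate([low, high])
        truth = np.concatenate([np.zeros(200, bool), np.ones(200, bool)])
        result = cs.explore_thresholds(scores, method="mixture", seed=0)
        assert 0.4 < result.threshold < 0.6
        assert (result.above == truth).mean() >= 0.99

    def test_constant_scores_fallback(self):
        scores = [cs.CellScoreResult(f"c{i}", 0.3, "full_integral") for i in range(20)]
        with pytest.warns(UserWarning, match="constant"):
            result = cs.explore_thresholds(scores, method="mixture")
        assert result.method == "percentile_fallback"
        assert result.threshold == pytest.approx(0.3)
        assert result.n_above == 0
        assert all(s.above_threshold is False for s in scores)

    def test_unimodal_mean_sd_flags_at_most_one_percent(self):
        """Monte-Carlo under a normal null: mean + 3sd flags <= 1% of
        cells in expectation (1,000 reps)."""
        rng = np.random.default_rng(31)
        flagged = 0
        total = 0
        for _ in range(1000):
            scores = rng.normal(0.5, 0.05, 200)
            result = cs.explore_thresholds(scores, method="mean_sd", k=3.0)
            flagged += result.n_above
            total += scores.size
        assert flagged / total <= 0.01

    def test_requires_ten_cells(self):
        with pytest.raises(ValueError, match=">= 10"):
            cs.explore_thresholds(np.array([0.1, 0.2, 0.3]))


class TestSignatureScore:
    def test_single_marker_equals_feature_zscore(self):
        rng = np.random.default_rng(40)
        values = rng.random((3, 12))
        mat = make_matrix(values)
        score = cs.signature_score(mat, cs.GeneSet("S", frozenset(["T2"])))
        expected = stats.zscore(values[1])
        assert np.allclose(score.to_numpy(), expected)

    def test_shifted_samples_rank_higher(self):
        rng = np.random.default_rng(41)
        values = rng.normal(10, 2, size=(20, 100))
        values[:10, 50:] += 2 * 2  # markers up by 2 sd in half the samples
        mat = make_matrix(values)
        markers = cs.GeneSet("S", frozenset(f"T{i + 1}" for i in range(10)))
        score = cs.signature_score(mat, markers)
        w = stats.mannwhitneyu(score[50:], score[:50], alternative="greater")
        assert w.pvalue < 0.01

    def test_auc_and_mean_z_orderings_agree(self):
        rng = np.random.default_rng(42)
        values = np.exp(rng.normal(1, 1, size=(60, 80)))
        lift = rng.random(80) * 4
        values[:12] *= np.exp(lift)[None, :]  # graded marker activity
        mat = make_matrix(values)
        markers = cs.GeneSet("S", frozenset(f"T{i + 1}" for i in range(12)))
        z = cs.signature_score(mat, markers, method="mean_z")
        a = cs.signature_score(mat, markers, method="auc")
        rho = stats.spearmanr(z, a).statistic
        assert rho > 0.8

    def test_insufficient_overlap_errors_listing_missing(self):
        mat = make_matrix(np.ones((3, 4)) + np.eye(3, 4))
        markers = cs.GeneSet("S", frozenset(["T1", "M1", "M2"]))
        with pytest.raises(ValueError, match="M1"):
            cs.signature_score(mat, markers)


class TestCoexpression:
    def test_identical_and_negated_features(self):
        rng = np.random.default_rng(50)
        base = rng.random(40) * 5 + 1
        values = np.vstack([base, base, base.max() + 1 - base, rng.random(40)])
        mat = make_matrix(values)
        table = cs.coexpression(mat, "T1").set_index("feature")
        assert table.loc["T2", "pearson_r"] == pytest.approx(1.0)
        assert table.loc["T3", "pearson_r"] == pytest.approx(-1.0)
        assert bool(table.loc["T2", "coexpressed"])

    def test_zero_variance_feature_excluded_from_family(self):
        rng = np.random.default_rng(51)
        values = np.vstack([rng.random(30), np.full(30, 2.0), rng.random(30)])
        mat = make_matrix(values)
        table = cs.coexpression(mat, "T1").set_index("feature")
        assert np.isnan(table.loc["T2", "pearson_r"])
        assert not bool(table.loc["T2", "coexpressed"])

    def test_zero_variance_target_rejected(self):
        mat = make_matrix(np.vstack([np.ones(10), np.arange(10)]))
        with pytest.raises(ValueError, match="zero variance"):
            cs.coexpression(mat, "T1")

    def test_planted_block_recovered(self):
        """Latent-factor block (loading 0.8, 300 cells) recovered at
        FDR 0.05 with sensitivity >= 0.9."""
        rng = np.random.default_rng(52)
        n_cells, n_feat, block = 300, 120, 20
        z = rng.normal(size=n_cells)
        values = rng.normal(size=(n_feat, n_cells))
        values[:block] = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(size=(block, n_cells))
        mat = make_matrix(values - values.min() + 0.01)
        table = cs.coexpression(mat, "T1").set_index("feature")
        block_ids = [f"T{i + 1}" for i in range(1, block)]
        sens = table.loc[block_ids, "coexpressed"].mean()
        assert sens >= 0.9

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(53)
        mat = make_matrix(rng.random((50, 40)))
        table = cs.coexpression(mat, "T1").dropna().sort_values("p_value")
        q = table["fdr_q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= table["p_value"].to_numpy() - 1e-12).all()

    def test_empirical_fdr_controlled_under_null(self):
        """500 simulations of independent features: empirical FDR at
        q < 0.05 stays <= 0.07 (every rejection is false here)."""
        rng = np.random.default_rng(54)
        fdp = []
        for _ in range(500):
            mat = make_matrix(rng.normal(size=(60, 50)) + 10)
            table = cs.coexpression(mat, "T1")
            n_rej = int(table["coexpressed"].sum())
            fdp.append(1.0 if n_rej > 0 else 0.0)
        assert np.mean(fdp) <= 0.07


class TestDrugCorrelation:
    def make_tables(self, rng, n_lines=30, n_drugs=20, planted_r=-0.7):
        lines = [f"L{i}" for i in range(n_lines)]
        z = rng.normal(size=n_lines)
        scores = pd.Series(z, index=lines)
        rows = []
        for d in range(n_drugs):
            if d == 0:
                y = planted_r * z + np.sqrt(1 - planted_r**2) * rng.normal(size=n_lines)
            else:
                y = rng.normal(size=n_lines)
            rows += [(l, f"D{d}", v) for l, v in zip(lines, y)]
        return scores, pd.DataFrame(rows, columns=["cell_line", "drug", "ic50"])

    def test_perfect_anticorrelation(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        ic50 = pd.DataFrame(
            {"cell_line": list("abcd"), "drug": "D", "ic50": [-1.0, -2.0, -3.0, -4.0]}
        )
        (corr,) = cs.correlate_with_ic50(scores, ic50)
        assert corr.pearson_r == pytest.approx(-1.0)

    def test_too_few_lines_skipped_with_warning(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        ic50 = pd.DataFrame({"cell_line": ["a", "b"], "drug": "D", "ic50": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="skipped"):
            assert cs.correlate_with_ic50(scores, ic50) == []

    def test_permutation_null_type_one_rate(self):
        """Permuted IC50 labels: |r| small, type-I rate <= 0.07 at
        alpha = 0.05 over 1,000 permutations."""
        rng = np.random.default_rng(60)
        n = 30
        z = rng.normal(size=n)
        y = -0.7 * z + 0.5 * rng.normal(size=n)
        rejections = 0
        for _ in range(1000):
            perm = rng.permutation(y)
            r, p = stats.pearsonr(z, perm)
            rejections += p < 0.05
        assert rejections / 1000 <= 0.07

    def test_planted_drug_most_negative_and_significant(self):
        """r = -0.7 planted among 19 nulls (30 lines): most-negative
        rank with q < 0.05 in >= 80% of 100 seeded replicates."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            scores, ic50 = self.make_tables(rng)
            frame = cs.correlations_to_frame(cs.correlate_with_ic50(scores, ic50))
            best = frame.sort_values("pearson_r").iloc[0]
            if best["drug"] == "D0" and best["fdr_q"] < 0.05:
                hits += 1
        assert hits >= 80
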