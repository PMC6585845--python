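import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import paveshape as ps
from paveshape import stats


class TestSpearman:
    def test_perfect_agreement_and_reversal(self):
        x = np.arange(10.0)
        assert stats.spearman(x, x).rho == pytest.approx(1.0)
        assert stats.spearman(x, -x).rho == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        r = stats.spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r.rho == pytest.approx(0.8)
        assert r.n == 5
        # two-sided t test with 3 df at t = 0.8 * sqrt(3 / 0.36)
        assert r.p_value == pytest.approx(0.104, abs=5e-4)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            rho = stats.spearman(x, y).rho
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert abs(rho - oracle) < 1e-12

    def test_matches_scipy_with_ties(self):
        x = [1, 2, 2, 3, 4, 4, 4, 5]
        y = [3, 1, 4, 4, 2, 5, 6, 6]
        r = stats.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert r.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_p_monotone_decreasing_in_abs_rho_at_fixed_n(self):
        n = 12
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        results = []
        for mix in (0.9, 0.5, 0.1):
            y = mix * rng.normal(size=n) + (1 - mix) * x
            results.append(stats.spearman(x, y))
        results.sort(key=lambda r: abs(r.rho))
        ps_ = [r.p_value for r in results]
        assert ps_[0] > ps_[1] > ps_[2]

    def test_degenerate_flagged_and_short_input_rejected(self):
        r = stats.spearman([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert r.degenerate and np.isnan(r.rho)
        with pytest.raises(ValueError, match="at least 5"):
            stats.spearman([1, 2], [3, 4])


class TestPCA:
    def test_orthonormal_loadings_and_unit_variance_sum(self, factorial_grid):
        res = stats.pca_descriptors(factorial_grid)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-8)
        assert res.variance_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_scores_covariance_is_diagonal(self, factorial_grid):
        res = stats.pca_descriptors(factorial_grid)
        C = np.cov(res.scores, rowvar=False)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(C)).max()

    def test_matches_sklearn_variance_fractions(self, factorial_grid):
        from sklearn.decomposition import PCA

        res = stats.pca_descriptors(factorial_grid, standardize=False)
        ref = PCA(n_components=4).fit(
            factorial_grid[["aspect_ratio", "area_um2", "circularity", "solidity"]]
        )
        assert res.variance_explained == pytest.approx(ref.explained_variance_ratio_, abs=1e-10)

    def test_independent_factors_give_near_perpendicular_loadings(self, factorial_grid):
        res = stats.pca_descriptors(factorial_grid)
        assert res.variance_explained[:2].sum() > 0.9
        v1 = res.loadings.loc["aspect_ratio", ["PC1", "PC2"]].to_numpy()
        v2 = res.loadings.loc["solidity", ["PC1", "PC2"]].to_numpy()
        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert abs(cos) < 0.3

    def test_single_varying_column_explains_everything(self):
        df = pd.DataFrame({"aspect_ratio": [0.2, 0.5, 0.9, 0.4], "area_um2": 1.0,
                           "circularity": 2.0, "solidity": 0.5})
        res = stats.pca_descriptors(df, standardize=False)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_row_duplication_invariance(self, factorial_grid):
        sub = factorial_grid.head(50)
        r1 = stats.pca_descriptors(sub)
        r2 = stats.pca_descriptors(pd.concat([sub, sub], ignore_index=True))
        assert np.allclose(r1.variance_explained, r2.variance_explained, atol=1e-10)
        assert np.allclose(r1.loadings.to_numpy(), r2.loadings.to_numpy(), atol=1e-8)

    def test_constant_column_rejected_by_name_when_standardizing(self):
        df = pd.DataFrame({"aspect_ratio": [0.2, 0.5, 0.9], "area_um2": 1.0,
                           "circularity": [1.0, 2.0, 3.0], "solidity": [0.9, 0.8, 0.7]})
        with pytest.raises(ValueError, match="area_um2"):
            stats.pca_descriptors(df)


class TestSummarize:
    def make_cells(self, species, side, n, solidity=0.8, ar=0.5):
        return pd.DataFrame({
            "species": species, "cell_id": [f"{species}_{side}_{i}" for i in range(n)],
            "side": side, "area_um2": 100.0, "perimeter_um": 40.0,
            "solidity": solidity, "aspect_ratio": ar, "circularity": 1.3,
        })

    def test_identical_cells_give_zero_sd_and_exact_mean(self):
        cells = pd.concat([self.make_cells("sp1", s, 30) for s in ("adaxial", "abaxial")]
                          + [self.make_cells("sp2", s, 30, solidity=0.6) for s in ("adaxial", "abaxial")])
        out = stats.summarize_species(cells)
        assert (out["adaxial_solidity_sd"] < 1e-12).all()
        assert out.set_index("species").loc["sp1", "adaxial_solidity_mean"] == pytest.approx(0.8)
        assert out.set_index("species").loc["sp2", "abaxial_solidity_mean"] == pytest.approx(0.6)

    def test_oversupplied_cells_subsampled_to_cap_reproducibly(self):
        cells = self.make_cells("sp1", "adaxial", 45)
        cells["solidity"] = np.linspace(0.5, 0.9, 45)
        out1 = stats.summarize_species(cells, seed=11)
        out2 = stats.summarize_species(cells.sample(frac=1.0, random_state=0), seed=11)
        assert out1.loc[0, "adaxial_n"] == 30
        # row-order permutation invariance of the seeded subsample
        assert out1.loc[0, "adaxial_solidity_mean"] == pytest.approx(
            out2.loc[0, "adaxial_solidity_mean"], abs=1e-12)
        out3 = stats.summarize_species(cells, seed=12)
        assert out1.loc[0, "adaxial_solidity_mean"] != out3.loc[0, "adaxial_solidity_mean"]

    def test_missing_metadata_species_listed(self):
        cells = self.make_cells("mystery", "adaxial", 5)
        meta = pd.DataFrame({"species": ["known"], "clade": ["fern"]})
        with pytest.raises(ValueError, match="mystery"):
            stats.summarize_species(cells, meta=meta)

    def test_single_sided_species_has_nan_diff(self):
        out = stats.summarize_species(self.make_cells("solo", "adaxial", 10))
        assert out.loc[0, "abaxial_n"] == 0
        assert np.isnan(out.loc[0, "solidity_diff"])

    def test_clade_mean_ordering_matches_generator(self, small_summaries):
        order = small_summaries.groupby("clade")["mean_solidity"].mean().sort_values()
        assert list(order.index) == ["fern", "eudicot", "monocot"]


class TestSideDifference:
    def test_identical_sides_give_zero(self):
        cells = pd.concat([
            TestSummarize().make_cells("sp1", "adaxial", 10),
            TestSummarize().make_cells("sp1", "abaxial", 10),
        ])
        sd = stats.side_difference(stats.summarize_species(cells))
        assert sd.per_species["solidity_diff"].tolist() == [0.0]
        assert sd.n_both_sides == 1 and sd.n_positive == 0

    def test_sign_convention(self):
        cells = pd.concat([
            TestSummarize().make_cells("sp1", "adaxial", 10, solidity=0.9),
            TestSummarize().make_cells("sp1", "abaxial", 10, solidity=0.8),
        ])
        sd = stats.side_difference(stats.summarize_species(cells))
        assert sd.per_species["solidity_diff"].iloc[0] == pytest.approx(0.1)
        assert sd.fraction_positive == 1.0

    def test_generator_abaxial_offset_detected(self, small_summaries):
        sd = stats.side_difference(small_summaries)
        assert sd.n_both_sides == 24
        assert sd.fraction_positive > 0.8


class TestLeafCellCorrelation:
    def test_perfect_rank_agreement(self):
        df = pd.DataFrame({
            "species": list("abcdef"), "clade": "fern",
            "leaf_ar": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            "mean_aspect_ratio": [0.15, 0.25, 0.3, 0.55, 0.6, 0.9],
        })
        assert stats.leaf_cell_correlation(df).rho == pytest.approx(1.0)

    def test_coupled_clades_correlate_uncoupled_do_not(self, small_summaries):
        coupled = stats.leaf_cell_correlation(small_summaries, ["fern", "monocot"])
        assert coupled.rho > 0.5 and coupled.p_value < 0.05
        uncoupled = stats.leaf_cell_correlation(small_summaries, ["eudicot"])
        assert abs(uncoupled.rho) < 0.75  # small n; just not spuriously perfect

    def test_too_few_species_rejected(self, small_summaries):
        with pytest.raises(ValueError, match="at least 5"):
            stats.leaf_cell_correlation(small_summaries.head(3))


class TestDatasetMedians:
    def test_species_vs_cells_scope(self, small_summaries, small_metrics):
        m_sp = stats.dataset_medians(small_summaries)
        m_cells = stats.dataset_medians(small_summaries, cells=small_metrics, over="cells")
        assert m_sp["n"] == 24 and m_cells["n"] == len(small_metrics)
        for key in ("solidity_median", "aspect_ratio_median"):
            assert 0 < m_sp[key] <= 1 and 0 < m_cells[key] <= 1
        lo, hi = m_sp["solidity_range"]
        assert lo <= m_sp["solidity_median"] <= hi
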