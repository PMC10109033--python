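import numpy as np
import pandas as pd
import pytest

from proteodx.errors import ConfigError, InputError, ValidationError
from proteodx.normalize_impute import (
    PreprocessConfig,
    assess_normalization,
    impute,
    quantile_normalize,
    rlr_normalize,
    vst_rna,
)
from proteodx.synthetic_cohort import PlantSpec, simulate_cohort

from conftest import make_matrix


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"impute_method": "magic"},
            {"min_det_quantile": 0.0},
            {"min_det_quantile": 0.6},
            {"pseudocount": 0.0},
            {"protein_norm": "loess"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            PreprocessConfig(**kw)


class TestImpute:
    def test_min_det_low_quantile_is_sample_minimum(self):
        vals = np.array([[4.0], [6.0], [8.0], [np.nan]])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = impute(m, PreprocessConfig(impute_method="min_det", min_det_quantile=0.001))
        assert out.values.loc["g4", "s1"] == pytest.approx(4.0, abs=0.01)

    def test_zero_method_puts_floor_at_every_mv(self):
        vals = np.array([[4.0, np.nan], [6.0, 7.0], [np.nan, 5.0]])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = impute(m, PreprocessConfig(impute_method="zero"))
        assert out.values.loc["g1", "s2"] == 0.0
        assert out.values.loc["g3", "s1"] == 0.0
        # observed values positive, so no shift applied
        assert out.values.loc["g1", "s1"] == 4.0

    def test_zero_method_shifts_nonpositive_scale(self):
        vals = np.array([[-3.0, np.nan], [2.0, 1.0]])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = impute(m, PreprocessConfig(impute_method="zero"))
        # observed minimum moved to 1, missing at 0 stays below everything
        assert out.values.loc["g1", "s1"] == pytest.approx(1.0)
        assert out.values.loc["g1", "s2"] == 0.0
        assert out.values.min().min() == 0.0

    def test_min_det_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        col = rng.normal(15, 3, 1000)
        vals = np.concatenate([col, [np.nan]])[:, None]
        m = make_matrix(vals, layer="protein", scale="log2")
        q = 0.01
        out = impute(m, PreprocessConfig(impute_method="min_det", min_det_quantile=q))
        # brute-force order-statistic quantile with linear interpolation
        s = np.sort(col)
        pos = q * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert out.values.iloc[-1, 0] == pytest.approx(expected, abs=1e-12)

    def test_sample_without_observations_errors(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        m = make_matrix(vals, layer="protein", scale="log2")
        with pytest.raises(InputError, match="s1"):
            impute(m, PreprocessConfig())

    def test_observed_cells_never_altered(self, small_cohort):
        logm = small_cohort[0].to_log2()
        for method in ("zero", "min_det"):
            out = impute(logm, PreprocessConfig(impute_method=method))
            obs = ~logm.mask.to_numpy()
            np.testing.assert_array_equal(
                out.values.to_numpy()[obs], logm.values.to_numpy()[obs]
            )

    def test_wrong_scale_rejected(self):
        m = make_matrix(np.ones((2, 2)), layer="protein", scale="linear")
        with pytest.raises(ValidationError):
            impute(m, PreprocessConfig())

    def test_min_det_preserves_planted_rank_minimum(self):
        from conftest import no_censor_config

        cfg = no_censor_config(censor_midpoint=14.0, censor_slope=1.0, seed=5)
        gene = "G0030"
        protein, *_ = simulate_cohort(
            cfg, [PlantSpec("concordant_down", "P002", 7.0, gene=gene)]
        )
        # the knocked-down cell fell below the detection limit (and only it)
        assert protein.mask.loc[gene, "P002"]
        assert protein.mask.loc[gene].sum() == 1
        out = impute(protein.to_log2(), PreprocessConfig(impute_method="min_det"))
        assert out.values.loc[gene].idxmin() == "P002"


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        col = np.array([1.0, 5.0, 3.0])
        m = make_matrix(np.column_stack([col, col]), layer="protein", scale="log2")
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_hand_computed_rank_mean_table(self):
        # columns sorted: s1 (2,4,6), s2 (1,5,9), s3 (3,7,8) -> row means (2,16/3,23/3)
        vals = np.array([[2.0, 9.0, 3.0], [4.0, 1.0, 8.0], [6.0, 5.0, 7.0]])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = quantile_normalize(m).values.to_numpy()
        r = [2.0, 16.0 / 3.0, 23.0 / 3.0]
        expected = np.array([[r[0], r[2], r[0]], [r[1], r[0], r[2]], [r[2], r[1], r[1]]])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_ties_get_mean_of_tied_positions(self):
        vals = np.array([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = quantile_normalize(m).values.to_numpy()
        row_means = np.array([1.0, 1.5, 4.0])
        # s1 has a two-way tie at sorted positions 0 and 1
        assert out[0, 0] == pytest.approx(row_means[:2].mean())
        assert out[1, 0] == pytest.approx(row_means[:2].mean())

    def test_defining_property_equal_quantile_vectors(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(10, 2, (50, 5)), layer="protein", scale="log2")
        out = quantile_normalize(m).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(10, 2, (80, 6)), layer="protein", scale="log2")
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-9
        )


class TestRlrNormalize:
    def test_constant_shift_removed_exactly(self):
        rng = np.random.default_rng(3)
        base = rng.normal(14, 2, 200)
        vals = np.column_stack([base, base + 1.7, base - 0.9])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = rlr_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 1], out[:, 0], atol=1e-6)
        np.testing.assert_allclose(out[:, 2], out[:, 0], atol=1e-6)

    def test_identity_cohort_unchanged(self):
        rng = np.random.default_rng(4)
        base = rng.normal(14, 2, 100)
        vals = np.column_stack([base, base, base])
        m = make_matrix(vals, layer="protein", scale="log2")
        out = rlr_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, vals, atol=1e-8)

    def test_robust_to_contamination_where_ols_is_not(self):
        rng = np.random.default_rng(5)
        n = 400
        ref = rng.normal(14, 2, n)
        clean = ref * 1.1 + 0.5 + rng.normal(0, 0.01, n)
        contaminated = clean.copy()
        idx = rng.choice(n, size=n // 20, replace=False)  # 5% wild outliers
        contaminated[idx] += rng.normal(20, 5, len(idx))
        import statsmodels.api as sm

        exog = sm.add_constant(ref)
        huber_slope = sm.RLM(contaminated, exog, M=sm.robust.norms.HuberT(t=1.345)).fit().params[1]
        ols_slope = np.polyfit(ref, contaminated, 1)[0]
        clean_slope = np.polyfit(ref, clean, 1)[0]
        assert abs(huber_slope - clean_slope) / clean_slope < 0.01
        assert abs(ols_slope - clean_slope) / clean_slope > 0.01

    def test_incomplete_matrix_rejected(self):
        m = make_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]), layer="protein", scale="log2")
        with pytest.raises(ValidationError):
            rlr_normalize(m)


class TestVstRna:
    def test_identical_samples_give_unit_size_factors(self):
        col = np.array([10.0, 200.0, 3000.0])
        m = make_matrix(np.column_stack([col] * 4), layer="rna", scale="linear")
        out = vst_rna(m)
        np.testing.assert_allclose(out.size_factors.to_numpy(), np.ones(4), atol=1e-12)

    def test_doubling_counts_doubles_size_factor_and_is_invariant(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(200, size=(100, 6)).astype(float) + 1.0
        m = make_matrix(counts, layer="rna", scale="linear")
        doubled = counts.copy()
        doubled[:, 2] *= 2
        m2 = make_matrix(doubled, layer="rna", scale="linear")
        out1, out2 = vst_rna(m), vst_rna(m2)
        assert out2.size_factors.iloc[2] == pytest.approx(2 * out1.size_factors.iloc[2], rel=1e-12)
        np.testing.assert_allclose(
            out2.values.iloc[:, 2].to_numpy(), out1.values.iloc[:, 2].to_numpy(), atol=1e-10
        )

    def test_variance_stabilization_on_nb_counts(self):
        rng = np.random.default_rng(7)
        n_genes, n_s = 3000, 30
        mean = 2.0 ** rng.uniform(3, 12, n_genes)
        disp = 0.1
        lam = rng.gamma(1 / disp, mean[:, None] * disp, size=(n_genes, n_s))
        counts = rng.poisson(lam).astype(float)
        m = make_matrix(counts, layer="rna", scale="linear")
        out = vst_rna(m).values.to_numpy()
        gene_mean = counts.mean(axis=1)
        quartile = pd.qcut(gene_mean, 4, labels=False)
        sds = [out[quartile == q].std(axis=1, ddof=1).mean() for q in (1, 2, 3)]
        assert max(sds) / min(sds) < 2.0

    def test_zero_heavy_matrix_falls_back_to_totals(self):
        counts = np.array([[0.0, 5.0], [3.0, 0.0]])
        m = make_matrix(counts, layer="rna", scale="linear")
        out = vst_rna(m)
        totals = counts.sum(axis=0)
        # leave-one-out total-count ratios: sf_j = t_j / geomean(other totals)
        expected = totals / np.array([totals[1], totals[0]])
        np.testing.assert_allclose(out.size_factors.to_numpy(), expected, rtol=1e-12)

    def test_wrong_layer_rejected(self):
        m = make_matrix(np.ones((2, 2)), layer="protein", scale="linear")
        with pytest.raises(ValidationError):
            vst_rna(m)


class TestAssessNormalization:
    def test_quantile_normalization_zeroes_sample_median_mad(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(10, 2, (60, 5)) + rng.normal(0, 1, 5), layer="protein", scale="log2")
        out = quantile_normalize(m)
        report = assess_normalization(m, out)
        assert report["after"]["sample_median_mad"] == pytest.approx(0.0, abs=1e-12)

    def test_shifted_cohort_improves_under_both_methods(self):
        rng = np.random.default_rng(9)
        base = rng.normal(14, 2, 200)
        shifts = np.array([0.0, 1.2, -0.8, 2.0])
        vals = base[:, None] + shifts[None, :] + rng.normal(0, 0.05, (200, 4))
        m = make_matrix(vals, layer="protein", scale="log2")
        for norm in (quantile_normalize, rlr_normalize):
            out = norm(m)
            rep = assess_normalization(m, out)
            assert rep["after"]["pooled_cv"] < rep["before"]["pooled_cv"]
            assert rep["after"]["sample_median_mad"] < rep["before"]["sample_median_mad"]

    def test_identical_matrices_identical_metrics(self, small_cohort):
        logm = impute(small_cohort[0].to_log2(), PreprocessConfig())
        rep = assess_normalization(logm, logm)
        assert rep["before"] == rep["after"]
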