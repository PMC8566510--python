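import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matriscope.io import ExpressionMatrix, ValidationError
from matriscope.normalize import (
    category_fraction,
    fit_vst_parameters,
    median_ratio_size_factors,
    median_tissue_profile,
    quantile_normalize,
    vst_transform,
)
from tests.conftest import make_sample_table


def matrix(values, units="raw_counts", prefix="g"):
    arr = np.atleast_2d(np.asarray(values))
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        units=units,
    )


def brute_force_size_factors(counts):
    """Explicit-loop median-of-ratios oracle."""
    values = counts.values.astype(float)
    ref_rows = [g for g in range(values.shape[0]) if all(values[g] > 0)]
    factors = []
    for j in range(values.shape[1]):
        ratios = []
        for g in ref_rows:
            geo = np.prod(values[g]) ** (1.0 / values.shape[1])
            ratios.append(values[g, j] / geo)
        factors.append(np.median(ratios))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = matrix([[5, 5, 5], [9, 9, 9]])
        assert np.allclose(median_ratio_size_factors(m).factors, 1.0)

    def test_two_gene_hand_example(self):
        m = matrix([[2, 4], [8, 16]])
        np.testing.assert_allclose(
            median_ratio_size_factors(m).factors, [np.sqrt(0.5), np.sqrt(2.0)], atol=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        m = matrix(rng.negative_binomial(10, 0.1, (50, 6)) + 1)
        np.testing.assert_allclose(
            median_ratio_size_factors(m).factors, brute_force_size_factors(m), atol=1e-12
        )

    def test_matches_reference_implementation(self, rng):
        """Independent cross-check against the DESeq2-style estimator.

        An odd reference-gene count makes the median a single order
        statistic, so median-of-ratios and exp(median(log-ratios)) — the
        reference tool's formulation — coincide exactly.
        """
        from pydeseq2.preprocessing import deseq2_norm

        counts = rng.negative_binomial(5, 0.05, (81, 8)) + 1
        m = matrix(counts)
        _, ref = deseq2_norm(pd.DataFrame(counts.T))
        np.testing.assert_allclose(
            median_ratio_size_factors(m).factors, np.asarray(ref), rtol=1e-12
        )

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        """Scaling sample j's counts by c scales factor_j / factor_k by
        exactly c (the geometric means absorb a common c^(1/n))."""
        counts = rng.poisson(50, (30, 5)) + 1
        base = median_ratio_size_factors(matrix(counts)).factors.to_numpy()
        scaled = counts.copy()
        scaled[:, 2] *= 3
        f = median_ratio_size_factors(matrix(scaled)).factors.to_numpy()
        np.testing.assert_allclose(f[2] / f[0], 3 * base[2] / base[0], rtol=1e-12)
        np.testing.assert_allclose(f[1] / f[0], base[1] / base[0], rtol=1e-12)

    def test_no_reference_gene_is_error(self):
        m = matrix([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="pseudo-reference"):
            median_ratio_size_factors(m)


class TestVST:
    def test_poisson_limit_tracks_sqrt(self, rng):
        counts = rng.poisson(rng.uniform(5, 500, (500, 1)), (500, 20))
        m = matrix(counts)
        a, b, sf = fit_vst_parameters(m)
        v = vst_transform(m)
        q = np.sqrt(m.values / sf.factors.to_numpy()[None, :])
        corr = np.corrcoef(q.ravel(), v.values.ravel())[0, 1]
        assert corr > 0.999

    def test_constant_gene_maps_to_constant(self, rng):
        # Anchor genes identical across samples force unit size factors,
        # so a constant-count gene stays constant after the transform.
        anchors = np.tile(np.arange(10, 310, 10)[:, None], (1, 6))
        varied = rng.negative_binomial(5, 0.05, (15, 6)) + 1
        m = matrix(np.vstack([anchors, varied]))
        sf = median_ratio_size_factors(m).factors.to_numpy()
        np.testing.assert_allclose(sf, 1.0, atol=1e-12)
        v = vst_transform(m)
        for g in range(anchors.shape[0]):
            assert np.ptp(v.values[g]) < 1e-9

    def test_monotone_in_normalized_counts_per_gene(self, rng):
        m = matrix(rng.negative_binomial(10, 0.05, (100, 8)))
        sf = median_ratio_size_factors(m).factors.to_numpy()
        v = vst_transform(m)
        q = m.values / sf[None, :]
        for g in range(0, 100, 7):
            order = np.argsort(q[g])
            assert np.all(np.diff(v.values[g][order]) >= -1e-12)

    def test_trend_parameter_recovery(self, rng):
        a_true, b_true = 1.0, 0.1
        mu = rng.uniform(5, 500, 2000)  # low means identify the 1/mu term
        phi = a_true / mu + b_true
        r = 1.0 / phi
        counts = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], (2000, 100))
        a, b, _ = fit_vst_parameters(matrix(counts))
        assert abs(a - a_true) / a_true < 0.2
        assert abs(b - b_true) / b_true < 0.2

    def test_log2_scale_at_large_counts(self, rng):
        from matriscope.normalize import _vst_closed_form

        diff = _vst_closed_form(np.array([2e6]), 0.5, 0.05) - _vst_closed_form(
            np.array([1e6]), 0.5, 0.05
        )
        assert abs(diff[0] - 1.0) < 1e-3


def brute_force_quantile(columns):
    """Tie-aware quantile normalization oracle: explicit per-column loop."""
    columns = [np.asarray(c, dtype=float) for c in columns]
    n = len(columns[0])
    ref = np.mean([np.sort(c) for c in columns], axis=0)
    out = []
    for col in columns:
        res = np.empty(n)
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        ranks = np.empty(n)
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            ranks[order[i : j + 1]] = np.mean(ref[i : j + 1])
            i = j + 1
        out.append(ranks)
    return out


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        m = matrix([[1, 1], [5, 5], [9, 9]], units="tpm")
        (out,) = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_two_column_hand_example(self):
        m1 = matrix([[1], [2], [3]], units="tpm")
        m2 = matrix([[4], [5], [6]], units="tpm")
        o1, o2 = quantile_normalize([m1, m2])
        np.testing.assert_allclose(o1.values.ravel(), [2.5, 3.5, 4.5])
        np.testing.assert_allclose(o2.values.ravel(), [2.5, 3.5, 4.5])

    def test_tie_shares_mean_of_spanned_quantiles(self):
        o1, o2 = quantile_normalize([matrix([[1], [1], [3]], units="tpm"), matrix([[2], [4], [6]], units="tpm")])
        np.testing.assert_allclose(o1.values.ravel(), [2.0, 2.0, 4.5])

    def test_matches_brute_force_tie_oracle(self, rng):
        for _ in range(20):
            cols = rng.integers(0, 6, (12, 3)).astype(float)  # many ties
            mats = [matrix(cols[:, [j]], units="tpm") for j in range(3)]
            outs = quantile_normalize(mats)
            oracle = brute_force_quantile([cols[:, j] for j in range(3)])
            for out, exp in zip(outs, oracle):
                np.testing.assert_allclose(out.values.ravel(), exp, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_columns_share_one_multiset(self, seed):
        rng = np.random.default_rng(seed)
        cols = rng.normal(0, 1, (15, 4)) ** 2
        mats = [matrix(cols[:, [j]], units="tpm") for j in range(4)]
        outs = quantile_normalize(mats)
        sorted_cols = [np.sort(o.values.ravel()) for o in outs]
        for c in sorted_cols[1:]:
            np.testing.assert_array_equal(c, sorted_cols[0])

    def test_gene_set_mismatch_is_error(self):
        m1 = matrix([[1], [2]], units="tpm")
        m2 = matrix([[1], [2]], units="tpm", prefix="h")
        with pytest.raises(ValidationError, match="symmetric difference"):
            quantile_normalize([m1, m2])


class TestCategoryFraction:
    def test_all_expression_in_collagens(self, tiny_catalog):
        genes = sorted(tiny_catalog.genes)
        tpm = pd.DataFrame(0.0, index=genes, columns=["LUNG"])
        tpm.loc[sorted(tiny_catalog.genes_in_category("collagens")), "LUNG"] = 50.0
        out = category_fraction(tpm, tiny_catalog)
        assert out.loc["LUNG", "collagens"] == 100.0
        assert out.loc["LUNG", "ECM_regulators"] == 0.0

    def test_uniform_tpm_proportion(self, tiny_catalog):
        genes = sorted(tiny_catalog.genes)
        tpm = pd.DataFrame(1.0, index=genes, columns=["LUNG"])
        out = category_fraction(tpm, tiny_catalog)
        assert out.loc["LUNG", "ECM_regulators"] == pytest.approx(20.0)

    def test_matches_brute_force_group_sums(self, tiny_catalog, rng):
        genes = sorted(tiny_catalog.genes)
        tpm = pd.DataFrame(rng.uniform(0, 100, (10, 3)), index=genes, columns=list("ABC"))
        out = category_fraction(tpm, tiny_catalog)
        for tissue in "ABC":
            total = tpm[tissue].sum()
            for cat in out.columns:
                expected = sum(
                    tpm.loc[g, tissue] for g in genes if tiny_catalog.category_of(g) == cat
                )
                assert out.loc[tissue, cat] == pytest.approx(100 * expected / total, abs=1e-12)

    def test_invariant_to_tissue_rescaling(self, tiny_catalog, rng):
        genes = sorted(tiny_catalog.genes)
        tpm = pd.DataFrame(rng.uniform(1, 100, (10, 2)), index=genes, columns=["A", "B"])
        out1 = category_fraction(tpm, tiny_catalog)
        tpm["A"] *= 7.5
        out2 = category_fraction(tpm, tiny_catalog)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_total_is_error(self, tiny_catalog):
        tpm = pd.DataFrame(0.0, index=sorted(tiny_catalog.genes), columns=["DEAD"])
        with pytest.raises(ValidationError, match="zero total"):
            category_fraction(tpm, tiny_catalog)


class TestMedianTissueProfile:
    def test_single_sample_per_tissue_is_identity(self):
        m = matrix([[1.0, 5.0], [2.0, 8.0]], units="vst")
        samples = make_sample_table(["s0", "s1"], ["LUNG", "COLON"])
        prof = median_tissue_profile(m, samples)
        np.testing.assert_allclose(prof.data["LUNG"], m.data["s0"])
        np.testing.assert_allclose(prof.data["COLON"], m.data["s1"])

    def test_brain_is_median_of_subtissue_medians(self):
        m = matrix([[1.0, 2.0, 9.0]], units="vst")
        samples = make_sample_table(["s0", "s1", "s2"], ["BRNCTX", "BRNCBL", "BRNHIP"])
        prof = median_tissue_profile(m, samples, collapse_brain=True)
        assert prof.data.loc["g0", "BRAIN"] == 2.0
        assert prof.tissues == ["BRAIN"]

    def test_matches_two_stage_oracle(self, rng):
        values = rng.normal(5, 2, (8, 9))
        m = matrix(np.abs(values), units="vst")
        tissues = ["BRNA"] * 2 + ["BRNB"] * 3 + ["LUNG"] * 4
        samples = make_sample_table([f"s{j}" for j in range(9)], tissues)
        prof = median_tissue_profile(m, samples, collapse_brain=True)
        vals = np.abs(values)
        for g in range(8):
            brain = np.median([np.median(vals[g, :2]), np.median(vals[g, 2:5])])
            assert prof.data.iloc[g]["BRAIN"] == pytest.approx(brain, abs=1e-12)
            assert prof.data.iloc[g]["LUNG"] == pytest.approx(np.median(vals[g, 5:]), abs=1e-12)
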