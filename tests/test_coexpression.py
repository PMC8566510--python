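import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from matriscope.coexpression import (
    association_models,
    cluster_score,
    cut_clusters,
    high_variance_filter,
    multi_tissue_gene_score,
    sample_cluster,
    select_extreme_subjects,
    tau_critical,
)
from matriscope.io import ExpressionMatrix, SampleTable, ValidationError
from matriscope.simulate import CohortSpec, CorrelatedBlock, generate_cohort
from tests.conftest import make_sample_table


def vst_matrix(values, prefix="g"):
    arr = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        units="vst",
    )


class TestHighVarianceFilter:
    def test_constant_gene_removed(self):
        m = vst_matrix([[6.0] * 5, [6, 4, 8, 3, 9]])
        assert "g0" not in high_variance_filter(m, mean_min=5, var_min=1.5)

    def test_threshold_rule(self):
        gene = 6.0 + np.array([-1.6, -0.8, 0.0, 0.8, 1.6])  # var 1.6, mean 6
        m = vst_matrix([gene, [0.1] * 5])
        kept = high_variance_filter(m, mean_min=5, var_min=1.5)
        assert kept == ["g0"]

    def test_matches_brute_force(self, rng):
        values = np.abs(rng.normal(5, 3, (40, 12)))
        m = vst_matrix(values)
        kept = high_variance_filter(m, mean_min=4, var_min=2)
        expected = [
            f"g{i}"
            for i in range(40)
            if values[i].mean() > 4 and values[i].var(ddof=1) > 2
        ]
        assert kept == expected

    def test_empty_result_is_error(self):
        m = vst_matrix([[1.0] * 5])
        with pytest.raises(ValidationError, match="filter"):
            high_variance_filter(m)


class TestTauCritical:
    def test_closed_form_example(self):
        # one gene pair, n=10: 1.96 * sqrt(50/810)
        assert tau_critical(10, 2, 0.05) == pytest.approx(1.96 * np.sqrt(50 / 810), abs=1e-3)

    def test_decreasing_in_sample_count(self):
        values = [tau_critical(n, 2, 0.05) for n in (5, 10, 20, 50, 100)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_matches_permutation_null_quantile(self, rng):
        # empirical |tau| critical value at n=12 from 20,000 shuffles
        n = 12
        x = np.arange(n, dtype=float)
        taus = np.empty(20_000)
        for k in range(20_000):
            taus[k] = kendalltau(x, rng.permutation(n)).statistic
        empirical = np.quantile(np.abs(taus), 0.95)
        assert abs(tau_critical(n, 2, 0.05) - empirical) < 0.03

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValidationError):
            tau_critical(10, 1)


class TestCutClusters:
    def test_gene_order_invariance(self, rng):
        spec = CohortSpec(
            n_genes=80,
            samples_per_tissue=60,
            seed=9,
            correlated_blocks=[CorrelatedBlock(10, 0.7)],
        )
        sim = generate_cohort(spec)
        from matriscope.normalize import vst_transform

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = vst_transform(sim.counts)
            res1 = cut_clusters(v)
            shuffled = v.data.sample(frac=1.0, random_state=1)
            res2 = cut_clusters(ExpressionMatrix(shuffled, units="vst"))
        sets1 = sorted(sorted(g) for g in res1.clusters.values())
        sets2 = sorted(sorted(g) for g in res2.clusters.values())
        assert sets1 == sets2

    def test_reported_clusters_respect_tau_bound(self):
        spec = CohortSpec(
            n_genes=100,
            samples_per_tissue=80,
            seed=13,
            correlated_blocks=[CorrelatedBlock(12, 0.6)],
        )
        sim = generate_cohort(spec)
        from matriscope.normalize import vst_transform

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = vst_transform(sim.counts)
            res = cut_clusters(v)
        for genes in res.clusters.values():
            assert len(genes) >= 2
            vals = v.data.loc[genes].to_numpy()
            taus = [
                kendalltau(vals[i], vals[j]).statistic
                for i in range(len(genes))
                for j in range(i + 1, len(genes))
            ]
            assert np.mean(taus) >= res.tau_critical

    def test_too_few_genes_is_error(self):
        m = vst_matrix(np.random.default_rng(0).normal(5, 1, (2, 10)))
        with pytest.raises(ValidationError):
            cut_clusters(m)


class TestClusterScore:
    def test_hand_example(self):
        # values [1,2,3,4]: mean 2.5, median 2.5, MAD 1.0 -> [-1.5,-0.5,0.5,1.5]
        m = vst_matrix([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        samples = make_sample_table(["s0", "s1", "s2", "s3"], ["T"] * 4)
        cs = cluster_score(m, samples, ["g0", "g1"])
        np.testing.assert_allclose(cs.scores, [-1.5, -0.5, 0.5, 1.5])
        assert cs.J("T") == 2

    def test_sample_at_gene_means_scores_zero(self, rng):
        vals = rng.normal(8, 2, (5, 9))
        vals[:, 0] = vals[:, 1:].mean(axis=1)
        samples = make_sample_table([f"s{j}" for j in range(9)], ["T"] * 9)
        # adjust: center is mean over ALL samples incl s0; set s0 to overall mean via fixpoint
        for _ in range(50):
            vals[:, 0] = vals.mean(axis=1)
        cs = cluster_score(vst_matrix(vals), samples, [f"g{i}" for i in range(5)])
        assert abs(cs.scores.iloc[0]) < 1e-10

    def test_tissue_mean_is_exactly_zero(self, rng):
        vals = np.abs(rng.normal(8, 2, (6, 20)))
        tissues = ["A"] * 12 + ["B"] * 8
        samples = make_sample_table([f"s{j}" for j in range(20)], tissues)
        cs = cluster_score(vst_matrix(vals), samples, [f"g{i}" for i in range(6)])
        for t in ("A", "B"):
            mask = [tt == t for tt in tissues]
            assert abs(cs.scores[mask].mean()) < 1e-13

    def test_per_gene_affine_invariance(self, rng):
        vals = np.abs(rng.normal(8, 2, (4, 15)))
        samples = make_sample_table([f"s{j}" for j in range(15)], ["T"] * 15)
        genes = [f"g{i}" for i in range(4)]
        base = cluster_score(vst_matrix(vals), samples, genes).scores
        vals2 = vals.copy()
        vals2[1] = 3.7 * vals2[1] + 11.0  # positive scale + shift
        shifted = cluster_score(vst_matrix(vals2), samples, genes).scores
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_zero_mad_gene_excluded_and_j_adjusted(self):
        vals = np.array([[1.0, 2, 3, 4], [5.0, 5, 5, 5]])
        samples = make_sample_table(["s0", "s1", "s2", "s3"], ["T"] * 4)
        with pytest.warns(UserWarning, match="zero-MAD"):
            cs = cluster_score(vst_matrix(vals), samples, ["g0", "g1"])
        assert cs.J("T") == 1
        np.testing.assert_allclose(cs.scores, [-1.5, -0.5, 0.5, 1.5])

    def test_all_zero_mad_is_error(self):
        vals = np.array([[5.0, 5, 5, 5]])
        samples = make_sample_table(["s0", "s1", "s2", "s3"], ["T"] * 4)
        with pytest.raises(ValidationError, match="zero MAD"):
            cluster_score(vst_matrix(vals), samples, ["g0"])


class TestAssociationModels:
    def test_noiseless_fixed_effects_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame(
            {
                "score": rng.normal(0, 1, n),
                "bmi": rng.normal(27, 4, n),
                "sex": rng.choice(["M", "F"], n),
            }
        )
        df["percent_adipose"] = 10 + 3.0 * df["score"] - 0.5 * df["bmi"] + 2.0 * (df["sex"] == "M")
        fit = association_models(df, "percent_adipose", ["score", "bmi", "sex"])
        assert fit.params["score"] == pytest.approx(3.0, abs=1e-10)
        assert fit.params["bmi"] == pytest.approx(-0.5, abs=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-16)

    def test_random_intercept_model_recovers_slope(self):
        rng = np.random.default_rng(42)
        hits = 0
        reps = 25
        for _ in range(reps):
            subjects = np.repeat(np.arange(14), 4)
            u = rng.normal(0, 1.0, 14)[subjects]
            score = rng.normal(0, 20, 14)[subjects]
            y = 1.0 + 0.03 * score + u + rng.normal(0, 0.5, len(subjects))
            df = pd.DataFrame({"y": y, "score": score, "subject": subjects})
            fit = association_models(df, "y", ["score"], random_intercept="subject")
            if abs(fit.params["score"] - 0.03) <= 3 * fit.bse["score"]:
                hits += 1
        assert hits / reps >= 0.8  # nominal ~0.997; wide margin at 25 reps
        assert fit.random_intercept_variance is not None

    def test_singular_design_is_error(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": [1.0, 1, 1, 1]})
        with pytest.raises(ValidationError, match="singular"):
            association_models(df, "y", ["a"])


class TestMultiTissueScore:
    def make_cohort(self):
        return generate_cohort(
            CohortSpec(n_genes=30, n_tissues=4, samples_per_tissue=20, seed=21)
        )

    def test_identical_values_give_that_value(self):
        genes = ["g0"]
        sample_ids, tissues, subjects = [], [], []
        for t in ("A", "B"):
            for s in ("p1", "p2"):
                sample_ids.append(f"{s}-{t}")
                tissues.append(t)
                subjects.append(s)
        m = ExpressionMatrix(
            pd.DataFrame([[7.0, 3.0, 7.0, 3.0]], index=genes, columns=sample_ids),
            units="vst",
        )
        samples = make_sample_table(sample_ids, tissues, subject_id=subjects)
        scores = multi_tissue_gene_score(m, samples, "g0", ["A", "B"])
        assert scores["p1"] == pytest.approx(7.0)
        assert scores["p2"] == pytest.approx(3.0)

    def test_ranking_matches_brute_force_mean(self):
        sim = self.make_cohort()
        from matriscope.normalize import vst_transform

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = vst_transform(sim.counts)
        gene = v.gene_ids[5]
        tissues = ["TISSUE1", "TISSUE2", "TISSUE3", "TISSUE4"]
        scores = multi_tissue_gene_score(v, sim.samples, gene, tissues)
        annot = sim.samples.data
        for subj in scores.index[:10]:
            vals = [
                v.data.loc[gene, annot.index[(annot["subject_id"] == subj) & (annot["tissue"] == t)]].mean()
                for t in tissues
            ]
            assert scores[subj] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_extreme_selector_bounds_and_blinding(self):
        scores = pd.Series(np.arange(10.0), index=[f"p{i}" for i in range(10)])
        out = select_extreme_subjects(scores, top_k=3, bottom_k=2, seed=0)
        assert len(out) == 5
        assert set(out.loc[out["group"] == "top", "subject_id"]) == {"p7", "p8", "p9"}
        with pytest.raises(ValidationError, match="exceeds"):
            select_extreme_subjects(scores, top_k=8, bottom_k=8)


class TestSampleCluster:
    def test_centering_is_exact(self, rng):
        vals = np.abs(rng.normal(8, 2, (5, 12)))
        m = vst_matrix(vals)
        samples = make_sample_table([f"s{j}" for j in range(12)], ["T"] * 12, disease=["normal"] * 12)
        groups, crosstab = sample_cluster(m, samples, k=2)
        assert set(groups.unique()) == {1, 2}
        assert crosstab.to_numpy().sum() == 12

    def test_duplicate_samples_share_a_group(self, rng):
        vals = np.abs(rng.normal(8, 2, (5, 6)))
        vals[:, 3] = vals[:, 0]  # duplicate
        m = vst_matrix(vals)
        samples = make_sample_table([f"s{j}" for j in range(6)], ["T"] * 6, disease=["normal"] * 6)
        groups, _ = sample_cluster(m, samples, k=3)
        assert groups["s0"] == groups["s3"]

    def test_k_exceeding_samples_is_error(self, rng):
        m = vst_matrix(np.abs(rng.normal(8, 2, (3, 4))))
        samples = make_sample_table([f"s{j}" for j in range(4)], ["T"] * 4, disease=["normal"] * 4)
        with pytest.raises(ValidationError):
            sample_cluster(m, samples, k=5)
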