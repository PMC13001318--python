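"""Pseudobulk differential expression, TMM, dispersion, permutations."""

import math

import numpy as np
import pandas as pd
import pytest

from raven import de, synthetic


def equal_offset_tmm(counts):
    """TMM stand-in that equalizes effective library sizes exactly."""
    lib = counts.sum(axis=0)
    gm = np.exp(np.mean(np.log(lib)))
    return gm / lib


class TestTMM:
    def test_identical_samples_unity(self):
        c = pd.DataFrame(
            np.tile([[5], [10], [20], [100]], (1, 3)), columns=list("abc")
        )
        assert de.tmm_factors(c).to_numpy() == pytest.approx([1, 1, 1])

    def test_pure_depth_change(self, rng):
        base = rng.poisson(50, 300) + 1
        c = pd.DataFrame({"a": base, "b": base * 2})
        assert de.tmm_factors(c).to_numpy() == pytest.approx([1, 1], abs=1e-6)

    def test_outlier_gene_trimmed(self, rng):
        """A single 100x gene is trimmed out of the M values; the factors
        only reflect the (small) library-composition shift it causes."""
        base = rng.poisson(50, 2000) + 1
        c = pd.DataFrame({"a": base.copy(), "b": base.copy()})
        c.iloc[0, 1] = base[0] * 100
        f = de.tmm_factors(c).to_numpy()
        assert np.all(np.abs(f - 1) < 0.05)

    def test_geometric_mean_one(self, rng):
        c = pd.DataFrame(rng.poisson(30, size=(500, 6)) + 1)
        f = de.tmm_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_errors(self):
        c = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            de.tmm_factors(c)


class TestNbGlmLrt:
    def test_poisson_limit_closed_form(self):
        """phi -> 0: LRT equals the Poisson deviance difference,
        2[22 ln(11/20) + 58 ln(29/20)] for counts {10,12} vs {30,28}."""
        counts = pd.DataFrame(
            {"s1": [10], "s2": [12], "s3": [30], "s4": [28]}, index=["g1"]
        )
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": [0.0, 0, 1, 1]}, index=counts.columns
        )
        res = de.nb_glm_lrt(
            counts, design, "disease", 1e-8, tmm=equal_offset_tmm(counts)
        )
        expected = 2 * (22 * math.log(11 / 20) + 58 * math.log(29 / 20))
        assert res.iloc[0]["lrt_stat"] == pytest.approx(expected, abs=1e-3)

    def test_null_pvalues_uniform(self, rng):
        """No group difference: LRT p-values approximately uniform."""
        from scipy import stats

        g, s = 800, 30
        mu = rng.lognormal(3.5, 0.8, size=(g, 1)) * np.ones((1, s))
        phi = 0.2
        r = 1 / phi
        Y = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(Y, columns=[f"s{i}" for i in range(s)])
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "disease": np.r_[np.zeros(15), np.ones(15)],
            },
            index=counts.columns,
        )
        res = de.nb_glm_lrt(
            counts, design, "disease", phi, tmm=equal_offset_tmm(counts)
        )
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_lrt_nonnegative(self, rng):
        g, s = 100, 16
        Y = rng.poisson(20, size=(g, s))
        counts = pd.DataFrame(Y, columns=[f"s{i}" for i in range(s)])
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": np.r_[np.zeros(8), np.ones(8)]},
            index=counts.columns,
        )
        res = de.nb_glm_lrt(counts, design, "disease", 0.1)
        assert (res["lrt_stat"] >= 0).all()


class TestDispersion:
    def test_poisson_counts_small_dispersion(self, rng):
        g, s = 200, 20
        mu = rng.lognormal(4, 0.8, size=(g, 1)) * np.ones((1, s))
        counts = pd.DataFrame(rng.poisson(mu), columns=[f"s{i}" for i in range(s)])
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": np.r_[np.zeros(10), np.ones(10)]},
            index=counts.columns,
        )
        common, _ = de.estimate_dispersion(
            counts, design, tmm=equal_offset_tmm(counts)
        )
        assert common < 0.05

    def test_nb_dispersion_recovery(self, rng):
        g, s = 500, 24
        mu = rng.lognormal(4, 1, size=(g, 1)) * np.ones((1, s))
        phi = 0.4
        r = 1 / phi
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu)),
            columns=[f"s{i}" for i in range(s)],
        )
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": np.r_[np.zeros(12), np.ones(12)]},
            index=counts.columns,
        )
        common, tagwise = de.estimate_dispersion(
            counts, design, tmm=equal_offset_tmm(counts)
        )
        assert 0.2 <= common <= 0.6
        assert tagwise.shape == (g,)

    def test_no_residual_df_errors(self):
        counts = pd.DataFrame({"s1": [5], "s2": [6]})
        design = pd.DataFrame(
            {"intercept": 1.0, "disease": [0.0, 1.0]}, index=counts.columns
        )
        with pytest.raises(ValueError):
            de.estimate_dispersion(counts, design)


class TestCovariateScreen:
    def _counts(self, rng, s=24, g=400):
        mu = rng.lognormal(4, 1, size=(g, 1)) * np.ones((1, s))
        return pd.DataFrame(
            rng.poisson(mu), columns=[f"s{i}" for i in range(s)]
        )

    def test_covariate_tracking_pc1_selected(self, rng):
        counts = self._counts(rng)
        # Build a covariate equal to the leading expression PC.
        lc = de.cpm(counts, log2=True)
        top = lc.var(axis=1).nlargest(200).index
        X = lc.loc[top].T - lc.loc[top].T.mean()
        u, sv, _ = np.linalg.svd(X.to_numpy(), full_matrices=False)
        cov = pd.DataFrame({"pc_mirror": u[:, 0]}, index=counts.columns)
        assert de.screen_covariates(counts, cov) == ["pc_mirror"]

    def test_orthogonal_covariate_not_selected(self, rng):
        counts = self._counts(rng)
        cov = pd.DataFrame(
            {"noise": rng.normal(size=counts.shape[1])}, index=counts.columns
        )
        # Independent noise: correlation with the top PCs is ~ 1/sqrt(n),
        # far below the 0.4 gate with overwhelming probability.
        assert de.screen_covariates(counts, cov, r_min=0.9) == []

    def test_constant_covariate_warns(self, rng):
        counts = self._counts(rng)
        cov = pd.DataFrame({"flat": 1.0}, index=counts.columns)
        with pytest.warns(UserWarning, match="constant"):
            out = de.screen_covariates(counts, cov)
        assert out == []


class TestPermutationBurden:
    def _null_data(self, seed, g=150, n=12):
        cfg = synthetic.CohortConfig(
            seed=seed,
            n_pb_cases=n,
            n_pb_controls=n,
            n_pb_genes=g,
            n_de_genes=0,
            n_stage_genes=0,
        )
        counts, meta, _ = synthetic.generate_pseudobulk(
            cfg, synthetic.SyntheticTruth()
        )
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "disease": (meta["disease"] == "PD").astype(float),
            },
            index=counts.columns,
        )
        return counts, design

    def test_null_burden_not_significant(self):
        counts, design = self._null_data(seed=11)
        res = de.permutation_deg_burden(counts, design, B=100, seed=5)
        assert res["empirical_p"] > 0.05
        assert res["null_counts"].shape == (100,)

    def test_planted_de_burden_significant(self):
        cfg = synthetic.CohortConfig(
            seed=3, n_pb_genes=300, n_de_genes=50, de_logfc=1.5
        )
        counts, meta, _ = synthetic.generate_pseudobulk(
            cfg, synthetic.SyntheticTruth()
        )
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "disease": (meta["disease"] == "PD").astype(float),
            },
            index=counts.columns,
        )
        res = de.permutation_deg_burden(counts, design, B=200, seed=1)
        assert res["empirical_p"] <= 0.01
        assert res["fold_enrichment"] > 1

    def test_zero_observed_p_one(self):
        counts, design = self._null_data(seed=21)
        res = de.permutation_deg_burden(counts, design, B=50, seed=2)
        if res["observed_deg_count"] == 0:
            assert res["empirical_p"] == 1.0

    def test_b_validation(self):
        counts, design = self._null_data(seed=31)
        with pytest.raises(ValueError):
            de.permutation_deg_burden(counts, design, B=0)


class TestRegionOverlap:
    def test_disjoint_sets(self):
        obs = {"r1": {"a", "b"}, "r2": {"c", "d"}}
        perms = [{"r1": set(), "r2": set()}] * 10
        res = de.region_overlap_permutation(obs, perms)
        assert res["observed_shared"] == 0
        assert res["empirical_p"] == 1.0

    def test_identical_sets(self):
        genes = {f"g{i}" for i in range(10)}
        obs = {"r1": set(genes), "r2": set(genes)}
        perms = [{"r1": set(), "r2": set()}] * 20
        res = de.region_overlap_permutation(obs, perms)
        assert res["observed_shared"] == 10
        assert res["empirical_p"] == pytest.approx(1 / 21)

    def test_single_region_errors(self):
        with pytest.raises(ValueError):
            de.region_overlap_permutation({"r1": set()}, [])


class TestTrajectory:
    def _stage_data(self, rng, slopes, g_extra=60):
        stages = ["I", "IIa", "III", "IV"]
        n_per = 6
        samples = []
        meta_rows = []
        for si, st_lab in enumerate(stages):
            for r in range(n_per):
                samples.append(f"s_{st_lab}_{r}")
                meta_rows.append({"disease": "PD", "stage": st_lab})
        meta = pd.DataFrame(meta_rows, index=samples)
        base = rng.lognormal(4, 0.5, size=(len(slopes) + g_extra, 1))
        stage_num = np.repeat(np.arange(1, 5), n_per)
        eta = np.log(base) * np.ones((1, len(samples)))
        for i, sl in enumerate(slopes):
            eta[i] += sl * (stage_num - 1)
        counts = pd.DataFrame(
            rng.poisson(np.exp(eta)),
            index=[f"g{i}" for i in range(eta.shape[0])],
            columns=samples,
        )
        return counts, meta

    def test_monotonic_classification(self, rng):
        counts, meta = self._stage_data(rng, slopes=[0.8, -0.8])
        res = de.trajectory_classify(counts, meta, dispersion=0.05)
        assert res.loc["g0", "class"] == "monotonic_increase"
        assert res.loc["g1", "class"] == "monotonic_decrease"

    def test_nonmonotonic_profile_other(self):
        """Per-stage means (1,3,2,4) violate monotonicity."""
        prof = np.array([1.0, 3.0, 2.0, 4.0])
        d = np.diff(prof)
        assert not (np.all(d >= 0) or np.all(d <= 0))

    def test_unknown_stage_errors(self, rng):
        counts, meta = self._stage_data(rng, slopes=[0.5])
        meta.iloc[0, meta.columns.get_loc("stage")] = "V"
        with pytest.raises(ValueError, match="stage"):
            de.trajectory_classify(counts, meta, dispersion=0.05)
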