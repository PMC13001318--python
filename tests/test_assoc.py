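"""Weighted kernel association testing: SKAT, burden, SKAT-O, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from raven import assoc


def intercept_null(y):
    return assoc.fit_null_logistic(np.asarray(y, dtype=float), np.ones((len(y), 1)))


class TestNullModel:
    def test_intercept_only_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        null = intercept_null(y)
        assert null.beta[0] == pytest.approx(np.log(30 / 70), abs=1e-6)

    def test_balanced_intercept_zero(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        null = intercept_null(y)
        assert null.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(null.mu, 0.5)

    def test_separation_detected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.column_stack([np.ones(20), y])  # perfectly separating covariate
        with pytest.raises(assoc.SeparationError):
            assoc.fit_null_logistic(y, x)

    def test_rank_deficient(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            assoc.fit_null_logistic(y, X)


class TestMixturePvalue:
    def test_single_lambda_exact(self):
        lam = [0.75]
        assert assoc.chi2_mixture_pvalue(1.0, lam) == pytest.approx(
            stats.chi2.sf(4 / 3, 1)
        )

    def test_ruben_matches_monte_carlo(self, rng):
        lam = np.array([2.0, 1.0, 0.3])
        draws = (lam * rng.chisquare(1, size=(400_000, 3))).sum(axis=1)
        for q in (1.0, 5.0, 12.0):
            p = assoc.chi2_mixture_pvalue(q, lam)
            p_mc = (draws >= q).mean()
            se = np.sqrt(p_mc * (1 - p_mc) / draws.size)
            assert abs(p - p_mc) < 4 * se

    def test_exact_vs_liu_tail_agreement(self):
        """Moment matching tracks the exact tail probability closely for
        well-conditioned spectra in the small-p regime."""
        lam = np.array([1.0, 0.9, 0.8, 0.5, 0.3])
        q = 25.0
        p_exact = assoc.chi2_mixture_pvalue(q, lam)
        p_liu = assoc.chi2_mixture_pvalue(q, lam, method="liu")
        assert p_exact < 0.01
        assert abs(p_exact - p_liu) < 1e-4

    def test_zero_q(self):
        assert assoc.chi2_mixture_pvalue(0.0, [1.0, 2.0]) == 1.0


class TestSkat:
    def test_closed_form_small_case(self):
        """n=4, y=(1,1,0,0), mu=0.5, g=(2,0,0,0), w=1: Q=1, lambda=0.75."""
        null = intercept_null([1, 1, 0, 0])
        G = np.array([2.0, 0, 0, 0])[:, None]
        q, p = assoc.skat_test(G, [1.0], null)
        assert q == pytest.approx(1.0)
        assert p == pytest.approx(stats.chi2.sf(4 / 3, 1), abs=1e-10)

    def test_zero_weights(self):
        null = intercept_null([1, 1, 0, 0])
        G = np.array([2.0, 0, 1, 0])[:, None]
        q, p = assoc.skat_test(G, [0.0], null)
        assert q == 0.0 and p == 1.0

    def test_single_variant_skat_equals_burden(self, rng):
        y = rng.binomial(1, 0.5, 60).astype(float)
        y[:5] = 1; y[-5:] = 0
        null = intercept_null(y)
        G = rng.binomial(2, 0.1, 60).astype(float)[:, None]
        q_s, p_s = assoc.skat_test(G, [1.3], null)
        q_b, p_b = assoc.burden_test(G, [1.3], null)
        assert p_s == pytest.approx(p_b, abs=1e-8)

    def test_weight_rescaling_invariance(self, rng):
        y = np.r_[np.ones(25), np.zeros(35)]
        null = intercept_null(y)
        G = rng.binomial(2, 0.15, size=(60, 4)).astype(float)
        w = np.array([1.0, 0.5, 2.0, 0.1])
        q1, p1 = assoc.skat_test(G, w, null)
        q2, p2 = assoc.skat_test(G, 3.0 * w, null)
        assert q2 == pytest.approx(9.0 * q1)
        assert p2 == pytest.approx(p1, abs=1e-7)

    def test_mean_imputation_of_missing(self):
        null = intercept_null([1, 1, 0, 0, 1, 0])
        G = np.array([2.0, np.nan, 0, 0, 1, np.nan])[:, None]
        q, p = assoc.skat_test(G, [1.0], null)
        assert np.isfinite(q) and 0 < p <= 1

    def test_burden_cancellation(self):
        """Opposite-direction carriers cancel in burden but not in SKAT."""
        y = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=float)
        null = intercept_null(y)
        # variant 1 carried by cases, variant 2 by controls
        G = np.array(
            [[2, 0], [2, 0], [0, 2], [0, 2], [2, 0], [0, 2], [2, 0], [0, 2]],
            dtype=float,
        )
        q_b, _ = assoc.burden_test(G, [1.0, 1.0], null)
        q_s, _ = assoc.skat_test(G, [1.0, 1.0], null)
        assert q_b == pytest.approx(0.0, abs=1e-12)
        assert q_s > 0

    def test_permutation_oracle_tail(self, rng):
        """At n<=12 the asymptotic p tracks the exhaustive permutation p in
        the tail regime (the asymptotics are approximate at the center)."""
        checked = 0
        for trial in range(12):
            n = 10 + 2 * (trial % 2)
            y = np.zeros(n)
            y[: n // 2] = 1
            rng.shuffle(y)
            G = rng.binomial(1, 0.3, size=(n, 2)).astype(float)
            if G.sum() == 0:
                continue
            w = np.array([1.0, 0.7])
            null = intercept_null(y)
            q_obs, p_dav = assoc.skat_test(G, w, null)
            ge = tot = 0
            for perm in multiset_permutations(list(y.astype(int))):
                yp = np.asarray(perm, dtype=float)
                s = G.T @ (yp - null.mu)
                q = float(np.sum((w * s) ** 2))
                tot += 1
                ge += q >= q_obs - 1e-12
            p_perm = ge / tot
            if p_perm <= 0.2:
                checked += 1
                assert abs(p_dav - p_perm) <= 0.1
        assert checked >= 1


class TestSkatO:
    def test_single_variant_all_equal(self):
        null = intercept_null([1, 1, 0, 0])
        G = np.array([2.0, 0, 0, 0])[:, None]
        res = assoc.skato_combine(G, [1.0], null)
        assert res["p_skato"] == pytest.approx(res["p_skat"])

    def test_bonferroni_bound_holds(self, rng):
        y = np.r_[np.ones(40), np.zeros(60)]
        null = intercept_null(y)
        for _ in range(5):
            G = rng.binomial(2, 0.05, size=(100, 6)).astype(float)
            w = rng.uniform(0.5, 2, 6)
            res = assoc.skato_combine(G, w, null)
            bound = min(res["p_rho"]) * len(res["rho_grid"])
            assert res["p_skato"] <= bound + 1e-12

    def test_grid_validation(self):
        null = intercept_null([1, 1, 0, 0])
        G = np.zeros((4, 2))
        with pytest.raises(ValueError):
            assoc.skato_combine(G, [1, 1], null, rho_grid=(0.0, 0.5))
        with pytest.raises(ValueError):
            assoc.skato_combine(G, [1, 1], null, rho_grid=(0.0, 0.5, 1.5))


class TestUnitsAndWeights:
    def _triplets(self):
        return pd.DataFrame(
            {
                "gene_id": ["G1", "G1", "G1", "G2"],
                "variant_id": ["v1", "v2", "v3", "v4"],
                "cell_type": "ct1",
                "peak_id": ["p1", "p1", "p2", "p3"],
                "score": [0.9, 0.8, 0.7, 0.95],
            }
        )

    def test_maf_filter(self):
        af = pd.Series({"v1": 0.02, "v2": 0.001, "v3": 0.005, "v4": 0.002})
        units = assoc.build_testing_units(
            self._triplets(), af, maf_max=0.01, top_fraction=1.0
        )
        by_id = {u.unit_id: u for u in units}
        assert "v1" not in by_id["G1"].variant_ids  # MAF 0.02 excluded
        assert set(by_id["G1"].variant_ids) == {"v2", "v3"}

    def test_gene_vs_peak_level(self):
        af = pd.Series({"v1": 0.001, "v2": 0.001, "v3": 0.005, "v4": 0.002})
        gene_units = assoc.build_testing_units(
            self._triplets(), af, top_fraction=1.0
        )
        assert {u.unit_id: len(u.variant_ids) for u in gene_units} == {
            "G1": 3,
            "G2": 1,
        }
        peak_units = assoc.build_testing_units(
            self._triplets(), af, top_fraction=1.0, level="peak"
        )
        assert {u.unit_id: len(u.variant_ids) for u in peak_units} == {
            "p1": 2,
            "p2": 1,
            "p3": 1,
        }

    def test_missing_af_dropped_with_warning(self):
        af = pd.Series({"v1": 0.001, "v2": 0.001, "v3": 0.005})
        with pytest.warns(UserWarning, match="allele frequency"):
            units = assoc.build_testing_units(
                self._triplets(), af, top_fraction=1.0
            )
        assert all("v4" not in u.variant_ids for u in units)

    def test_beta_weight_closed_form(self):
        unit = assoc.TestingUnit("G1", "ct1", ["v1"])
        af = pd.Series({"v1": 0.001})
        scores = pd.Series({"v1": 0.5})
        w = assoc.compute_weights(unit, af, scores)
        assert w[0] == pytest.approx(25 * 0.999**24, rel=1e-9)

    def test_zero_score_zero_weight(self):
        unit = assoc.TestingUnit("G1", "ct1", ["v1", "v2"])
        af = pd.Series({"v1": 0.001, "v2": 0.001})
        scores = pd.Series({"v1": 0.0, "v2": 0.4})
        w = assoc.compute_weights(unit, af, scores)
        assert w[0] == 0.0

    def test_weight_proportional_to_score(self):
        unit = assoc.TestingUnit("G1", "ct1", ["v1", "v2"])
        af = pd.Series({"v1": 0.003, "v2": 0.003})
        scores = pd.Series({"v1": 0.2, "v2": 0.4})
        w = assoc.compute_weights(unit, af, scores)
        assert w[1] / w[0] == pytest.approx(2.0)


class TestDiagnostics:
    def test_lambda_all_half(self):
        assert assoc.genomic_lambda([0.5] * 10) == pytest.approx(1.0)

    def test_lambda_chi2_one(self):
        p = stats.chi2.sf(1.0, 1)
        lam = assoc.genomic_lambda([p] * 7)
        assert lam == pytest.approx(1 / 0.4549364, rel=1e-4)

    def test_lambda_uniform_near_one(self, rng):
        p = rng.uniform(0, 1, 10_000)
        assert assoc.genomic_lambda(p) == pytest.approx(1.0, abs=0.05)

    def test_lambda_empty_errors(self):
        with pytest.raises(ValueError):
            assoc.genomic_lambda([])

    def test_skat_null_lambda_calibrated(self, rng):
        """lambda over SKAT p-values from null simulations stays near 1
        when the statistic's distribution is smooth (common variants);
        with very rare variants the median-based diagnostic drifts, which
        is the behavior the diagnostic exists to reveal."""
        n, m = 300, 10
        pvals = []
        for _ in range(2000):
            y = rng.binomial(1, 0.5, n).astype(float)
            mafs = rng.uniform(0.05, 0.3, m)
            G = rng.binomial(2, mafs[None, :], (n, m)).astype(float)
            null = assoc.fit_null_logistic(y, np.ones((n, 1)))
            _, p = assoc.skat_test(G, np.ones(m), null)
            pvals.append(p)
        lam = assoc.genomic_lambda(pvals)
        assert 0.9 <= lam <= 1.1

    def test_two_tier_bh(self):
        res = pd.DataFrame(
            {
                "unit_id": ["a", "b", "c"],
                "cell_type": ["ct1", "ct1", "ct1"],
                "p_skato": [0.001, 0.02, 0.8],
            }
        )
        out = assoc.multiple_testing(res)
        assert out["fdr_cell_type"].to_numpy() == pytest.approx(
            [0.003, 0.03, 0.8]
        )

    def test_single_test_adjusted_equals_raw(self):
        res = pd.DataFrame(
            {"unit_id": ["a"], "cell_type": ["ct1"], "p_skato": [0.04]}
        )
        out = assoc.multiple_testing(res)
        assert out["fdr_global"].iloc[0] == pytest.approx(0.04)

    def test_all_ones_nothing_flagged(self):
        res = pd.DataFrame(
            {
                "unit_id": list("abc"),
                "cell_type": ["ct1"] * 3,
                "p_skato": [1.0, 1.0, 1.0],
            }
        )
        out = assoc.multiple_testing(res)
        assert not out["cell_type_significant"].any()
        assert not out["globally_significant"].any()


class TestCohortUtilities:
    def test_printed_cohort_10to1_match(self):
        cases = pd.DataFrame(
            {"sex": ["M"] * 1941 + ["F"] * 1129},
            index=[f"case{i}" for i in range(3070)],
        )
        pool = pd.DataFrame(
            {"sex": ["M"] * 25_000 + ["F"] * 20_000},
            index=[f"ctrl{i}" for i in range(45_000)],
        )
        out = assoc.select_matched_controls(cases, pool, ratio=10, seed=0)
        assert len(out) == 30_700
        assert (out["sex"] == "M").sum() == 19_410
        assert (out["sex"] == "F").sum() == 11_290
        assert out.index.is_unique

    def test_ratio_one_whole_pool(self):
        cases = pd.DataFrame({"sex": ["M", "F"]}, index=["c1", "c2"])
        pool = pd.DataFrame({"sex": ["M", "F"]}, index=["p1", "p2"])
        out = assoc.select_matched_controls(cases, pool, ratio=1, seed=1)
        assert sorted(out.index) == ["p1", "p2"]

    def test_shortfall_names_sex(self):
        cases = pd.DataFrame({"sex": ["F"]}, index=["c1"])
        pool = pd.DataFrame({"sex": ["F"] * 5}, index=[f"p{i}" for i in range(5)])
        with pytest.raises(ValueError, match="F"):
            assoc.select_matched_controls(cases, pool, ratio=10)

    def test_replication_lookup_counts(self):
        hits = pd.DataFrame(
            {"unit_id": [f"g{i}" for i in range(78)], "cell_type": "ct1"}
        )
        rep = pd.DataFrame(
            {
                "unit_id": [f"g{i}" for i in range(78)],
                "cell_type": "ct1",
                # four tiny p-values survive BH over the searched subset
                "p_skato": [1e-6] * 4 + [0.9] * 74,
            }
        )
        out = assoc.replication_lookup(hits, rep)
        assert int(out["replicated"].sum()) == 4

    def test_replication_untested_flag(self):
        hits = pd.DataFrame({"unit_id": ["gX"], "cell_type": ["ct1"]})
        rep = pd.DataFrame(
            {"unit_id": ["gY"], "cell_type": ["ct1"], "p_skato": [0.01]}
        )
        out = assoc.replication_lookup(hits, rep)
        assert out.iloc[0]["status"] == "untested"
        assert not out.iloc[0]["replicated"]

    def test_replication_empty(self):
        out = assoc.replication_lookup(
            pd.DataFrame(columns=["unit_id", "cell_type"]),
            pd.DataFrame(columns=["unit_id", "cell_type", "p_skato"]),
        )
        assert out.empty
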