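"""Association layer: FDR, rank tests, partial correlations, mixed model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mesoinfluence import stats
from mesoinfluence.stats import (
    adjusted_group_difference,
    adjusted_partial_correlation,
    bh_fdr,
    connectivity_table,
    cross_state_spearman,
    fit_adjusted_regression,
    learning_mixed_model,
    rank_sum_test,
    seed_roi_connectivity,
)


class TestSeedRoiConnectivity:
    def test_matches_correlation_matrix_entry(self, rng):
        from mesoinfluence.depna import correlation_matrix

        panel = rng.standard_normal((5, 300))
        z = seed_roi_connectivity(panel, 0, 3)
        C = correlation_matrix(panel)
        assert z == pytest.approx(C.z[0, 3], abs=1e-12)

    def test_identical_series_clipped(self, rng):
        x = rng.standard_normal(100)
        panel = np.vstack([x, x])
        assert seed_roi_connectivity(panel, 0, 1) == pytest.approx(np.arctanh(0.99))

    def test_independent_noise_small(self, rng):
        panel = rng.standard_normal((2, 5000))
        assert abs(seed_roi_connectivity(panel, 0, 1)) < 0.05

    def test_table_layout(self, rng):
        panels = [rng.standard_normal((3, 50)) for _ in range(4)]
        t = connectivity_table(panels, list("abcd"), ["VTA", "NAc", "BLA"], seed="VTA")
        assert list(t.columns) == ["NAc", "BLA", "state"]
        assert len(t) == 4


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(bh_fdr(np.ones(5)) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_dominates_p(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_null_calibration(self):
        """BH on uniform p-values: family-wise false discoveries at nominal rate."""
        rng = np.random.default_rng(0)
        any_disc = [np.any(bh_fdr(rng.random(7)) < 0.05) for _ in range(2000)]
        assert abs(np.mean(any_disc) - 0.05) < 0.02


class TestRankSum:
    def test_extreme_separation_exact_p(self):
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments as extreme

    def test_swap_invariance(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(y, x)
        assert p1 == pytest.approx(p2)

    def test_matches_enumeration_all_small_inputs(self, rng):
        """Exact-path p equals an independent full-enumeration oracle, n <= 6."""
        for n1, n2 in [(2, 2), (2, 3), (3, 3), (2, 4), (1, 5), (3, 2)]:
            for _ in range(5):
                x = rng.integers(0, 5, n1).astype(float)  # ties likely
                y = rng.integers(0, 5, n2).astype(float)
                w, p = rank_sum_test(x, y)
                from scipy.stats import rankdata

                pooled = np.concatenate([x, y])
                ranks = rankdata(pooled)
                mu = n1 * (n1 + n2 + 1) / 2
                stats_all = [
                    ranks[list(c)].sum()
                    for c in itertools.combinations(range(n1 + n2), n1)
                ]
                p_oracle = np.mean(
                    [abs(s - mu) >= abs(w - mu) - 1e-12 for s in stats_all]
                )
                assert p == pytest.approx(p_oracle)

    def test_normal_approx_calibration(self):
        rng = np.random.default_rng(3)
        rej = [
            rank_sum_test(rng.normal(size=25), rng.normal(size=25))[1] < 0.05
            for _ in range(500)
        ]
        assert abs(np.mean(rej) - 0.05) < 0.03

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestAdjustedRegression:
    def test_collinear_covariate_named(self, rng):
        n = 30
        g = np.repeat(["HC", "MDD"], n // 2)
        cohort = pd.DataFrame({"group": g, "dup": (g == "MDD").astype(float)})
        with pytest.raises(ValueError, match="collinear"):
            fit_adjusted_regression(rng.standard_normal(n), cohort, "group", ["dup"])

    def test_group_family_recovers_planted_roi(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            n = 60
            g = np.repeat(["HC", "MDD"], n // 2)
            cohort = pd.DataFrame({"group": g, "age": rng.uniform(20, 60, n)})
            vals = pd.DataFrame(
                {f"roi{k}": rng.standard_normal(n) for k in range(7)}
            )
            vals["roi3"] += 1.0 * (g == "MDD")
            res = adjusted_group_difference(vals, cohort, ["age"])
            qmin = min(r.q_fdr for r in res)
            hits += [r.analysis_id for r in res if r.q_fdr == qmin][0].startswith("roi3")
        assert hits >= 18

    def test_listwise_deletion(self, rng):
        n = 20
        cohort = pd.DataFrame({"x": rng.standard_normal(n), "c": rng.standard_normal(n)})
        cohort.loc[3, "c"] = np.nan
        res = fit_adjusted_regression(rng.standard_normal(n), cohort, "x", ["c"])
        assert res.n == n - 1


class TestPartialCorrelation:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        res = adjusted_partial_correlation(y, x)
        assert res.coefficient == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 80
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = 0.5 * z + rng.standard_normal(n)
        res = adjusted_partial_correlation(y, x, pd.DataFrame({"z": z}))
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert res.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_uncorr == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_matches_matrix_identity_single_covariate(self, rng):
        """Residualization equals the first-order partial-correlation formula."""
        from mesoinfluence.depna import partial_correlation

        n = 500
        z = rng.standard_normal(n)
        x = 0.6 * z + rng.standard_normal(n)
        y = -0.4 * z + rng.standard_normal(n)
        C = np.corrcoef(np.vstack([x, y, z]))
        res = adjusted_partial_correlation(y, x, pd.DataFrame({"z": z}))
        assert res.coefficient == pytest.approx(partial_correlation(C, 0, 1, 2), abs=1e-10)

    def test_planted_link_detected(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(30):
            n = 60
            z = rng.standard_normal(n)
            score = rng.standard_normal(n)
            vals = 0.5 * score + 0.3 * z + np.sqrt(1 - 0.25) * rng.standard_normal(n)
            res = adjusted_partial_correlation(vals, score, pd.DataFrame({"z": z}))
            hits += (res.p_uncorr < 0.05) and (res.coefficient > 0)
        assert hits >= 27

    def test_shuffled_score_null(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            ps.append(
                adjusted_partial_correlation(
                    rng.standard_normal(40), rng.standard_normal(40)
                ).p_uncorr
            )
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestMixedModel:
    def _trial_table(self, rng, n_subj=20, group_effect=0.0, subj_sd=0.1):
        rows = []
        for s in range(n_subj):
            grp = "MDD" if s >= n_subj // 2 else "HC"
            intercept = 0.7 + rng.normal(0, subj_sd)
            for t in range(40):
                ttype = "gain" if t % 2 == 0 else "loss"
                p = intercept
                if grp == "MDD" and ttype == "gain":
                    p -= group_effect
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "group": grp,
                        "trial_type": ttype,
                        "trial": t,
                        "correct": float(rng.random() < np.clip(p, 0, 1)),
                    }
                )
        return pd.DataFrame(rows)

    def test_interaction_sign_for_gain_specific_deficit(self, rng):
        tt = self._trial_table(rng, n_subj=40, group_effect=0.25)
        res = learning_mixed_model(tt)
        assert res.loc["interaction", "coef"] < 0
        assert res.loc["interaction", "p"] < 0.05

    def test_null_interaction(self, rng):
        tt = self._trial_table(rng, n_subj=30, group_effect=0.0)
        res = learning_mixed_model(tt)
        assert res.loc["interaction", "p"] > 0.01

    def test_zero_subject_variance_matches_ols(self, rng):
        import statsmodels.api as sm

        tt = self._trial_table(rng, n_subj=16, subj_sd=0.0)
        res = learning_mixed_model(tt)
        X = pd.DataFrame(
            {
                "g": (tt["group"] == "MDD").astype(float),
                "t": (tt["trial_type"] == "gain").astype(float),
                "trial": tt["trial"],
            }
        )
        X["gt"] = X["g"] * X["t"]
        ols = sm.OLS(tt["correct"].astype(float), sm.add_constant(X)).fit()
        assert res.loc["interaction", "coef"] == pytest.approx(ols.params["gt"], abs=5e-3)

    def test_requires_two_participants(self):
        tt = pd.DataFrame(
            {
                "subject_id": ["a"] * 4,
                "group": ["HC"] * 4,
                "trial_type": ["gain", "loss"] * 2,
                "trial": range(4),
                "correct": [1, 0, 1, 0],
            }
        )
        with pytest.raises(ValueError):
            learning_mixed_model(tt)


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(20)
        rho, _ = cross_state_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = np.arange(10.0)
        rho, _ = cross_state_spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        # ranks x: 1..5; ranks y: (2,1,4,3,5); sum d^2 = 4 -> rho = 1 - 24/120
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([5.0, 1.0, 8.0, 7.0, 20.0])
        rho, _ = cross_state_spearman(x, y)
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            cross_state_spearman(np.ones(5), np.arange(5.0))
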