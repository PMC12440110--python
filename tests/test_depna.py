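"""Dependency-network analysis against brute-force and residualization oracles."""

import numpy as np
import pytest

from mesoinfluence import depna, synthetic
from mesoinfluence.depna import (
    DegenerateInputError,
    correlation_influence,
    correlation_matrix,
    dependency_matrix,
    edge_graph,
    exclude_outliers,
    fisher_z,
    influence_degrees,
    influence_regression,
    partial_correlation,
)


def random_correlation(n, rng):
    """Random SPD correlation matrix via normalized Wishart draw."""
    X = rng.standard_normal((n, 4 * n))
    S = X @ X.T
    d = 1.0 / np.sqrt(np.diag(S))
    return d[:, None] * S * d[None, :]


def dependency_matrix_bruteforce(c):
    """Naive triple loop over (j, i, R) pairs -- the independent oracle."""
    n = c.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0.0
            for R in range(n):
                if R in (i, j):
                    continue
                pc = (c[j, R] - c[j, i] * c[R, i]) / np.sqrt(
                    (1 - c[j, i] ** 2) * (1 - c[R, i] ** 2)
                )
                d = np.arctanh(np.clip(c[j, R], -0.99, 0.99)) - np.arctanh(
                    np.clip(pc, -0.99, 0.99)
                )
                total += max(0.0, d)
            D[j, i] = total / (n - 1)
    return D


class TestCorrelationMatrix:
    def test_matches_two_pass_pearson(self, rng):
        panel = rng.standard_normal((5, 200))
        C = correlation_matrix(panel)
        oracle = np.empty((5, 5))
        for a in range(5):
            for b in range(5):
                xa = panel[a] - panel[a].mean()
                xb = panel[b] - panel[b].mean()
                oracle[a, b] = (xa @ xb) / np.sqrt((xa @ xa) * (xb @ xb))
        assert np.allclose(C.values, oracle, atol=1e-12)

    def test_constant_series_names_node(self):
        panel = np.vstack([np.ones(50), np.arange(50.0), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(DegenerateInputError, match="nodeA"):
            correlation_matrix(panel, ["nodeA", "nodeB", "nodeC"])

    def test_identical_nodes_clipped_for_fisher(self, rng):
        x = rng.standard_normal(100)
        panel = np.vstack([x, x, rng.standard_normal(100)])
        C = correlation_matrix(panel)
        assert C.values[0, 1] == pytest.approx(1.0)
        assert np.isfinite(C.z).all()
        assert C.z[0, 1] == pytest.approx(np.arctanh(0.99))

    def test_independent_noise_near_zero(self, rng):
        panel = rng.standard_normal((4, 5000))
        C = correlation_matrix(panel)
        off = C.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_diagonal_reported_as_one(self, rng):
        C = correlation_matrix(rng.standard_normal((4, 100)))
        assert np.all(np.diag(C.values) == 1.0)
        assert np.allclose(np.diag(C.z), np.arctanh(0.99))


class TestPartialCorrelation:
    def test_uncorrelated_third_node_reduction(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        assert partial_correlation(c, 0, 1, 2) == pytest.approx(0.5)

    def test_hand_value(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        c[0, 2] = c[2, 0] = 0.6
        c[1, 2] = c[2, 1] = 0.6
        assert partial_correlation(c, 0, 1, 2) == pytest.approx(0.6875)

    def test_symmetry_in_jk(self, rng):
        c = random_correlation(5, rng)
        assert partial_correlation(c, 1, 3, 0) == pytest.approx(
            partial_correlation(c, 3, 1, 0)
        )

    def test_matches_residualization_on_population_matrix(self, rng):
        """Formula equals correlating residuals after regressing out node i.

        On a population covariance this is an exact identity; we check it by
        drawing a huge Gaussian sample so the sample version converges.
        """
        c = random_correlation(4, rng)
        L = np.linalg.cholesky(c)
        X = (L @ rng.standard_normal((4, 400_000)))
        for (j, k, i) in [(0, 1, 2), (1, 3, 0)]:
            zi = np.vstack([np.ones(X.shape[1]), X[i]]).T
            rj = X[j] - zi @ np.linalg.lstsq(zi, X[j], rcond=None)[0]
            rk = X[k] - zi @ np.linalg.lstsq(zi, X[k], rcond=None)[0]
            emp = np.corrcoef(rj, rk)[0, 1]
            Cs = np.corrcoef(X)
            assert partial_correlation(Cs, j, k, i) == pytest.approx(emp, abs=1e-10)

    def test_degenerate_denominator(self):
        c = np.eye(3)
        c[0, 2] = c[2, 0] = 1.0
        with pytest.raises(DegenerateInputError):
            partial_correlation(c, 0, 1, 2)


class TestCorrelationInfluence:
    def test_zero_when_third_uncorrelated(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        assert correlation_influence(c, 0, 1, 2) == 0.0

    def test_hand_value_with_fisher(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        c[0, 2] = c[2, 0] = 0.6
        c[1, 2] = c[2, 1] = 0.6
        expected = np.arctanh(0.8) - np.arctanh(0.6875)
        assert correlation_influence(c, 0, 1, 2) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.25541, abs=1e-3)

    def test_suppression_clamped_to_zero(self):
        # partial exceeds full correlation -> negative influence -> clamp
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.1
        c[0, 2] = c[2, 0] = 0.7
        c[1, 2] = c[2, 1] = -0.7
        pc = partial_correlation(c, 0, 1, 2)
        assert pc > c[0, 1]
        assert correlation_influence(c, 0, 1, 2) == 0.0

    def test_raw_difference_variant(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        c[0, 2] = c[2, 0] = 0.6
        c[1, 2] = c[2, 1] = 0.6
        assert correlation_influence(c, 0, 1, 2, use_fisher=False) == pytest.approx(
            0.8 - 0.6875
        )


class TestDependencyMatrix:
    def test_three_node_minimal_case(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.8
        c[0, 2] = c[2, 0] = 0.6
        c[1, 2] = c[2, 1] = 0.6
        D = dependency_matrix(c).values
        # single valid partner divided by n-1 = 2
        assert D[0, 2] == pytest.approx(correlation_influence(c, 0, 1, 2) / 2)

    def test_matches_bruteforce_on_random_spd(self, rng):
        for _ in range(5):
            c = random_correlation(8, rng)
            D = dependency_matrix(c).values
            assert np.allclose(D, dependency_matrix_bruteforce(c), atol=1e-12)

    def test_block_independent_node_has_no_influence(self, rng):
        x = np.random.default_rng(0).standard_normal((3, 20000))
        C = correlation_matrix(np.vstack([x[:2] + 0.0, x[2:]]))
        D = dependency_matrix(C).values
        assert D[0, 2] < 0.01 and D[1, 2] < 0.01

    def test_normalization_switch_scales(self, rng):
        c = random_correlation(6, rng)
        D1 = dependency_matrix(c, normalization="n-1").values
        D2 = dependency_matrix(c, normalization="n-2").values
        assert np.allclose(D1 * 5, D2 * 4)

    def test_permutation_equivariance(self, rng):
        c = random_correlation(6, rng)
        perm = np.random.default_rng(3).permutation(6)
        Dp = dependency_matrix(c[np.ix_(perm, perm)]).values
        D = dependency_matrix(c).values
        assert np.allclose(Dp, D[np.ix_(perm, perm)], atol=1e-12)
        deg, degp = influence_degrees(D), influence_degrees(Dp)
        assert np.allclose(degp.influencing, deg.influencing[perm])
        assert np.allclose(degp.influenced, deg.influenced[perm])


class TestInfluenceDegrees:
    def test_all_zero(self):
        deg = influence_degrees(np.zeros((5, 5)))
        assert np.all(deg.influencing == 0) and np.all(deg.influenced == 0)

    def test_degree_conservation(self, rng):
        for _ in range(5):
            D = dependency_matrix(random_correlation(7, rng)).values
            deg = influence_degrees(D)
            assert deg.influencing.sum() == pytest.approx(deg.influenced.sum(), abs=1e-12)
            off = D - np.diag(np.diag(D))
            assert deg.influencing.sum() == pytest.approx(off.sum(), abs=1e-12)

    def test_var_hub_ranks_first(self):
        cfg = synthetic.NetSimConfig(hub_out_coupling=0.4, n_timepoints=1000, seed=10)
        panel = synthetic.simulate_timeseries_panel(cfg, ["HC"] * 20)
        wins = 0
        for i in range(20):
            D = dependency_matrix(correlation_matrix(panel.subject(i)))
            wins += int(np.argmax(influence_degrees(D).influencing) == cfg.hub_index)
        assert wins >= 18


class TestOutlierExclusion:
    def test_small_sample_keeps_apparent_outlier(self):
        mask = exclude_outliers(np.array([0.0, 0.0, 0.0, 100.0]))
        assert mask.all()  # |z| ~ 1.5 at n=4: nothing can exceed 3 SD

    def test_all_equal_included(self):
        assert exclude_outliers(np.full(10, 3.3)).all()

    def test_constructed_exclusion_counts(self, rng):
        base = rng.normal(0, 1, 60)
        one_out = np.concatenate([base, [base.mean() + 8 * base.std()]])
        assert (~exclude_outliers(one_out)).sum() == 1
        two_out = np.concatenate([base, [base.mean() + 9 * base.std(), base.mean() - 9 * base.std()]])
        assert (~exclude_outliers(two_out)).sum() == 2

    def test_non_iterative(self):
        # computed once on the full sample: the masked recomputation would
        # flag more points, which must not happen
        vals = np.concatenate([np.zeros(20), [10.0, 1.0]])
        mask = exclude_outliers(vals)
        assert mask.sum() == 21 and not mask[20]


class TestInfluenceAssociations:
    def test_group_effect_recovered(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        cfg = synthetic.NetSimConfig(
            hub_out_coupling=0.25, group_coupling_delta=0.2, n_timepoints=500, seed=5
        )
        groups = ["HC"] * 20 + ["MDD"] * 20
        panel = synthetic.simulate_timeseries_panel(cfg, groups)
        deg = [
            influence_degrees(dependency_matrix(correlation_matrix(panel.subject(i)))).influencing[0]
            for i in range(40)
        ]
        cohort = pd.DataFrame({"group": groups, "age": rng.uniform(20, 60, 40)})
        res = influence_regression(np.array(deg), cohort, "group", ["age"])
        assert res.coefficient > 0 and res.p_uncorr < 0.05

    def test_null_predictor_calibrated(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            y = rng.standard_normal(40)
            cohort = pd.DataFrame({"x": rng.standard_normal(40)})
            ps.append(influence_regression(y, cohort, "x").p_uncorr)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_covariate_free_matches_simple_slope(self, rng):
        import pandas as pd

        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        res = influence_regression(y, pd.DataFrame({"x": x}), "x")
        slope = np.polyfit(x, y, 1)[0]
        assert res.coefficient == pytest.approx(slope, abs=1e-10)


class TestEdgeGraph:
    def _stack_and_cohort(self, rng, n=40, effect=0.0):
        import pandas as pd

        groups = np.array(["HC"] * (n // 2) + ["MDD"] * (n // 2))
        D = rng.uniform(0, 0.2, size=(n, 4, 4))
        D[groups == "MDD", 1, 0] += effect  # hub(0) -> node1 edge
        cohort = pd.DataFrame({"group": groups, "age": rng.uniform(20, 60, n)})
        return D, cohort

    def test_empty_cohort_rejected(self, rng):
        import pandas as pd

        D, _ = self._stack_and_cohort(rng)
        with pytest.raises(ValueError):
            edge_graph(D[:0], pd.DataFrame(), "group")

    def test_planted_edge_recovered(self, rng):
        D, cohort = self._stack_and_cohort(rng, effect=0.3)
        g = edge_graph(D, cohort, "group", ["age"], node_names=list("hxyz"), hub=0)
        assert g.has_edge("h", "x")
        assert g["h"]["x"]["q_fdr"] == g.graph["tests"]["q_fdr"].min()

    def test_type_one_rate_without_effects(self):
        rng = np.random.default_rng(7)
        n_edges = []
        for _ in range(40):
            D, cohort = self._stack_and_cohort(rng)
            g = edge_graph(D, cohort, "group", node_names=list("hxyz"), hub=0)
            n_edges.append(g.number_of_edges())
        # 6 tested pairs at alpha=.05 -> expected 0.3 edges per rep
        assert np.mean(n_edges) < 1.0

    def test_direction_convention(self, rng):
        D, cohort = self._stack_and_cohort(rng, effect=0.3)
        g = edge_graph(D, cohort, "group", node_names=list("hxyz"), hub=0)
        # D[1, 0] carries hub->node1, so the edge must read h -> x
        assert g.has_edge("h", "x") and not g.has_edge("x", "h")


def test_fisher_z_matches_atanh_in_open_interval():
    r = np.array([-0.95, -0.5, 0.0, 0.5, 0.95])
    assert np.allclose(fisher_z(r), np.arctanh(r))
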