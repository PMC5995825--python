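import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micronet.correlation import (
    build_network,
    degree_distribution_fit,
    estimate_pi0,
    qvalues,
    spearman_screen,
)
from micronet.preprocessing import AbundanceTable, to_relative

from conftest import make_network


def relative_table(X, otu_ids=None):
    otu_ids = otu_ids or [f"O{i}" for i in range(X.shape[0])]
    values = pd.DataFrame(X, index=otu_ids,
                          columns=[f"s{j}" for j in range(X.shape[1])])
    return to_relative(AbundanceTable(values=values, mode="counts"))


def brute_force_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearmanScreen:
    def test_monotone_and_hand_evaluated_rho(self):
        # row O1 = 2 * row O0, so their proportions are proportional within
        # every sample: identical ranks -> rho = 1 exactly
        X = np.array([
            [1, 2, 3, 4, 5],
            [2, 4, 6, 8, 10],
            [9, 1, 4, 2, 7],
        ], dtype=float)
        table = relative_table(X)
        screen = spearman_screen(table)
        assert screen.R.loc["O0", "O1"] == pytest.approx(1.0)
        P = table.values.to_numpy()
        assert screen.R.loc["O0", "O2"] == pytest.approx(
            brute_force_spearman(P[0], P[2]), abs=1e-12
        )

    def test_rank_difference_formula_minus_half(self):
        # x=(1,2,3), y=(3,1,2): rho = 1 - 6*6/(3*8) = -0.5 (no ties)
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.0, 1.0, 2.0])
        d2 = ((stats.rankdata(x) - stats.rankdata(y)) ** 2).sum()
        assert 1 - 6 * d2 / (3 * 8) == pytest.approx(-0.5)
        assert brute_force_spearman(x, y) == pytest.approx(-0.5)
        # the screen itself requires >= 4 samples; check on proportions
        X = np.array([[1, 2, 3, 4], [3, 1, 2, 4], [5, 1, 2, 3]], dtype=float)
        table = relative_table(X)
        screen = spearman_screen(table)
        P = table.values.to_numpy()
        assert screen.R.loc["O0", "O1"] == pytest.approx(
            brute_force_spearman(P[0], P[1]), abs=1e-12
        )

    def test_brute_force_oracle_all_pairs(self):
        """Screen matches an explicit-ranks recomputation to 1e-12 (8x10)."""
        rng = np.random.default_rng(7)
        X = rng.integers(1, 50, size=(8, 10)).astype(float)
        table = relative_table(X)
        screen = spearman_screen(table)
        P = table.values.to_numpy()
        for i, j in itertools.combinations(range(8), 2):
            expected = brute_force_spearman(P[i], P[j])
            assert screen.R.iloc[i, j] == pytest.approx(expected, abs=1e-12)
            assert screen.R.iloc[j, i] == pytest.approx(expected, abs=1e-12)
        # p-values: two-sided t approximation with n-2 df
        n = 10
        r = screen.R.iloc[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_expected = 2 * stats.t.sf(abs(t), n - 2)
        assert screen.P.iloc[0, 1] == pytest.approx(p_expected, rel=1e-9)

    def test_constant_profile_is_na_and_never_an_edge(self):
        # row 1 constant in *proportions*: equal values, constant column sums
        X = np.array([
            [1, 2, 3, 4, 5],
            [1, 1, 1, 1, 1],
            [8, 7, 6, 5, 4],
        ], dtype=float)  # column sums 10 -> row 1 proportions constant 0.1
        screen = spearman_screen(relative_table(X))
        assert np.isnan(screen.R.loc["O1", "O0"])
        assert screen.P.loc["O1", "O0"] == 1.0
        net = build_network(screen, r_min=0.0, p_max=1.0, q_max=1.0)
        assert "O1" not in net.graph

    def test_permutation_pvalues_exact_small_n(self):
        X = np.array([
            [1, 5, 2, 9, 7],
            [2, 6, 1, 8, 9],
            [9, 1, 8, 2, 3],
        ], dtype=float)
        screen = spearman_screen(relative_table(X), p_method="permutation")
        # exact enumeration at n=5: p is a multiple of 1/120
        p = screen.P.loc["O0", "O1"]
        assert (p * 120) == pytest.approx(round(p * 120), abs=1e-9)

    def test_edge_set_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 40, size=(6, 8)).astype(float)
        t1 = relative_table(X)
        perm = rng.permutation(8)
        t2 = relative_table(X[:, perm])
        s1 = spearman_screen(t1)
        s2 = spearman_screen(t2)
        n1 = build_network(s1, r_min=0.5, p_max=0.2, q_max=1.0)
        n2 = build_network(s2, r_min=0.5, p_max=0.2, q_max=1.0)
        assert set(map(frozenset, n1.graph.edges())) == set(
            map(frozenset, n2.graph.edges())
        )

    def test_requires_enough_samples(self):
        X = np.ones((3, 3))
        with pytest.raises(ValueError, match="4 samples"):
            spearman_screen(relative_table(X))


class TestQvalues:
    def test_ties_get_equal_q_and_monotone(self):
        p = np.array([0.2, 0.05, 0.2, 0.8, 0.05])
        q = qvalues(p)
        assert q[0] == q[2] and q[1] == q[4]
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_near_one_for_uniform(self):
        """pi0 estimate within [0.9, 1.1] when all hypotheses are null."""
        rng = np.random.default_rng(11)
        p = rng.uniform(size=10_000)
        assert 0.9 <= estimate_pi0(p) <= 1.1

    def test_q_below_independent_bh(self):
        """pi0 <= 1 implies Storey q <= BH-adjusted p (statsmodels oracle)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(size=500), rng.beta(0.2, 5, size=100)])
        q = qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (q <= bh + 1e-12).all()

    def test_empty_and_invalid(self):
        assert qvalues(np.array([])).size == 0
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))


class TestBuildNetwork:
    @staticmethod
    def _screen(rho, p, q):
        ids = pd.Index(["a", "b"])
        mk = lambda v, diag: pd.DataFrame(
            [[diag, v], [v, diag]], index=ids, columns=ids
        )
        from micronet.correlation import CorrelationScreen

        return CorrelationScreen(
            R=mk(rho, 1.0), P=mk(p, 0.0), Q=mk(q, 0.0), n_samples=10,
            kingdom=pd.Series(["bact", "bact"], index=ids),
        )

    @pytest.mark.parametrize(
        "rho,p,q,kept,sign",
        [
            (0.95, 0.001, 0.01, True, "positive"),
            (-0.92, 0.005, 0.04, True, "negative"),
            (0.95, 0.02, 0.04, False, None),   # p threshold strict
            (0.85, 0.001, 0.01, False, None),  # strength threshold
            (0.95, 0.001, 0.06, False, None),  # q threshold
        ],
    )
    def test_threshold_conjunction(self, rho, p, q, kept, sign):
        net = build_network(self._screen(rho, p, q))
        if kept:
            assert net.n_edges == 1
            assert net.graph.edges[("a", "b")]["sign"] == sign
        else:
            assert net.n_edges == 0
            assert net.n_nodes == 0  # no isolated nodes

    def test_raising_r_min_never_adds_edges(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 30, size=(10, 8)).astype(float)
        screen = spearman_screen(relative_table(X))
        loose = build_network(screen, r_min=0.3, p_max=1.0, q_max=1.0)
        tight = build_network(screen, r_min=0.6, p_max=1.0, q_max=1.0)
        assert set(map(frozenset, tight.graph.edges())) <= set(
            map(frozenset, loose.graph.edges())
        )


class TestDegreeFit:
    @staticmethod
    def _graph_from_degrees(deg, seed=0):
        import networkx as nx

        deg = np.asarray(deg).copy()
        if deg.sum() % 2:
            deg[0] += 1
        g = nx.configuration_model(deg, seed=seed)
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    def test_truncated_nests_power_and_exponential(self):
        rng = np.random.default_rng(4)
        deg = rng.geometric(0.2, size=500)
        fit = degree_distribution_fit(self._graph_from_degrees(deg))
        assert fit.r2("truncated") >= fit.r2("power") - 1e-9
        assert fit.r2("truncated") >= fit.r2("exponential") - 1e-9
        assert all(f["r2"] <= 1 + 1e-12 for f in fit.fits.values())

    def test_exponential_degrees_not_best_fit_by_pure_power(self):
        rng = np.random.default_rng(9)
        deg = rng.geometric(0.15, size=2000)
        fit = degree_distribution_fit(self._graph_from_degrees(deg))
        assert fit.best_model in ("exponential", "truncated")

    def test_truncated_power_law_recovered(self):
        """Degrees from k^-1.5 e^{-k/20} select the truncated model."""
        ks = np.arange(1, 200)
        pk = ks**-1.5 * np.exp(-ks / 20)
        pk /= pk.sum()
        rng = np.random.default_rng(12)
        deg = rng.choice(ks, size=2000, p=pk)
        fit = degree_distribution_fit(self._graph_from_degrees(deg, seed=12))
        assert fit.best_model == "truncated"
        assert fit.fits["truncated"]["alpha"] == pytest.approx(1.5, abs=0.6)

    def test_degenerate_degree_sequence_skipped(self):
        import networkx as nx

        g = nx.cycle_graph(12)  # all degrees 2 -> single point
        with pytest.warns(UserWarning, match="skipped"):
            fit = degree_distribution_fit(g)
        assert fit.skipped

    def test_small_networks_rejected(self):
        import networkx as nx

        with pytest.raises(ValueError, match="10 nodes"):
            degree_distribution_fit(nx.path_graph(5))
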