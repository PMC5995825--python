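"""Spearman correlation screen, Storey q-values, network construction, degree fits.

Edges of the co-occurrence network are OTU pairs whose rank correlation is
both strong (|rho| >= 0.9 by default) and significant after multiple-testing
control (p < 0.01 and Storey q < 0.05). Degree distributions are fitted on
log-log axes by least squares under power-law, exponential and truncated
power-law models; the truncated model nests the other two, so its R^2 is
never smaller.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import RELATIVE, AbundanceTable

__all__ = [
    "CorrelationScreen",
    "CoNetwork",
    "DegreeFitResult",
    "spearman_screen",
    "qvalues",
    "build_network",
    "degree_distribution_fit",
]


@dataclass
class CorrelationScreen:
    """All-pairs Spearman R / P / Q matrices over the OTUs of one table."""

    R: pd.DataFrame
    P: pd.DataFrame
    Q: pd.DataFrame
    n_samples: int
    mean_abundance: pd.Series | None = None
    kingdom: pd.Series | None = None

    @property
    def otu_ids(self) -> pd.Index:
        return self.R.index


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence graph.

    Nodes carry ``kingdom``, ``phylum`` and ``mean_abundance`` attributes;
    edges carry ``rho``, ``p``, ``q``, ``sign`` and ``kingdom_pair``.
    Isolated nodes are never present: a node exists iff it has at least one
    retained edge.
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, d in sorted(self.graph.edges(data=True)):
            a, b = (a, b) if a < b else (b, a)
            rows.append(
                {"otu_a": a, "otu_b": b, "rho": d["rho"], "p": d["p"], "q": d["q"],
                 "sign": d["sign"], "kingdom_pair": d["kingdom_pair"]}
            )
        return pd.DataFrame(
            rows, columns=["otu_a", "otu_b", "rho", "p", "q", "sign", "kingdom_pair"]
        )


def _exact_perm_pvalues(X: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Permutation p-values for every pair; exact for n<=7, Monte Carlo above."""
    n_otu, n = X.shape
    ranks = stats.rankdata(X, axis=1)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1))
    P = np.ones((n_otu, n_otu))
    if n <= 7:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(0)
        perms = np.array([rng.permutation(n) for _ in range(9999)])
    for i in range(n_otu):
        for j in range(i + 1, n_otu):
            if norm[i] == 0 or norm[j] == 0 or np.isnan(rho[i, j]):
                continue
            null = z[i][perms] @ z[j] / (norm[i] * norm[j])
            p = (np.abs(null) >= abs(rho[i, j]) - 1e-12).mean()
            P[i, j] = P[j, i] = p
    return P


def spearman_screen(
    table: AbundanceTable, p_method: str = "t"
) -> CorrelationScreen:
    """All-pairs Spearman rank correlations with two-sided p-values.

    Rho uses average ranks (tie-corrected); p-values use the t-distribution
    approximation with n-2 degrees of freedom (``p_method="t"``, the standard
    for rank correlation at moderate n), or permutation (``"permutation"``,
    exact for n <= 7 samples). Constant OTU profiles have undefined rho:
    recorded as NaN with p = 1 so the pair can never become an edge.
    """
    if table.mode != RELATIVE:
        raise ValueError("spearman_screen expects a relative-mode table")
    if table.n_samples < 4:
        raise ValueError(f"need >= 4 samples, got {table.n_samples}")
    X = table.values.to_numpy(dtype=float)
    ids = table.otu_ids
    n = X.shape[1]
    ranks = stats.rankdata(X, axis=1)  # average ranks: tie-corrected rho
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows: zero variance -> NaN
        rho = np.corrcoef(ranks)
    rho = np.clip(np.atleast_2d(rho), -1.0, 1.0)
    constant = np.isnan(rho) & ~np.eye(len(ids), dtype=bool)
    # two-sided p via the t approximation with n-2 degrees of freedom
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p = np.where(constant, 1.0, p)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    if p_method == "permutation":
        p = _exact_perm_pvalues(X, rho)
        np.fill_diagonal(p, 0.0)
        p = np.where(constant, 1.0, p)
    elif p_method != "t":
        raise ValueError(f"unknown p_method {p_method!r}")

    iu = np.triu_indices(len(ids), k=1)
    flat_p = p[iu]
    tested = ~constant[iu]  # constant pairs carry no test
    q_flat = np.ones_like(flat_p)
    if tested.any():
        q_flat[tested] = qvalues(flat_p[tested])
    Qm = np.ones_like(p)
    Qm[iu] = q_flat
    Qm.T[iu] = q_flat
    np.fill_diagonal(Qm, 0.0)

    mean_ab = table.mean_abundance() if table.mode == RELATIVE else None
    return CorrelationScreen(
        R=pd.DataFrame(rho, index=ids, columns=ids),
        P=pd.DataFrame(p, index=ids, columns=ids),
        Q=pd.DataFrame(Qm, index=ids, columns=ids),
        n_samples=table.n_samples,
        mean_abundance=mean_ab,
        kingdom=table.kingdom,
    )


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    lambda = 0.05, 0.10, ..., 0.95, a cubic polynomial is fitted through the
    points, and the fit is read off at the largest lambda. Falls back to 1
    (the conservative BH limit) when the estimate leaves (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    return pi0


def qvalues(p, method: str = "smoother", pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a collection of p-values.

    q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j); monotone non-decreasing
    in p and equal on ties. ``method="bh"`` returns plain Benjamini-Hochberg
    adjusted values (pi0 = 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return stats.false_discovery_control(p, method="bh")
    if method != "smoother":
        raise ValueError(f"unknown q-value method {method!r}")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def build_network(
    screen: CorrelationScreen,
    taxonomy: pd.DataFrame | None = None,
    r_min: float = 0.9,
    p_max: float = 0.01,
    q_max: float = 0.05,
) -> CoNetwork:
    """Threshold the screen into a signed co-occurrence graph.

    An edge is kept iff |rho| >= r_min AND p < p_max AND q < q_max. Nodes
    without any surviving edge are dropped. Edge kingdom_pair is ``intra``
    when both endpoints share a kingdom, else ``inter``.
    """
    ids = screen.otu_ids
    R = screen.R.to_numpy()
    P = screen.P.to_numpy()
    Q = screen.Q.to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    keep = (
        (np.abs(R[iu]) >= r_min)
        & (P[iu] < p_max)
        & (Q[iu] < q_max)
        & ~np.isnan(R[iu])
    )
    g = nx.Graph()
    kingdoms = screen.kingdom
    phylum = None
    if taxonomy is not None and "phylum" in taxonomy.columns:
        phylum = taxonomy["phylum"]
    mean_ab = screen.mean_abundance
    for i, j in zip(iu[0][keep], iu[1][keep]):
        a, b = ids[i], ids[j]
        a, b = (a, b) if a < b else (b, a)  # canonical lexicographic orientation
        for node in (a, b):
            if node not in g:
                g.add_node(
                    node,
                    kingdom=str(kingdoms[node]) if kingdoms is not None else "unknown",
                    phylum=str(phylum[node]) if phylum is not None and node in phylum.index else "unclassified",
                    mean_abundance=float(mean_ab[node]) if mean_ab is not None else float("nan"),
                )
        rho = float(R[i, j])
        kp = "intra"
        if kingdoms is not None and kingdoms[a] != kingdoms[b]:
            kp = "inter"
        g.add_edge(
            a, b,
            rho=rho, p=float(P[i, j]), q=float(Q[i, j]),
            sign="positive" if rho > 0 else "negative",
            kingdom_pair=kp,
        )
    return CoNetwork(graph=g)


@dataclass
class DegreeFitResult:
    """Least-squares fits of the degree distribution on log-log axes."""

    fits: dict = field(default_factory=dict)  # model -> {alpha, kappa, intercept, r2}
    best_model: str | None = None
    skipped: bool = False

    def r2(self, model: str) -> float:
        return self.fits[model]["r2"]


def _ols_r2(Xcols: list[np.ndarray], y: np.ndarray) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(y)] + Xcols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return beta, r2


def degree_distribution_fit(network: CoNetwork | nx.Graph) -> DegreeFitResult:
    """Fit P(k) under power-law, exponential and truncated power-law models.

    The empirical P(k) is the fraction of nodes with degree k (k >= 1).
    Models, all linear in their parameters on the (log k, k, log P) scale:

    - power:       log P = a - alpha log k
    - exponential: log P = a - k / kappa
    - truncated:   log P = a - alpha log k - k / kappa

    Model selection is by maximum R^2 on log P. Needs >= 3 distinct degrees;
    otherwise the fit is skipped with a warning.
    """
    g = network.graph if isinstance(network, CoNetwork) else network
    degrees = np.array([d for _, d in g.degree() if d >= 1])
    if g.number_of_nodes() < 10:
        raise ValueError("degree fit requires a network with >= 10 nodes")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        warnings.warn("fewer than 3 distinct degrees; degree fit skipped")
        return DegreeFitResult(skipped=True)
    pk = counts / counts.sum()
    logk = np.log(ks.astype(float))
    logp = np.log(pk)
    k = ks.astype(float)

    fits = {}
    beta, r2 = _ols_r2([logk], logp)
    fits["power"] = {"intercept": beta[0], "alpha": -beta[1], "kappa": None, "r2": r2}
    beta, r2 = _ols_r2([k], logp)
    kappa = -1.0 / beta[1] if beta[1] != 0 else np.inf
    fits["exponential"] = {"intercept": beta[0], "alpha": None, "kappa": kappa, "r2": r2}
    beta, r2 = _ols_r2([logk, k], logp)
    kappa = -1.0 / beta[2] if beta[2] != 0 else np.inf
    fits["truncated"] = {"intercept": beta[0], "alpha": -beta[1], "kappa": kappa, "r2": r2}
    best = max(fits, key=lambda mdl: fits[mdl]["r2"])
    return DegreeFitResult(fits=fits, best_model=best)
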