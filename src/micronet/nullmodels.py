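"""Random-network null ensembles, Z-tests, and bootstrap zone comparison.

The default null model is G(n, m): uniform simple graphs with exactly the
empirical node and edge counts. A degree-preserving double-edge-swap null is
available as an alternative. Observed indices are compared to the ensemble
by a Z-test; two zones are compared by rebuilding each zone's network on
bootstrap resamples of its samples and testing the observed index difference
against the combined bootstrap spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CoNetwork, build_network, spearman_screen
from .preprocessing import AbundanceTable, prevalence_filter, to_relative
from .topology import average_clustering, detect_modules, network_indices, path_length_stats

__all__ = [
    "NullEnsembleSummary",
    "ZTestResult",
    "random_ensemble",
    "z_test",
    "compare_zones",
]

DEFAULT_INDICES = ("MD", "CC", "APL", "ND")


@dataclass
class NullEnsembleSummary:
    model: str
    n_replicates: int
    n_nodes: int
    n_edges: int
    mean: dict
    sd: dict
    seed: int | None = None
    samples: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ZTestResult:
    index: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    degenerate: bool = False


def _replicate_indices(g: nx.Graph, which: tuple[str, ...]) -> dict:
    out = {}
    if "CC" in which:
        out["CC"] = average_clustering(g) if g.number_of_nodes() else float("nan")
    if "APL" in which or "ND" in which:
        apl, nd = path_length_stats(g)
        if "APL" in which:
            out["APL"] = apl
        if "ND" in which:
            out["ND"] = nd
    if "MD" in which:
        out["MD"] = detect_modules(g).modularity
    return out


def random_ensemble(
    network: CoNetwork | nx.Graph | tuple[int, int],
    n: int = 1000,
    model: str = "gnm",
    seed: int | None = None,
    indices: tuple[str, ...] = DEFAULT_INDICES,
) -> NullEnsembleSummary:
    """Mean/SD of topological indices over ``n`` random networks.

    ``model="gnm"`` draws uniform simple graphs with the empirical node and
    edge counts; ``model="degree_preserving_swap"`` rewires the empirical
    graph with 10E double-edge swaps per replicate. Fast-greedy modules are
    re-detected in every replicate when MD is requested.
    ``network`` may be a ``(n_nodes, n_edges)`` pair for the gnm model.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    if isinstance(network, tuple):
        if model != "gnm":
            raise ValueError("node/edge counts alone only support the gnm model")
        n_nodes, n_edges = network
        base = None
    else:
        g0 = network.graph if isinstance(network, CoNetwork) else network
        n_nodes, n_edges = g0.number_of_nodes(), g0.number_of_edges()
        base = g0
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("edge count exceeds simple-graph maximum")

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child_seeds = ss.generate_state(n)
    rows = []
    for r in range(n):
        rep_seed = int(child_seeds[r] % (2**31 - 1))
        if model == "gnm":
            g = nx.gnm_random_graph(n_nodes, n_edges, seed=rep_seed)
        elif model == "degree_preserving_swap":
            if base is None:
                raise ValueError("degree-preserving model needs the empirical graph")
            g = base.copy()
            if n_edges > 1:
                nx.double_edge_swap(
                    g, nswap=10 * n_edges, max_tries=1000 * n_edges, seed=rep_seed
                )
        else:
            raise ValueError(f"unknown null model {model!r}")
        rows.append(_replicate_indices(g, tuple(indices)))
    samples = pd.DataFrame(rows)
    return NullEnsembleSummary(
        model=model,
        n_replicates=n,
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean={k: float(samples[k].mean()) for k in samples.columns},
        sd={k: float(samples[k].std(ddof=1)) for k in samples.columns},
        seed=seed,
        samples=samples,
    )


def z_test(observed: float, summary: NullEnsembleSummary, index: str) -> ZTestResult:
    """Z-test of an observed index against the random-network ensemble."""
    if index not in summary.mean:
        raise KeyError(f"index {index!r} not in ensemble summary {list(summary.mean)}")
    mu, sd = summary.mean[index], summary.sd[index]
    if sd == 0:
        degenerate = True
        if observed == mu:
            z, p = 0.0, 1.0
        else:
            z = float("inf") if observed > mu else float("-inf")
            p = 0.0
    else:
        degenerate = False
        z = (observed - mu) / sd
        p = 2.0 * stats.norm.sf(abs(z))
    return ZTestResult(index=index, observed=float(observed), null_mean=mu,
                       null_sd=sd, z=float(z), p=float(p), degenerate=degenerate)


def _pipeline_indices(table: AbundanceTable, config, indices) -> dict | None:
    """counts table -> filter -> proportions -> screen -> network -> indices."""
    filtered = prevalence_filter(table, min_prevalence=config.min_prevalence)
    if filtered.n_otus < 2:
        return None
    rel = to_relative(filtered)
    screen = spearman_screen(rel)
    net = build_network(
        screen, r_min=config.r_min, p_max=config.p_max, q_max=config.q_max
    )
    if net.n_nodes == 0:
        return None
    idx = network_indices(net)
    d = idx.as_dict()
    return {k: d[k] for k in indices}


def compare_zones(
    tables_by_zone: dict[str, AbundanceTable],
    config=None,
    n_boot: int = 50,
    seed: int | None = None,
    indices: tuple[str, ...] = ("AD", "CC", "MD", "APL", "ND"),
    method: str = "z",
) -> pd.DataFrame:
    """Bootstrap two-sample comparison of network indices between two zones.

    For each zone the samples (columns) are resampled with replacement
    ``n_boot`` times; the full network pipeline is rebuilt on every resample
    to obtain a bootstrap distribution of each index. Default ``method="z"``
    tests the observed difference against the combined bootstrap spread:
    z = (I_1 - I_2) / sqrt(sd_boot1^2 + sd_boot2^2), two-sided normal p.
    ``method="welch"`` instead runs a Welch t-test between the two bootstrap
    index distributions (anti-conservative at large n_boot; kept for
    comparability).

    Returns a DataFrame indexed by index name with observed values per zone,
    the statistic, the p-value and bootstrap drop counts.
    """
    from .config import PipelineConfig

    if config is None:
        config = PipelineConfig()
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for a two-sample comparison")
    if len(tables_by_zone) != 2:
        raise ValueError("compare_zones needs exactly two zones")
    zones = list(tables_by_zone)
    for z, t in tables_by_zone.items():
        if t.n_samples < 4:
            raise ValueError(f"zone {z!r} has fewer than 4 samples")

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    zone_rngs = {z: np.random.default_rng(s) for z, s in zip(zones, ss.spawn(2))}

    observed: dict[str, dict] = {}
    boots: dict[str, pd.DataFrame] = {}
    dropped: dict[str, int] = {}
    for z in zones:
        table = tables_by_zone[z]
        obs = _pipeline_indices(table, config, indices)
        if obs is None:
            raise ValueError(f"zone {z!r} yields an empty network on the observed data")
        observed[z] = obs
        rng = zone_rngs[z]
        rows = []
        n_drop = 0
        cols = np.asarray(table.sample_ids)
        for _ in range(n_boot):
            pick = rng.integers(0, len(cols), size=len(cols))
            resampled = table.values.iloc[:, pick].copy()
            resampled.columns = [f"b{k}" for k in range(len(cols))]
            bt = AbundanceTable(values=resampled, mode="counts",
                                kingdom=table.kingdom.copy())
            res = _pipeline_indices(bt, config, indices)
            if res is None:
                n_drop += 1
            else:
                rows.append(res)
        if n_drop > n_boot / 2:
            raise ValueError(
                f"zone {z!r}: {n_drop}/{n_boot} bootstrap replicates degenerate"
            )
        dropped[z] = n_drop
        boots[z] = pd.DataFrame(rows)

    z1, z2 = zones
    out = []
    for name in indices:
        b1 = boots[z1][name].dropna().to_numpy()
        b2 = boots[z2][name].dropna().to_numpy()
        o1, o2 = observed[z1][name], observed[z2][name]
        if method == "z":
            spread = np.sqrt(np.var(b1, ddof=1) + np.var(b2, ddof=1))
            if spread == 0:
                stat = 0.0 if o1 == o2 else np.inf * np.sign(o1 - o2)
                p = 1.0 if o1 == o2 else 0.0
            else:
                stat = (o1 - o2) / spread
                p = 2.0 * stats.norm.sf(abs(stat))
        elif method == "welch":
            stat, p = stats.ttest_ind(b1, b2, equal_var=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append({
            "index": name, f"observed_{z1}": o1, f"observed_{z2}": o2,
            "statistic": float(stat), "p": float(p),
            f"dropped_{z1}": dropped[z1], f"dropped_{z2}": dropped[z2],
        })
    return pd.DataFrame(out).set_index("index")
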