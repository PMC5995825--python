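"""Topological node roles: within-module connectivity Zi and participation Pi.

Zi standardizes a node's number of links inside its own module against the
within-module degree distribution of that module (population SD; Zi = 0 by
convention when the SD is 0). Pi = 1 - sum_s (k_is / k_i)^2 measures how a
node's links spread over modules: 0 when all links stay in one module,
approaching 1 - 1/M when spread evenly over M modules. The four-role scheme
uses the thresholds Zi = 2.5 and Pi = 0.62: peripherals (low, low),
connectors (low Zi, high Pi), module hubs (high Zi, low Pi) and network
hubs (high, high).
"""

from __future__ import annotations

import pandas as pd

from .correlation import CoNetwork
from .topology import ModulePartition

__all__ = ["zi_pi", "classify_roles", "ZI_THRESHOLD", "PI_THRESHOLD"]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def zi_pi(network: CoNetwork, partition: ModulePartition) -> pd.DataFrame:
    """Per-node Zi/Pi table (columns: module, degree, zi, pi, phylum, ...).

    Requires the partition to cover every network node; degree-0 nodes
    cannot occur because isolated nodes are dropped at construction.
    """
    g = network.graph if isinstance(network, CoNetwork) else network
    membership = partition.membership
    missing = [n for n in g.nodes() if n not in membership]
    if missing:
        raise ValueError(f"partition does not cover nodes {missing[:5]}")

    # within-module link counts k_is for every node i and module s
    k_is: dict = {}
    for node in g.nodes():
        counts: dict = {}
        for nb in g.neighbors(node):
            s = membership[nb]
            counts[s] = counts.get(s, 0) + 1
        k_is[node] = counts

    # per-module mean/SD of the within-module degree k_js (j in s)
    module_stats: dict = {}
    for mod in set(membership.values()):
        members = [n for n in g.nodes() if membership[n] == mod]
        within = [k_is[n].get(mod, 0) for n in members]
        mean = sum(within) / len(within)
        var = sum((w - mean) ** 2 for w in within) / len(within)  # population
        module_stats[mod] = (mean, var**0.5)

    rows = []
    for node in sorted(g.nodes()):
        mod = membership[node]
        k = g.degree(node)
        mean, sd = module_stats[mod]
        within = k_is[node].get(mod, 0)
        zi = 0.0 if sd == 0 else (within - mean) / sd
        pi = 1.0 - sum((c / k) ** 2 for c in k_is[node].values())
        data = g.nodes[node]
        rows.append({
            "otu": node, "module": mod, "degree": k, "zi": zi, "pi": pi,
            "phylum": data.get("phylum", "unclassified"),
            "kingdom": data.get("kingdom", "unknown"),
            "mean_abundance": data.get("mean_abundance", float("nan")),
        })
    return pd.DataFrame(rows).set_index("otu")


def classify_roles(
    records: pd.DataFrame,
    zi_thr: float = ZI_THRESHOLD,
    pi_thr: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Assign the four-category role from (Zi, Pi); boundaries are inclusive
    on the low side (Zi <= 2.5 and Pi <= 0.62 is peripheral)."""
    out = records.copy()

    def role(zi: float, pi: float) -> str:
        if zi <= zi_thr:
            return "peripheral" if pi <= pi_thr else "connector"
        return "module_hub" if pi <= pi_thr else "network_hub"

    out["role"] = [role(z, p) for z, p in zip(out["zi"], out["pi"])]
    return out
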