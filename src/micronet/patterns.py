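"""Intra-/inter-phylum co-occurrence and co-exclusion O/R ratios.

O(a, b) is the observed incidence: the percentage of same-sign edges that
join phylum a to phylum b. R(a, b) is the mean of the same incidence over
random G(n, m) networks drawn on the same labelled node set with the same
number of same-sign edges. O/R > 1 indicates more co-occurrence between the
two taxa than expected at random; significance is assessed empirically from
the ensemble with an add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CoNetwork

__all__ = ["ORRatioTable", "observed_incidence", "or_ratio"]


@dataclass
class ORRatioTable:
    sign: str
    table: pd.DataFrame | None  # rows (phylum_a, phylum_b): O, R, ratio, p
    n_random: int
    no_edges: bool = False  # flagged when the network has no edges of this sign


def _phylum_of(network: CoNetwork, taxonomy: pd.DataFrame | None) -> dict:
    g = network.graph
    out = {}
    for node, data in g.nodes(data=True):
        ph = data.get("phylum")
        if (ph is None or ph == "unclassified") and taxonomy is not None:
            if node in taxonomy.index and "phylum" in taxonomy.columns:
                ph = taxonomy.loc[node, "phylum"]
        out[node] = str(ph) if ph is not None else "unclassified"
    return out


def _pair_key(pa: str, pb: str) -> tuple[str, str]:
    return (pa, pb) if pa <= pb else (pb, pa)


def _incidence_from_edges(edges, phylum: dict) -> dict:
    counts: dict = {}
    total = 0
    for a, b in edges:
        key = _pair_key(phylum[a], phylum[b])
        counts[key] = counts.get(key, 0) + 1
        total += 1
    return {k: 100.0 * v / total for k, v in counts.items()}


def observed_incidence(
    network: CoNetwork, taxonomy: pd.DataFrame | None = None, sign: str = "positive"
) -> dict:
    """O(a, b): percentage of ``sign`` edges joining phyla a and b.

    Keys are sorted (phylum_a, phylum_b) tuples; intra-phylum incidence uses
    a == b. Values over all pairs sum to 100. Raises ValueError when the
    network has no edges of the requested sign (undefined, not zero).
    """
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    phylum = _phylum_of(network, taxonomy)
    edges = [
        (a, b) for a, b, d in network.graph.edges(data=True) if d.get("sign") == sign
    ]
    if not edges:
        raise ValueError(f"network has no {sign} edges; incidence undefined")
    return _incidence_from_edges(edges, phylum)


def expected_random_incidence(phylum_counts: dict) -> dict:
    """Exact G(n, m) expectation: 100 * (# a-b node pairs) / (total node pairs)."""
    phyla = sorted(phylum_counts)
    n = sum(phylum_counts.values())
    total_pairs = n * (n - 1) / 2
    out = {}
    for i, a in enumerate(phyla):
        for b in phyla[i:]:
            if a == b:
                pairs = phylum_counts[a] * (phylum_counts[a] - 1) / 2
            else:
                pairs = phylum_counts[a] * phylum_counts[b]
            out[(a, b)] = 100.0 * pairs / total_pairs
    return out


def or_ratio(
    network: CoNetwork,
    taxonomy: pd.DataFrame | None = None,
    sign: str = "positive",
    n_random: int = 1000,
    seed: int | None = None,
) -> ORRatioTable:
    """O/R ratios with empirical significance from a G(n, m) ensemble.

    Random networks keep the observed nodes and their phylum labels and
    redraw the same number of ``sign`` edges uniformly among all node pairs.
    The empirical p-value is (1 + #{replicate incidence >= O}) / (n + 1)
    when O/R > 1 and the mirrored lower-tail count otherwise. The ratio is
    NA where R = 0.
    """
    phylum = _phylum_of(network, taxonomy)
    nodes = sorted(network.graph.nodes())
    try:
        obs = observed_incidence(network, taxonomy, sign=sign)
    except ValueError:
        return ORRatioTable(sign=sign, table=None, n_random=n_random, no_edges=True)
    e_sign = sum(
        1 for _, _, d in network.graph.edges(data=True) if d.get("sign") == sign
    )
    n_nodes = len(nodes)

    phyla = sorted(set(phylum.values()))
    keys = [
        (a, b) for i, a in enumerate(phyla) for b in phyla[i:]
    ]
    key_pos = {k: i for i, k in enumerate(keys)}

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rep_seeds = ss.generate_state(n_random)
    inc = np.zeros((n_random, len(keys)))
    for r in range(n_random):
        g = nx.gnm_random_graph(n_nodes, e_sign, seed=int(rep_seeds[r] % (2**31 - 1)))
        for i, j in g.edges():
            key = _pair_key(phylum[nodes[i]], phylum[nodes[j]])
            inc[r, key_pos[key]] += 1
    inc = 100.0 * inc / e_sign

    rows = []
    for key in keys:
        col = inc[:, key_pos[key]]
        O = obs.get(key, 0.0)
        R = float(col.mean())
        if R > 0:
            ratio = O / R
        else:
            ratio = float("nan")
        if np.isnan(ratio) or ratio >= 1.0:
            p = (1 + int((col >= O - 1e-12).sum())) / (n_random + 1)
        else:
            p = (1 + int((col <= O + 1e-12).sum())) / (n_random + 1)
        rows.append({"phylum_a": key[0], "phylum_b": key[1], "O": O, "R": R,
                     "ratio": ratio, "p": p})
    table = pd.DataFrame(rows).set_index(["phylum_a", "phylum_b"])
    return ORRatioTable(sign=sign, table=table, n_random=n_random)
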