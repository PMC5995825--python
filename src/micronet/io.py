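"""Readers and writers for the tab-delimited interchange formats.

Counts TSV: first column OTU id, header row sample ids, integer counts.
Taxonomy TSV: otu, kingdom, phylum, class, order, family, genus
("unclassified" allowed at any rank). Metadata TSV: sample, then one column
per environmental variable. Groups TSV: sample, group. All files UTF-8,
tab-delimited; lines starting with '#' are ignored. Networks export to
GraphML with node taxonomy/abundance/module attributes, loadable by
Cytoscape.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocessing import AbundanceTable

__all__ = [
    "read_counts", "read_taxonomy", "read_metadata", "read_groups",
    "load_abundance_table", "write_edge_table", "write_graphml",
]

_READ_KW = dict(sep="\t", comment="#", index_col=0)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    return df


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, **_READ_KW)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, **_READ_KW)


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, dtype=str, **_READ_KW)
    return df.iloc[:, 0]


def load_abundance_table(
    counts_path, taxonomy_path=None, groups_path=None
) -> AbundanceTable:
    """Assemble a counts-mode AbundanceTable from the interchange TSVs."""
    counts = read_counts(counts_path)
    kingdom = None
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
        missing = counts.index.difference(taxonomy.index)
        if len(missing):
            raise ValueError(f"OTUs missing from taxonomy: {list(missing[:5])}")
        taxonomy = taxonomy.loc[counts.index]
        if "kingdom" in taxonomy.columns:
            kingdom = taxonomy["kingdom"]
    groups = None
    if groups_path is not None:
        groups = read_groups(groups_path)
        missing = counts.columns.difference(groups.index)
        if len(missing):
            raise ValueError(f"samples missing from groups: {list(missing[:5])}")
        groups = groups.loc[counts.columns]
    return AbundanceTable(
        values=counts, mode="counts", kingdom=kingdom, groups=groups,
        taxonomy=taxonomy,
    )


def write_edge_table(network, path) -> None:
    network.edge_table().to_csv(path, sep="\t", index=False)


def write_graphml(network, path, partition=None) -> None:
    """GraphML export with node attributes (phylum, kingdom, abundance, module)."""
    g = network.graph.copy()
    if partition is not None:
        for node in g.nodes():
            g.nodes[node]["module"] = partition.membership.get(node, "")
    nx.write_graphml(g, Path(path))
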