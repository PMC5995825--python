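"""Model/Results interface over the co-occurrence analysis.

``CooccurrenceNetworkModel`` holds the data (counts, taxonomy, environment,
zone labels) and the thresholds; ``fit()`` runs prevalence filtering,
closure to proportions, the Spearman screen and network construction for
one zone (or the whole table) and returns a ``CooccurrenceNetworkResults``
with the network, module partition, topological indices and node roles.
Null-model comparisons, O/R ratios and eigengene-environment correlations
hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import envassoc, nullmodels, patterns, roles
from .config import PipelineConfig
from .correlation import (
    CoNetwork,
    CorrelationScreen,
    DegreeFitResult,
    build_network,
    degree_distribution_fit,
    spearman_screen,
)
from .preprocessing import AbundanceTable, combine_kingdoms, prevalence_filter, to_relative
from .synthetic import SyntheticDataset
from .topology import ModulePartition, NetworkIndices, detect_modules, network_indices

__all__ = ["CooccurrenceNetworkModel", "CooccurrenceNetworkResults"]


class CooccurrenceNetworkModel:
    """Co-occurrence network model for an OTU count table.

    Parameters
    ----------
    table
        Counts-mode :class:`AbundanceTable` (OTUs x samples).
    env
        Optional sample x variable environmental matrix.
    config
        :class:`PipelineConfig` with the screening thresholds; defaults are
        the reference values (r >= 0.9, p < 0.01, q < 0.05, prevalence 8).
    """

    def __init__(
        self,
        table: AbundanceTable,
        env: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.table = table
        self.env = env
        self.config = config or PipelineConfig()

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_tsv(cls, counts, taxonomy=None, metadata=None, groups=None,
                 config: PipelineConfig | None = None) -> "CooccurrenceNetworkModel":
        from .io import load_abundance_table, read_metadata

        table = load_abundance_table(counts, taxonomy, groups)
        env = read_metadata(metadata) if metadata is not None else None
        return cls(table, env=env, config=config)

    @classmethod
    def from_synthetic(cls, dataset: SyntheticDataset,
                       config: PipelineConfig | None = None) -> "CooccurrenceNetworkModel":
        table = AbundanceTable(
            values=dataset.counts, mode="counts",
            kingdom=dataset.taxonomy["kingdom"], groups=dataset.zone,
            taxonomy=dataset.taxonomy,
        )
        return cls(table, env=dataset.env, config=config)

    # -- fitting ----------------------------------------------------------
    def fit(self, group: str | None = None) -> "CooccurrenceNetworkResults":
        """Build the thresholded network for one group (zone) or all samples."""
        cfg = self.config
        table = self.table
        if group is not None:
            table = table.select_group(group)
        filtered = prevalence_filter(table, min_prevalence=cfg.min_prevalence)
        if filtered.n_otus < 2:
            raise ValueError(
                f"fewer than 2 OTUs pass the prevalence filter "
                f"(min_prevalence={cfg.min_prevalence})"
            )
        rel = to_relative(filtered)
        screen = spearman_screen(rel)
        taxonomy = filtered.taxonomy
        network = build_network(
            screen, taxonomy=taxonomy,
            r_min=cfg.r_min, p_max=cfg.p_max, q_max=cfg.q_max,
        )
        if network.n_nodes == 0:
            partition = None
            indices = None
            role_table = None
        else:
            partition = detect_modules(network)
            indices = network_indices(network, partition)
            role_table = roles.classify_roles(
                roles.zi_pi(network, partition), zi_thr=cfg.zi_thr, pi_thr=cfg.pi_thr
            )
        env = None
        if self.env is not None:
            env = self.env.loc[rel.sample_ids]
        return CooccurrenceNetworkResults(
            model=self, group=group, table=rel, screen=screen,
            network=network, partition=partition, indices=indices,
            roles=role_table, env=env, taxonomy=taxonomy,
        )


@dataclass
class CooccurrenceNetworkResults:
    """Fitted co-occurrence network with its downstream statistics."""

    model: CooccurrenceNetworkModel
    group: str | None
    table: AbundanceTable          # relative-mode, filtered
    screen: CorrelationScreen
    network: CoNetwork
    partition: ModulePartition | None
    indices: NetworkIndices | None
    roles: pd.DataFrame | None
    env: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    _null: nullmodels.NullEnsembleSummary | None = field(default=None, repr=False)

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    # -- downstream statistics -------------------------------------------
    def degree_fit(self) -> DegreeFitResult:
        return degree_distribution_fit(self.network)

    def null_summary(self, n: int | None = None, model: str | None = None,
                     seed: int | None = None,
                     indices=nullmodels.DEFAULT_INDICES) -> nullmodels.NullEnsembleSummary:
        cfg = self.config
        summary = nullmodels.random_ensemble(
            self.network,
            n=n if n is not None else cfg.n_replicates,
            model=model if model is not None else cfg.null_model,
            seed=seed if seed is not None else cfg.seed,
            indices=indices,
        )
        self._null = summary
        return summary

    def z_tests(self, summary: nullmodels.NullEnsembleSummary | None = None) -> pd.DataFrame:
        if summary is None:
            summary = self._null or self.null_summary()
        rows = []
        for name in summary.mean:
            res = nullmodels.z_test(self.indices[name], summary, name)
            rows.append({
                "index": name, "observed": res.observed,
                "null_mean": res.null_mean, "null_sd": res.null_sd,
                "z": res.z, "p": res.p, "degenerate": res.degenerate,
            })
        return pd.DataFrame(rows).set_index("index")

    def or_ratios(self, sign: str = "positive", n_random: int | None = None,
                  seed: int | None = None) -> patterns.ORRatioTable:
        cfg = self.config
        return patterns.or_ratio(
            self.network, taxonomy=self.taxonomy, sign=sign,
            n_random=n_random if n_random is not None else cfg.n_replicates,
            seed=seed if seed is not None else cfg.seed,
        )

    def eigengenes(self, min_module_size: int | None = None) -> dict:
        """Eigengene per module with at least ``min_module_size`` members."""
        if self.partition is None:
            return {}
        min_size = (min_module_size if min_module_size is not None
                    else self.config.min_module_size)
        out = {}
        for mod in self.partition.module_ids:
            members = [m for m in self.partition.members(mod)
                       if m in self.table.otu_ids]
            if len(members) >= min_size:
                out[mod] = envassoc.module_eigengene(self.table, self.partition, mod)
        return out

    def eigengene_env(self, env: pd.DataFrame | None = None,
                      min_module_size: int | None = None) -> pd.DataFrame:
        env = env if env is not None else self.env
        if env is None:
            raise ValueError("no environmental matrix available")
        profiles = self.eigengenes(min_module_size)
        return envassoc.eigengene_env_correlations(
            profiles, env, p_max=self.config.env_p_max
        )

    def env_edges(self, env: pd.DataFrame | None = None) -> pd.DataFrame:
        env = env if env is not None else self.env
        if env is None:
            raise ValueError("no environmental matrix available")
        cfg = self.config
        # only OTUs that made it into the network carry env edges
        keep = [o for o in self.table.otu_ids if o in self.network.graph]
        sub = AbundanceTable(
            values=self.table.values.loc[keep], mode="relative",
            kingdom=self.table.kingdom.loc[keep],
        )
        return envassoc.env_edges(sub, env, r_min=cfg.env_r_min, p_max=cfg.env_p_max)

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted network."""
        lines = []
        title = "Co-occurrence network"
        if self.group:
            title += f" — group {self.group}"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"Samples: {self.table.n_samples}   "
                     f"OTUs screened: {self.table.n_otus}")
        cfg = self.config
        lines.append(
            f"Edge thresholds: |rho| >= {cfg.r_min}, p < {cfg.p_max}, q < {cfg.q_max}"
        )
        if self.indices is None:
            lines.append("Network: empty (no edge passed the thresholds)")
            return "\n".join(lines)
        idx = self.indices
        pos = sum(1 for _, _, d in self.network.graph.edges(data=True)
                  if d["sign"] == "positive")
        lines.append(f"Nodes: {idx.n_nodes}   Edges: {idx.n_edges} "
                     f"({pos} positive, {idx.n_edges - pos} negative)")
        lines.append(f"Modules: {len(self.partition.module_ids)}   "
                     f"Modularity (MD): {idx.md:.3f}")
        lines.append(f"Clustering coefficient (CC): {idx.cc:.3f}   "
                     f"Average path length (APL): {idx.apl:.3f}")
        lines.append(f"Diameter (ND): {idx.nd:.0f}   "
                     f"Average degree (AD): {idx.ad:.2f}   "
                     f"Graph density (GD): {idx.gd:.3f}")
        if self.roles is not None:
            counts = self.roles["role"].value_counts()
            parts = ", ".join(f"{k}: {v}" for k, v in counts.items())
            lines.append(f"Node roles (Zi/Pi at {cfg.zi_thr}/{cfg.pi_thr}): {parts}")
        return "\n".join(lines)
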