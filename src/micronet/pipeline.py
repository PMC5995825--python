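"""End-to-end pipeline: per-zone networks, null reports, O/R, roles, eigengenes.

``run_pipeline`` chains every stage for each zone found in the group labels
and writes the artifact bundle to disk: edge TSV + GraphML per zone,
topological indices JSON, null-model Z-test report, O/R tables per sign,
node-role TSV, eigengene and eigengene-environment TSVs, plus a run
manifest (config, seed, package versions, wall clock, success flag).
"""

from __future__ import annotations

import json
import platform
import time
import traceback
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

from . import __version__
from .config import PipelineConfig
from .io import write_edge_table, write_graphml
from .model import CooccurrenceNetworkModel

__all__ = ["run_pipeline"]


def _versions() -> dict:
    return {
        "micronet": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(config: PipelineConfig, model: CooccurrenceNetworkModel | None = None) -> dict:
    """Run the full analysis and write all artifacts under ``config.outdir``.

    Returns a manifest dict (also written to ``manifest.json``). If any
    stage fails, the manifest is still written with ``success: false`` and
    the failing stage named, then the exception is re-raised.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "success": False,
        "stage": "setup",
        "zones": {},
    }
    try:
        if model is None:
            manifest["stage"] = "load"
            if config.counts is None:
                raise ValueError("config.counts is required when no model is given")
            model = CooccurrenceNetworkModel.from_tsv(
                counts=config.counts, taxonomy=config.taxonomy,
                metadata=config.metadata, groups=config.groups, config=config,
            )
        zones = (sorted(model.table.groups.unique())
                 if model.table.groups is not None else [None])
        indices_report: dict = {}
        for zone in zones:
            zname = zone if zone is not None else "all"
            manifest["stage"] = f"fit:{zname}"
            zdir = outdir / zname
            zdir.mkdir(exist_ok=True)
            res = model.fit(group=zone)
            write_edge_table(res.network, zdir / "edges.tsv")
            if res.indices is None:
                indices_report[zname] = None
                manifest["zones"][zname] = {"n_nodes": 0, "n_edges": 0}
                continue
            write_graphml(res.network, zdir / "network.graphml", res.partition)
            indices_report[zname] = res.indices.as_dict()

            manifest["stage"] = f"null:{zname}"
            summary = res.null_summary()
            res.z_tests(summary).to_csv(zdir / "null_ztests.tsv", sep="\t")

            manifest["stage"] = f"orratio:{zname}"
            for sign in ("positive", "negative"):
                orr = res.or_ratios(sign=sign)
                if orr.table is not None:
                    orr.table.to_csv(zdir / f"or_ratio_{sign}.tsv", sep="\t")

            manifest["stage"] = f"roles:{zname}"
            res.roles.to_csv(zdir / "node_roles.tsv", sep="\t")
            membership = pandas.Series(res.partition.membership, name="module")
            membership.rename_axis("otu").to_csv(zdir / "modules.tsv", sep="\t")

            if res.env is not None:
                manifest["stage"] = f"envcorr:{zname}"
                res.env_edges().to_csv(zdir / "env_edges.tsv", sep="\t", index=False)
                profiles = res.eigengenes()
                if profiles:
                    eig = pandas.DataFrame(
                        {m: p.eigengene for m, p in profiles.items()}
                    ).T
                    eig.rename_axis("module").to_csv(zdir / "eigengenes.tsv", sep="\t")
                res.eigengene_env().to_csv(
                    zdir / "eigengene_env.tsv", sep="\t", index=False
                )
            manifest["zones"][zname] = {
                "n_nodes": res.indices.n_nodes, "n_edges": res.indices.n_edges,
            }
        manifest["stage"] = "report"
        with open(outdir / "indices.json", "w") as fh:
            json.dump(indices_report, fh, indent=2)
        manifest["success"] = True
        manifest["stage"] = "done"
    except Exception:
        manifest["error"] = traceback.format_exc()
        raise
    finally:
        manifest["wall_clock_s"] = round(time.time() - t0, 3)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
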