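"""Environment integration: env-OTU edges, module eigengenes, eigengene-env correlations.

A module eigengene is the first principal component of the module's member
OTU profiles across samples (each profile standardized to mean 0, SD 1
before the decomposition), oriented to correlate non-negatively with the
module's mean standardized profile. Eigengenes act as single representative
abundance profiles whose Spearman correlations with measured environmental
variables (TN, TP, NH4, NO2, DOC, pH, ...) summarize module-environment
relationships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import AbundanceTable
from .topology import ModulePartition

__all__ = [
    "EigengeneProfile",
    "env_edges",
    "module_eigengene",
    "eigengene_env_correlations",
]


@dataclass
class EigengeneProfile:
    module_id: str
    eigengene: pd.Series  # per-sample, unit norm
    variance_explained: float
    n_members: int
    single_member: bool = False


def env_edges(
    table: AbundanceTable,
    env: pd.DataFrame,
    r_min: float = 0.6,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Significant, strong Spearman links between env variables and OTUs.

    Retains (variable, OTU) pairs with |rho| >= r_min and p < p_max
    (p-values uncorrected). Constant variables are skipped with a warning.
    Returns columns: variable, otu, rho, p, sign.
    """
    env = env.loc[table.sample_ids]
    rows = []
    X = table.values.to_numpy(dtype=float)
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        if np.all(y == y[0]):
            warnings.warn(f"environmental variable {var!r} is constant; skipped")
            continue
        for i, otu in enumerate(table.otu_ids):
            x = X[i]
            if np.all(x == x[0]):
                continue
            rho, p = stats.spearmanr(x, y)
            if np.isnan(rho):
                continue
            if abs(rho) >= r_min and p < p_max:
                rows.append({
                    "variable": var, "otu": otu, "rho": float(rho), "p": float(p),
                    "sign": "positive" if rho > 0 else "negative",
                })
    return pd.DataFrame(rows, columns=["variable", "otu", "rho", "p", "sign"])


def module_eigengene(
    table: AbundanceTable, partition: ModulePartition, module_id: str
) -> EigengeneProfile:
    """First principal component of the module's standardized member profiles.

    Member rows are standardized across samples (population SD); the
    eigengene is the first right singular vector (unit norm over samples),
    sign-fixed to correlate non-negatively with the mean standardized
    profile. Variance explained is s1^2 / sum s_k^2. A single-member module
    returns that standardized profile (normalized), flagged.
    """
    members = [m for m in partition.members(module_id) if m in table.otu_ids]
    if not members:
        raise ValueError(f"module {module_id!r} has no members in the table")
    Z = table.values.loc[members].to_numpy(dtype=float)
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant member contributes zeros
    Z = (Z - mu) / sd

    if len(members) == 1:
        v = Z[0]
        norm = np.linalg.norm(v)
        e = v / norm if norm > 0 else v
        return EigengeneProfile(
            module_id=module_id,
            eigengene=pd.Series(e, index=table.sample_ids),
            variance_explained=1.0,
            n_members=1,
            single_member=True,
        )

    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    if float(e @ Z.mean(axis=0)) < 0:
        e = -e
    varexp = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 1.0
    return EigengeneProfile(
        module_id=module_id,
        eigengene=pd.Series(e, index=table.sample_ids),
        variance_explained=varexp,
        n_members=len(members),
    )


def eigengene_env_correlations(
    profiles: list[EigengeneProfile] | dict[str, EigengeneProfile],
    env: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho/p per (module eigengene, environmental variable).

    Returns all pairs with a ``significant`` flag at p < p_max; the
    Fig.-style export keeps only significant rows, with |rho| as line
    weight.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    rows = []
    for prof in profiles:
        e = prof.eigengene
        env_aligned = env.loc[e.index]
        for var in env_aligned.columns:
            y = env_aligned[var].to_numpy(dtype=float)
            if np.all(y == y[0]):
                continue
            rho, p = stats.spearmanr(e.to_numpy(), y)
            rows.append({
                "module": prof.module_id, "variable": var,
                "rho": float(rho), "p": float(p),
                "significant": bool(p < p_max),
                "sign": "positive" if rho > 0 else "negative",
            })
    return pd.DataFrame(
        rows, columns=["module", "variable", "rho", "p", "significant", "sign"]
    )
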