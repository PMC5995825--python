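import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import micronet as mn
from micronet.envassoc import (
    eigengene_env_correlations,
    env_edges,
    module_eigengene,
)
from micronet.preprocessing import AbundanceTable
from micronet.topology import ModulePartition


def relative(values):
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"O{i}" for i in range(df.shape[0])]
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    df = df / df.sum(axis=0)
    return AbundanceTable(values=df, mode="relative")


def part(mapping):
    return ModulePartition(membership=mapping, modularity=0.0)


class TestEnvEdges:
    def test_identity_profile_retained(self):
        tab = relative(np.array([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1.0]]))
        env = pd.DataFrame({"TN": tab.values.loc["O0"].to_numpy()},
                           index=tab.sample_ids)
        edges = env_edges(tab, env)
        row = edges[edges["otu"] == "O0"].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["sign"] == "positive"

    def test_thresholds_respected(self):
        rng = np.random.default_rng(0)
        tab = relative(rng.integers(1, 50, size=(10, 8)))
        env = pd.DataFrame(rng.standard_normal((8, 2)), index=tab.sample_ids,
                           columns=["TN", "pH"])
        edges = env_edges(tab, env, r_min=0.6, p_max=0.05)
        for _, row in edges.iterrows():
            assert abs(row["rho"]) >= 0.6 and row["p"] < 0.05

    def test_constant_variable_skipped_with_warning(self):
        tab = relative(np.array([[1, 2, 3, 4, 5, 6.0]]))
        env = pd.DataFrame({"pH": [7.0] * 6}, index=tab.sample_ids)
        with pytest.warns(UserWarning, match="constant"):
            edges = env_edges(tab, env)
        assert edges.empty


class TestModuleEigengene:
    def test_identical_members_rank_one(self):
        base = np.array([1, 5, 2, 9, 3, 7.0])
        tab = relative(np.vstack([base, base, base, np.ones(6)]))
        p = part({"O0": "M1", "O1": "M1", "O2": "M1", "O3": "M2"})
        prof = module_eigengene(tab, p, "M1")
        assert prof.variance_explained == pytest.approx(1.0)
        # equals the common standardized (closed) profile up to norm
        common = tab.values.loc["O0"].to_numpy()
        z = (common - common.mean()) / common.std()
        rho = np.corrcoef(prof.eigengene, z)[0, 1]
        assert rho == pytest.approx(1.0)

    def test_anticorrelated_pair_still_rank_one_with_orientation(self):
        base = np.array([1, 5, 2, 9, 3, 7.0])
        anti = base.max() + base.min() - base
        tab = relative(np.vstack([base * 10, anti * 10, np.ones(6)]))
        p = part({"O0": "M1", "O1": "M1", "O2": "M2"})
        prof = module_eigengene(tab, p, "M1")
        assert prof.variance_explained > 0.95
        # sign convention: non-negative correlation with the mean profile
        members = tab.values.loc[["O0", "O1"]].to_numpy()
        z = (members - members.mean(1, keepdims=True)) / members.std(1, keepdims=True)
        assert float(prof.eigengene @ z.mean(axis=0)) >= -1e-12

    def test_single_member_flagged(self):
        tab = relative(np.array([[1, 2, 3, 4, 5, 6.0], [2, 2, 2, 2, 2, 2.0]]))
        prof = module_eigengene(tab, part({"O0": "M1", "O1": "M2"}), "M1")
        assert prof.single_member and prof.n_members == 1

    def test_invariant_under_member_reordering(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 30, size=(5, 8)).astype(float)
        tab1 = relative(X)
        tab2 = relative(X[::-1])
        tab2.values.index = [f"O{i}" for i in range(4, -1, -1)]
        members = {f"O{i}": "M1" for i in range(5)}
        p1 = module_eigengene(tab1, part(members), "M1")
        p2 = module_eigengene(tab2, part(members), "M1")
        rho = np.corrcoef(p1.eigengene, p2.eigengene)[0, 1]
        assert abs(rho) == pytest.approx(1.0, abs=1e-9)

    def test_variance_explained_decreases_with_noise_members(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 10, size=8)
        rows = [base * s for s in (1.0, 2.0, 3.0)]
        ve = []
        for n_noise in (0, 2, 4):
            noise = rng.uniform(1, 10, size=(n_noise, 8))
            X = np.vstack(rows + [noise]) if n_noise else np.vstack(rows)
            tab = relative(np.vstack([X, np.ones(8)]))
            members = {f"O{i}": "M1" for i in range(3 + n_noise)}
            members[f"O{3 + n_noise}"] = "M2"
            ve.append(module_eigengene(tab, part(members), "M1").variance_explained)
        assert ve[0] >= ve[1] >= ve[2]


class TestEigengeneEnv:
    def test_identity_env_variable(self):
        base = np.array([1, 5, 2, 9, 3, 7.0])
        tab = relative(np.vstack([base, base * 2, np.ones(6)]))
        p = part({"O0": "M1", "O1": "M1", "O2": "M2"})
        prof = module_eigengene(tab, p, "M1")
        env = pd.DataFrame({"TN": prof.eigengene.to_numpy()},
                           index=prof.eigengene.index)
        out = eigengene_env_correlations([prof], env)
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert bool(out.iloc[0]["significant"])

    def test_planted_env_link_recovered(self):
        """Module driven by TN: pipeline recovers the TN association."""
        hits = 0
        for seed in range(5):
            cfg = mn.SyntheticConfig(
                loading_strength=0.95, seed=seed,
                env_link={1: ("TN", 1.0)},
            )
            ds = mn.generate_dataset(cfg)
            model = mn.CooccurrenceNetworkModel.from_synthetic(ds)
            res = model.fit(group="Z1")
            corr = res.eigengene_env()
            if corr.empty:
                continue
            # at least one detected module must carry a significant positive
            # TN correlation matching the planted driver
            tn = corr[(corr["variable"] == "TN") & corr["significant"]]
            strong = tn[tn["rho"].abs() >= 0.6]
            hits += not strong.empty
        assert hits >= 4

    def test_factor_recovery_via_truth_modules(self):
        """Eigengene of a planted module tracks its latent factor."""
        rhos = []
        for seed in range(3):
            cfg = mn.SyntheticConfig(loading_strength=0.95, seed=seed)
            ds = mn.generate_dataset(cfg)
            tab = mn.to_relative(AbundanceTable(ds.counts, mode="counts"))
            p = part(ds.truth_modules.to_dict())
            for mod in ("M1", "M2", "M3", "M4"):
                prof = module_eigengene(tab, p, mod)
                f = ds.truth_factors[mod].loc[prof.eigengene.index]
                rhos.append(abs(spearmanr(prof.eigengene, f)[0]))
        assert np.median(rhos) >= 0.9
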