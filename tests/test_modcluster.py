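"""Module clustering of condition profiles and the color-consistency filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from wingarray import build_profiles, filter_inconsistent, mmc_cluster
from wingarray.config import ClusterConfig
from wingarray.modcluster import ModuleAssignment, _modularity, summarize_modules


def block_profiles(n_blocks=3, n_per_block=30, n_cond=45, rho=0.9, seed=0):
    """Planted correlation blocks: shared block signal + independent noise."""
    rng = np.random.default_rng(seed)
    noise_sd = 0.2
    signal_sd = noise_sd * np.sqrt(rho / (1 - rho))
    rows, labels = [], []
    for b in range(n_blocks):
        signal = rng.normal(0.0, signal_sd, n_cond)
        for g in range(n_per_block):
            rows.append(signal + rng.normal(0.0, noise_sd, n_cond))
            labels.append(b)
    idx = [f"g{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(labels)


def perfect_blocks(n_per_block=20, n_cond=30, seed=1):
    """Two blocks with within-block correlation 1 and between-block 0."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.normal(size=n_cond), rng.normal(size=n_cond)
    scale = np.concatenate([rng.uniform(0.5, 2.0, n_per_block),
                            rng.uniform(0.5, 2.0, n_per_block)])
    rows = [s1 * scale[i] for i in range(n_per_block)]
    rows += [s2 * scale[n_per_block + i] for i in range(n_per_block)]
    idx = [f"g{i:03d}" for i in range(2 * n_per_block)]
    truth = np.repeat([0, 1], n_per_block)
    return pd.DataFrame(rows, index=idx), truth


class TestBuildProfiles:
    def _design(self):
        return pd.DataFrame({
            "sample_id": ["s1", "s2", "s3"],
            "wing": "forewing", "morph": "hybrid", "section": ["proximal"] * 2 + ["medial"],
            "stage": "D1", "individual": ["i1", "i2", "i3"], "slide": "sl1",
            "color": ["red", "red", "yellow"],
        })

    def test_condition_means(self):
        expr = pd.DataFrame([[1.0, 3.0, 7.0]], index=["c"], columns=["s1", "s2", "s3"])
        profiles, conditions = build_profiles(expr, self._design())
        assert profiles.loc["c", "forewing:hybrid:proximal:D1"] == pytest.approx(2.0)
        assert profiles.loc["c", "forewing:hybrid:medial:D1"] == pytest.approx(7.0)
        assert conditions.loc["forewing:hybrid:proximal:D1", "n_samples"] == 2

    def test_identical_samples_identical_profiles(self):
        expr = pd.DataFrame([[1.0, 3.0, 7.0], [1.0, 3.0, 7.0]],
                            index=["a", "b"], columns=["s1", "s2", "s3"])
        profiles, _ = build_profiles(expr, self._design())
        assert profiles.loc["a"].equals(profiles.loc["b"])

    def test_empty_condition_rejected(self):
        expr = pd.DataFrame([[1.0, 3.0]], index=["c"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="condition"):
            build_profiles(expr, self._design())


class TestMMCCluster:
    def test_perfect_two_blocks(self):
        profiles, truth = perfect_blocks()
        out = mmc_cluster(profiles)
        assert out.membership.nunique() == 2
        assert adjusted_rand_score(truth, pd.factorize(out.membership)[0]) == 1.0

    def test_single_contig_singleton(self):
        profiles = pd.DataFrame([np.arange(10.0)], index=["only"])
        out = mmc_cluster(profiles)
        assert out.membership["only"] == "M001"
        assert out.membership.nunique() == 1

    def test_three_planted_blocks_recovered(self):
        """rho=0.9 within, 0 between, 30 genes per block, noise SD 0.2:
        adjusted Rand index vs planted labels >= 0.9."""
        profiles, truth = block_profiles(seed=7)
        out = mmc_cluster(profiles)
        ari = adjusted_rand_score(truth, pd.factorize(out.membership)[0])
        assert ari >= 0.9

    def test_constant_profile_becomes_singleton(self):
        profiles, _ = perfect_blocks(n_per_block=5)
        profiles.loc["gflat"] = 2.0
        out = mmc_cluster(profiles)
        assert (out.membership == out.membership["gflat"]).sum() == 1

    def test_partition_property(self):
        profiles, _ = block_profiles(n_per_block=10, seed=3)
        out = mmc_cluster(profiles)
        assert set(out.membership.index) == set(profiles.index)
        assert out.membership.notna().all()

    def test_modularity_beats_trivial_partition(self):
        profiles, _ = block_profiles(n_per_block=10, seed=4)
        out = mmc_cluster(profiles)
        rho = np.abs(np.corrcoef(profiles.loc[sorted(profiles.index)]))
        np.fill_diagonal(rho, 0.0)
        W = rho ** out.sharpness
        trivial = _modularity(W, [set(range(len(profiles)))])
        assert out.modularity >= trivial - 1e-12

    def test_permutation_invariance(self):
        profiles, _ = block_profiles(n_per_block=8, seed=5)
        out1 = mmc_cluster(profiles)
        shuffled = profiles.sample(frac=1.0, random_state=99)
        out2 = mmc_cluster(shuffled)
        pd.testing.assert_series_equal(out1.membership.sort_index(),
                                       out2.membership.sort_index())

    def test_matches_networkx_on_block_graph(self):
        """Independent check: networkx's greedy modularity agrees on a clean
        two-block weight matrix."""
        import networkx as nx

        profiles, truth = perfect_blocks(n_per_block=10)
        out = mmc_cluster(profiles)
        order = sorted(profiles.index)
        rho = np.abs(np.corrcoef(profiles.loc[order]))
        np.fill_diagonal(rho, 0.0)
        G = nx.from_numpy_array(rho ** out.sharpness)
        communities = nx.community.greedy_modularity_communities(G, weight="weight")
        nx_labels = np.empty(len(order), dtype=int)
        for lab, comm in enumerate(communities):
            for i in comm:
                nx_labels[i] = lab
        ours = pd.factorize(out.membership[order])[0]
        assert adjusted_rand_score(nx_labels, ours) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mmc_cluster(pd.DataFrame())


def toy_conditions():
    rows = []
    for stage in ("OMMO", "MELA"):
        for color, cond in (("red", f"fw:h:prox:{stage}"), ("black", f"fw:h:dist:{stage}")):
            rows.append({"condition": cond, "wing": "fw", "morph": "h",
                         "section": "x", "stage": stage, "color": color,
                         "n_samples": 3})
    return pd.DataFrame(rows).set_index("condition")


def assignment_for(profile_rows, conditions):
    profiles = pd.DataFrame(profile_rows, columns=conditions.index)
    profiles.index = [f"g{i}" for i in range(len(profiles))]
    membership = pd.Series("M001", index=profiles.index)
    membership.index.name = "contig_id"
    return profiles, ModuleAssignment(membership=membership, sharpness=1.0, modularity=0.0)


class TestConsistencyFilter:
    def test_consistent_module_kept_with_direction(self):
        """red-black of +1.2 at OMMO and +0.9 at MELA: members kept,
        direction upregulated."""
        conditions = toy_conditions()
        profiles, assignment = assignment_for(
            [[1.2, 0.0, 0.9, 0.0]], conditions)
        summarize_modules(assignment, profiles, conditions, epsilon=0.5)
        out = filter_inconsistent(["g0"], assignment)
        assert list(out["contig_id"]) == ["g0"]
        assert out.iloc[0]["direction"] == "upregulated"

    def test_sign_flip_removed(self):
        conditions = toy_conditions()
        profiles, assignment = assignment_for(
            [[0.8, 0.0, -0.8, 0.0]], conditions)
        summarize_modules(assignment, profiles, conditions, epsilon=0.5)
        assert filter_inconsistent(["g0"], assignment).empty

    def test_small_contrast_removed(self):
        conditions = toy_conditions()
        profiles, assignment = assignment_for(
            [[0.2, 0.0, 0.3, 0.0]], conditions)
        summarize_modules(assignment, profiles, conditions, epsilon=0.5)
        assert filter_inconsistent(["g0"], assignment).empty

    def test_output_subset_of_candidates(self, recovery_run):
        final = set(recovery_run.final["contig_id"])
        assert final <= set(recovery_run.candidates["contig_id"])

    def test_morph_global_leakers_purged(self, recovery_run):
        """If every planted morph-wide contig is forced into the candidate
        pool, the module filter removes >= 90% of them."""
        from wingarray.modcluster import build_profiles as bp, mmc_cluster as mc

        truth = recovery_run.truth.set_index("contig_id")
        morph = sorted(truth.index[truth["effect_class"] == "morph_global"])
        candidates = sorted(set(recovery_run.candidates["contig_id"]) | set(morph))
        profiles, conditions = bp(recovery_run.expr["joint"], recovery_run.design)
        sub = profiles.loc[candidates]
        assignment = mc(sub, ClusterConfig())
        summarize_modules(assignment, sub, conditions, epsilon=0.5)
        final = set(filter_inconsistent(candidates, assignment)["contig_id"])
        removed = [c for c in morph if c not in final]
        assert len(removed) / len(morph) >= 0.9
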