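import numpy as np
import pytest

import sweepscan as ss
from sweepscan.genotypes_io import MISSING

from conftest import make_gm, single_pop_map
from oracles import random_additive_distances


class TestIbsDistance:
    def test_identical_and_opposite(self):
        gm = make_gm([[0, 0, 2], [2, 2, 0], [1, 1, 1]])
        dm = ss.ibs_distance(gm)
        assert dm.values[0, 1] == 0.0          # identical samples
        assert dm.values[0, 2] == pytest.approx((1 + 1 + 0) / 3)
        gm = make_gm([[0, 2], [2, 0], [0, 2]])
        assert ss.ibs_distance(gm).values[0, 1] == 1.0  # opposite homozygotes

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(0)
        geno = rng.choice([0, 1, 2, MISSING], size=(80, 7),
                          p=[0.35, 0.3, 0.25, 0.1]).astype(np.int8)
        gm = make_gm(geno)
        dm = ss.ibs_distance(gm)
        for i in range(7):
            for j in range(i + 1, 7):
                num = den = 0
                for s in range(80):
                    gi, gj = geno[s, i], geno[s, j]
                    if gi < 0 or gj < 0:
                        continue
                    num += abs(int(gi) - int(gj)) / 2
                    den += 1
                assert dm.values[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_no_cocalled_pair_errors(self):
        gm = make_gm([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="share no called SNPs"):
            ss.ibs_distance(gm)


def tree_distances(tree: ss.TreeNode) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths of a TreeNode, via root paths."""
    depths = {}

    def walk(node, acc):
        for ch in node.children:
            if ch.children:
                walk(ch, acc + ch.length)
            else:
                depths[ch.name] = (acc + ch.length, ch)
        return None

    # path length = depth_i + depth_j - 2 * depth of LCA; easier: recurse
    out = {}

    def collect(node):
        """Return {leaf: dist to this node}; fill `out` for cross-child pairs."""
        maps = []
        for ch in node.children:
            sub = collect(ch) if ch.children else {ch.name: 0.0}
            maps.append({k: v + ch.length for k, v in sub.items()})
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for x, dx in maps[a].items():
                    for y, dy in maps[b].items():
                        out[frozenset((x, y))] = dx + dy
        merged = {}
        for m in maps:
            merged.update(m)
        return merged

    collect(tree)
    return out


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        """Additive AB=3 AC=5 AD=6 BC=6 BD=7 CD=7 recovers AB|CD with exact lengths."""
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = ss.nj_tree(ss.DistanceMatrix(["A", "B", "C", "D"], D))
        assert ss.bipartitions(tree) == {frozenset({"C", "D"})}
        dists = tree_distances(tree)
        assert dists[frozenset(("A", "B"))] == pytest.approx(3)
        assert dists[frozenset(("C", "D"))] == pytest.approx(7)
        assert dists[frozenset(("A", "D"))] == pytest.approx(6)
        # leaf branch lengths A:1 B:2 C:3 D:4
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_three_point_formula(self):
        D = np.array([[0, 4, 5], [4, 0, 7], [5, 7, 0]], float)
        tree = ss.nj_tree(ss.DistanceMatrix(["x", "y", "z"], D))
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["x"] == pytest.approx((4 + 5 - 7) / 2)
        assert lengths["y"] == pytest.approx((4 + 7 - 5) / 2)
        assert lengths["z"] == pytest.approx((5 + 7 - 4) / 2)

    def test_recovers_random_additive_trees(self):
        """Exact topology and path-length recovery on 20 random additive
        matrices with 5-8 taxa."""
        rng = np.random.default_rng(42)
        for rep in range(20):
            n = int(rng.integers(5, 9))
            names, D, splits = random_additive_distances(rng, n)
            tree = ss.nj_tree(ss.DistanceMatrix(names, D))
            assert ss.bipartitions(tree) == splits
            dists = tree_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    assert dists[frozenset((names[i], names[j]))] == pytest.approx(
                        D[i, j], abs=1e-9)

    def test_leaf_permutation_gives_same_tree(self):
        rng = np.random.default_rng(1)
        names, D, splits = random_additive_distances(rng, 6)
        perm = rng.permutation(6)
        tree = ss.nj_tree(ss.DistanceMatrix([names[i] for i in perm], D[np.ix_(perm, perm)]))
        assert ss.bipartitions(tree) == splits

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            ss.nj_tree(ss.DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            ss.nj_tree(ss.DistanceMatrix(["a", "b", "c"], bad))


class TestBootstrap:
    def test_strong_split_saturates_support(self, two_pop_sim):
        gm, pm, _, _ = two_pop_sim
        tree = ss.bootstrap_support(gm, n_reps=100, seed=3)
        supports = {}

        def walk(node):
            for ch in node.children:
                if ch.support is not None:
                    supports[ch.leaf_names()] = ch.support
                walk(ch)

        walk(tree)
        pop_b = frozenset(s for s in gm.samples if s.startswith("B"))
        assert any(k == pop_b and v == 1.0 for k, v in supports.items())

    def test_zero_reps_and_seed_determinism(self, two_pop_sim):
        gm, _, _, _ = two_pop_sim
        plain = ss.bootstrap_support(gm, n_reps=0, seed=0)
        assert all(ch.support is None for ch in plain.children)
        t1 = ss.bootstrap_support(gm, n_reps=20, seed=9)
        t2 = ss.bootstrap_support(gm, n_reps=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_unit_interval(self, two_pop_sim):
        gm, _, _, _ = two_pop_sim
        tree = ss.bootstrap_support(gm, n_reps=20, seed=1)

        def walk(node):
            for ch in node.children:
                if ch.support is not None:
                    assert 0.0 <= ch.support <= 1.0
                walk(ch)

        walk(tree)

    def test_same_population_samples_cluster(self, sweep_sim):
        gm, pm, _, _ = sweep_sim
        dm = ss.ibs_distance(gm)
        labels = np.array([pm.assignment[s] for s in dm.ids])
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        intra = dm.values[same & off_diag].mean()
        inter = dm.values[~same].mean()
        assert intra < inter


class TestPca:
    def test_two_populations_separate_on_pc1(self, two_pop_sim):
        gm, pm, _, _ = two_pop_sim
        res = ss.pca(gm)
        a = res.coords[[i for i, s in enumerate(gm.samples) if s.startswith("A")], 0]
        b = res.coords[[i for i, s in enumerate(gm.samples) if s.startswith("B")], 0]
        assert a.max() < b.min() or b.max() < a.min()

    def test_identical_samples_collapse(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=np.int8)
        gm = make_gm(np.column_stack([col, col, col]).astype(np.int8).reshape(10, 3))
        res = ss.pca(gm)
        assert np.allclose(res.coords, res.coords[0], atol=1e-10)

    def test_explained_variance_non_increasing(self, two_pop_sim):
        gm, _, _, _ = two_pop_sim
        res = ss.pca(gm)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert (res.explained >= 0).all()

    def test_sample_order_invariance_up_to_sign(self, two_pop_sim):
        gm, _, _, _ = two_pop_sim
        res = ss.pca(gm, n_components=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_samples)
        gm2 = make_gm(gm.geno[:, perm], chrom=list(gm.chrom), pos=gm.pos,
                      samples=[gm.samples[i] for i in perm])
        res2 = ss.pca(gm2, n_components=3)
        back = np.argsort(perm)
        for c in range(3):
            x, y = res.coords[:, c], res2.coords[back, c]
            assert np.allclose(x, y, atol=1e-8) or np.allclose(x, -y, atol=1e-8)


class TestLdDecay:
    def test_duplicated_snp_gives_r2_one(self):
        rng = np.random.default_rng(5)
        col = rng.choice([0, 1, 2], size=20).astype(np.int8)
        other = rng.choice([0, 1, 2], size=20).astype(np.int8)
        gm = make_gm(np.vstack([col, col, other]).astype(np.int8),
                     pos=[100, 150, 5000])
        pm = single_pop_map(gm)
        ld = ss.ld_decay(gm, pm, "P", max_dist=10_000, n_bins=10)
        first = ld[ld["n_pairs"] > 0].iloc[0]
        assert first["mean_r2"] == pytest.approx(1.0)

    def test_independent_snps_near_null_inflation(self):
        # unlinked sites: E[r2] ~ 1/n from finite-sample inflation
        cfg = ss.SimConfig(pop_names=["A"], samples_per_pop=50, pop_F=0.0,
                           chrom_lengths={"chr1": 500_000}, snp_density=1e-3,
                           founder_haplotypes=None, missing_rate=0.0, seed=2)
        gm, pm, _, _ = ss.simulate(cfg)
        ld = ss.ld_decay(gm, pm, "A", max_dist=400_000, n_bins=4)
        vals = ld.loc[ld["n_pairs"] > 100, "mean_r2"]
        assert (vals < 3 / 50).all()

    def test_monomorphic_snps_skipped(self):
        gm = make_gm([[1, 0, 1, 2], [0, 0, 0, 0], [2, 1, 0, 1]], pos=[10, 20, 30])
        ld = ss.ld_decay(gm, single_pop_map(gm), "P", max_dist=100, n_bins=2)
        # only the polymorphic pair (pos 10, 30) contributes
        assert ld["n_pairs"].sum() == 1
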