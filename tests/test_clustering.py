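import numpy as np
import pandas as pd
import pytest

from seedtrace.clustering import (
    detect_homogeneous_source,
    neighbor_joining,
    population_mixing_index,
)


def _random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive edge lengths; returns
    (newick-free) leaf distance matrix built by path-length accumulation."""
    import itertools

    # start from 3 leaves joined at a hub, then attach leaves to random edges
    nodes = {0: {}, 1: {}, 2: {}, "h0": {}}
    edges = {}

    def connect(a, b, w):
        edges[(a, b)] = w
        edges[(b, a)] = w
        nodes[a][b] = w
        nodes[b][a] = w

    for leaf in (0, 1, 2):
        connect(leaf, "h0", float(rng.uniform(0.5, 2.0)))
    hub = 1
    for leaf in range(3, n_leaves):
        # split a random existing edge and hang the new leaf off the split
        pairs = [(a, b) for (a, b) in edges if str(a) < str(b) or (
            isinstance(a, int) and isinstance(b, int) and a < b)]
        a, b = pairs[int(rng.integers(len(pairs)))]
        w = edges[(a, b)]
        for key in ((a, b), (b, a)):
            del edges[key]
        nodes[a].pop(b)
        nodes[b].pop(a)
        mid = f"h{hub}"
        hub += 1
        nodes[mid] = {}
        t = float(rng.uniform(0.2, 0.8))
        connect(a, mid, w * t)
        connect(mid, b, w * (1 - t))
        nodes[leaf] = {}
        connect(leaf, mid, float(rng.uniform(0.5, 2.0)))

    # all-pairs path lengths by BFS over the tree
    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in nodes[cur].items():
                if nb not in out:
                    out[nb] = out[cur] + w
                    stack.append(nb)
        return out

    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        d = dist_from(i)
        for j in range(n_leaves):
            D[i, j] = d[j]
    return D


def _newick_distances(newick, labels):
    """Leaf-to-leaf path lengths recomputed independently with dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[str(labels[i])], taxa[str(labels[j])])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> a=1, b=2, c=3
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = neighbor_joining(D)
        dist = _newick_distances(tree.newick, list("ABC"))
        assert np.allclose(dist, D.to_numpy(), atol=1e-9)

    def test_four_taxon_additive(self):
        D = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        tree = neighbor_joining(D)
        # additive reconstruction: path lengths reproduce D exactly
        dist = _newick_distances(tree.newick, list("ABCD"))
        assert np.allclose(dist, D.to_numpy(), atol=1e-9)
        # topology ((A,B),(C,D)): A-B distance 2 split as pendant edges of 1
        assert "(A:1,B:1)" in tree.newick or "(B:1,A:1)" in tree.newick

    def test_clone_pair_zero_cherry(self):
        D = pd.DataFrame(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0.5], [1, 1, 0.5, 0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        tree = neighbor_joining(D)
        dist = _newick_distances(tree.newick, list("AB"))
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_reconstructs_random_additive(self, rng, n_leaves):
        for rep in range(5):
            D = _random_additive_tree(rng, n_leaves)
            labels = [f"L{i}" for i in range(n_leaves)]
            tree = neighbor_joining(pd.DataFrame(D, index=labels, columns=labels))
            dist = _newick_distances(tree.newick, labels)
            assert np.allclose(dist, D, atol=1e-8)

    def test_non_symmetric_raises(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))

    def test_too_few_leaves(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)))


def _mixing_oracle(D, labels, group):
    """Exhaustive nearest-neighbour scan."""
    inds = [i for i in D.index if labels[i] in group]
    out = {}
    for pop in group:
        members = [i for i in inds if labels[i] == pop]
        cross = 0
        for i in members:
            best, best_d = None, np.inf
            for j in inds:
                if j == i:
                    continue
                d = D.loc[i, j]
                if d < best_d:
                    best, best_d = j, d
            cross += labels[best] != pop
        out[pop] = cross / len(members)
    return out


class TestMixingIndex:
    def test_matches_oracle_on_clones(self):
        # two populations of identical genotypes: deterministic tie-breaks
        n = 8
        ids = [f"i{k}" for k in range(n)]
        D = pd.DataFrame(np.zeros((n, n)), index=ids, columns=ids)
        labels = {f"i{k}": ("P" if k < 4 else "Q") for k in range(n)}
        got = population_mixing_index(D, labels, {"P", "Q"})
        assert got == _mixing_oracle(D, labels, {"P", "Q"})

    def test_separated_populations_zero(self, rng):
        n = 10
        ids = [f"i{k}" for k in range(n)]
        within = rng.uniform(0.0, 0.1, (n, n))
        D = (within + within.T) / 2
        D[:5, 5:] += 10.0
        D[5:, :5] += 10.0
        np.fill_diagonal(D, 0)
        Df = pd.DataFrame(D, index=ids, columns=ids)
        labels = {f"i{k}": ("P" if k < 5 else "Q") for k in range(n)}
        got = population_mixing_index(Df, labels, {"P", "Q"})
        assert got == {"P": 0.0, "Q": 0.0}

    def test_matches_oracle_random(self, rng):
        n = 20
        ids = [f"i{k}" for k in range(n)]
        M = rng.uniform(0, 1, (n, n))
        D = pd.DataFrame((M + M.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(D.values, 0)
        labels = {f"i{k}": f"P{k % 4}" for k in range(n)}
        group = {"P0", "P1", "P2", "P3"}
        assert population_mixing_index(D, labels, group) == _mixing_oracle(
            D, labels, group
        )

    def test_relabeling_invariance(self, rng):
        n = 12
        ids = [f"i{k}" for k in range(n)]
        M = rng.uniform(0, 1, (n, n))
        D = pd.DataFrame((M + M.T) / 2, index=ids, columns=ids)
        np.fill_diagonal(D.values, 0)
        labels = {f"i{k}": ("P" if k < 6 else "Q") for k in range(n)}
        base = population_mixing_index(D, labels, {"P", "Q"})
        # permute individuals within populations (reorder matrix rows)
        perm = [3, 1, 5, 0, 2, 4] + [6 + k for k in [2, 0, 1, 5, 4, 3]]
        ids2 = [ids[k] for k in perm]
        D2 = D.loc[ids2, ids2]
        assert population_mixing_index(D2, labels, {"P", "Q"}) == base

    def test_singleton_raises(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        with pytest.raises(ValueError):
            population_mixing_index(D, {"a": "P", "b": "P", "c": "Q"}, {"P", "Q"})


class TestDetectHomogeneousSource:
    def _scenario_report(self, seed):
        from seedtrace.scenarios import demo_scenario
        from seedtrace.simulate import generate_scenario
        from seedtrace.popstats import ibs_dissimilarity, pairwise_fst
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            G, truth, _ = generate_scenario(demo_scenario(seed=seed), tmp)
        labels = {i: truth.pop_of_individual[i] for i in G.individual_ids}
        fst = pairwise_fst(G, labels)
        D = ibs_dissimilarity(G)
        esu_of_pop = {
            "natA1": "A", "natA2": "A", "seedA1": "A", "seedA2": "A",
            "seedA3": "A", "admixAB": "A", "natB1": "B", "natC1": "C",
            "allochC": "C",
        }
        return truth, detect_homogeneous_source(fst, D, labels, esu_of_pop)

    def test_flags_seed_lot_not_naturals(self):
        hits = 0
        for seed in range(5):
            truth, report = self._scenario_report(300 + seed)
            flagged = report.flagged_populations()
            if flagged == {"seedA1", "seedA2", "seedA3"}:
                hits += 1
        assert hits >= 4

    def test_differentiated_naturals_unflagged(self, rng):
        # two populations at high FST -> nothing flagged
        ids = [f"i{k}" for k in range(8)]
        labels = {f"i{k}": ("P" if k < 4 else "Q") for k in range(8)}
        fst = pd.DataFrame([[0.0, 0.2], [0.2, 0.0]], index=["P", "Q"],
                           columns=["P", "Q"])
        M = rng.uniform(0, 1, (8, 8))
        D = pd.DataFrame((M + M.T) / 2, index=ids, columns=ids)
        report = detect_homogeneous_source(fst, D, labels, {"P": "A", "Q": "A"})
        assert report.flagged_populations() == set()

    def test_single_population_group(self, rng):
        ids = ["a", "b"]
        D = pd.DataFrame(np.zeros((2, 2)), index=ids, columns=ids)
        fst = pd.DataFrame([[0.0]], index=["P"], columns=["P"])
        report = detect_homogeneous_source(
            fst, D, {"a": "P", "b": "P"}, {"P": "A"}
        )
        assert report.flagged_populations() == set()
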