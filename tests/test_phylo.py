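"""Distance computation, neighbor joining and bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

from telandscape.phylo import (
    DistanceMatrix,
    NJTree,
    bootstrap,
    neighbor_joining,
    pdistance,
    read_newick,
    write_newick,
)


def random_additive_matrix(rng, n):
    """Random unrooted binary tree with positive branch lengths, returned
    as (bipartition set, additive DistanceMatrix); NJ must recover both."""
    labels = [f"T{i}" for i in range(n)]
    adj: dict = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def drop_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    add_edge("x0", labels[0], float(rng.uniform(0.1, 2.0)))
    add_edge("x0", labels[1], float(rng.uniform(0.1, 2.0)))
    add_edge("x0", labels[2], float(rng.uniform(0.1, 2.0)))
    next_internal = 1
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = adj[u][v]
        t = float(rng.uniform(0.2, 0.8))
        x = f"x{next_internal}"
        next_internal += 1
        drop_edge(u, v)
        add_edge(u, x, w * t)
        add_edge(x, v, w * (1 - t))
        add_edge(x, leaf, float(rng.uniform(0.1, 2.0)))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in out:
                    out[nb] = out[node] + w
                    stack.append(nb)
        return out

    taxa = sorted(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        da = dists_from(a)
        for j, b in enumerate(taxa):
            if i != j:
                d[i, j] = da[b]

    # bipartitions: leaves on one side of each internal-internal edge
    all_labels = frozenset(labels)
    ref = min(all_labels)
    bps = set()
    for u in adj:
        for v in adj[u]:
            if u < v and not u.startswith("T") and not v.startswith("T"):
                # leaves reachable from v without crossing u
                seen = {u, v}
                stack = [v]
                side = set()
                while stack:
                    node = stack.pop()
                    if node.startswith("T"):
                        side.add(node)
                    for nb in adj[node]:
                        if nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
                side = frozenset(side)
                if ref in side:
                    side = all_labels - side
                if 2 <= len(side) <= n - 2:
                    bps.add(side)
    return bps, DistanceMatrix(taxa=taxa, d=d)


def tree_distances(njt: NJTree):
    """Leaf-to-leaf patristic distances of an NJ tree."""
    pdm = njt.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in njt.tree.taxon_namespace}
    labels = sorted(taxa)
    return {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for a, b in itertools.combinations(labels, 2)
    }


def topology_key(tree: dendropy.Tree):
    """Set of nontrivial bipartitions (as label frozensets)."""
    labels = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = labels - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = pdistance([("a", "ARND"), ("b", "ARND")])
        assert dm.d[0, 1] == 0.0

    def test_mismatch_over_comparable_columns(self):
        dm = pdistance([("a", "AR-ND"), ("b", "AK-ND")])
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            pdistance([("a", "AR--"), ("b", "--ND")])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            pdistance([("a", "ARND"), ("b", "ARN")])

    def test_poisson_correction(self):
        dm = pdistance([("a", "AAAA"), ("b", "AARR")], poisson_correct=True)
        assert dm.d[0, 1] == pytest.approx(-np.log(0.5))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        njt = neighbor_joining(DistanceMatrix(taxa=["A", "B", "C"], d=d))
        dist = tree_distances(njt)
        assert dist[("A", "B")] == pytest.approx(3.0)
        assert dist[("A", "C")] == pytest.approx(5.0)
        assert dist[("B", "C")] == pytest.approx(6.0)

    def test_four_taxon_additive_recovery(self):
        # additive matrix of ((A:2,B:3):3,(C:4,D:5):2)
        d = np.array(
            [
                [0, 5, 9, 10],
                [5, 0, 10, 11],
                [9, 10, 0, 9],
                [10, 11, 9, 0],
            ],
            dtype=float,
        )
        njt = neighbor_joining(DistanceMatrix(taxa=list("ABCD"), d=d))
        assert topology_key(njt.tree) == {frozenset({"C", "D"})}
        dist = tree_distances(njt)
        for (a, b), expected in {
            ("A", "B"): 5,
            ("A", "C"): 9,
            ("A", "D"): 10,
            ("B", "C"): 10,
            ("B", "D"): 11,
            ("C", "D"): 9,
        }.items():
            assert dist[(a, b)] == pytest.approx(expected)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(taxa=["A", "B"], d=np.array([[0, 1], [1, 0.0]]))
            )

    def test_consistency_on_random_additive_matrices(self, rng):
        """Exact topology and path-length recovery, random trees n<=8."""
        for trial in range(30):
            n = int(rng.integers(4, 9))
            true_bps, dm = random_additive_matrix(rng, n)
            njt = neighbor_joining(dm)
            assert topology_key(njt.tree) == true_bps
            dist = tree_distances(njt)
            labels = sorted(dm.taxa)
            for i, a in enumerate(labels):
                for j in range(i + 1, len(labels)):
                    b = labels[j]
                    assert dist[(a, b)] == pytest.approx(
                        dm.d[dm.taxa.index(a), dm.taxa.index(b)], abs=1e-8
                    )

    def test_total_length_invariant_to_relabeling(self, rng):
        _, dm = random_additive_matrix(rng, 6)
        njt = neighbor_joining(dm)
        perm = rng.permutation(len(dm.taxa))
        dm2 = DistanceMatrix(
            taxa=[dm.taxa[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
        )
        njt2 = neighbor_joining(dm2)
        assert njt.total_length() == pytest.approx(njt2.total_length())

    def test_ultrametric_five_taxa_vs_exhaustive_search(self):
        """NJ topology equals brute-force minimum evolution over all 15
        unrooted 5-taxon topologies (least-squares branch lengths)."""
        # ultrametric: ((A,B),(C,D)),E with heights 1,1,2,4
        labels = list("ABCDE")
        d = np.array(
            [
                [0, 2, 4, 4, 8],
                [2, 0, 4, 4, 8],
                [4, 4, 0, 2, 8],
                [4, 4, 2, 0, 8],
                [8, 8, 8, 8, 0],
            ],
            dtype=float,
        )
        njt = neighbor_joining(DistanceMatrix(taxa=labels, d=d))
        best = _brute_force_min_evolution(labels, d)
        assert topology_key(njt.tree) == best

    def test_agrees_with_skbio_reference(self, rng):
        """Independent cross-check against scikit-bio's NJ on random
        noisy matrices."""
        skbio = pytest.importorskip("skbio")
        for _ in range(10):
            _, dm = random_additive_matrix(rng, 6)
            noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            njt = neighbor_joining(DistanceMatrix(taxa=dm.taxa, d=noisy))
            sk_tree = skbio.tree.nj(
                skbio.DistanceMatrix(noisy, ids=dm.taxa)
            )
            sk_dendro = dendropy.Tree.get(
                data=str(sk_tree), schema="newick"
            )
            assert topology_key(njt.tree) == topology_key(sk_dendro)


def _brute_force_min_evolution(labels, d):
    """Enumerate all unrooted topologies on 5 taxa; return the bipartition
    set of the one minimizing total least-squares branch length."""
    from scipy.optimize import nnls

    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    best_len, best_top = np.inf, None
    # a 5-taxon unrooted binary tree = two cherries + one free taxon
    for cherry1 in itertools.combinations(range(n), 2):
        rest = [x for x in range(n) if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            if cherry1 > cherry2:
                continue
            free = [x for x in rest if x not in cherry2][0]
            # edges: 5 pendant + 2 internal
            splits = [frozenset([i]) for i in range(n)]
            splits.append(frozenset(cherry1))
            splits.append(frozenset(cherry2))
            A = np.zeros((len(pairs), len(splits)))
            y = np.array([d[i, j] for i, j in pairs])
            for r, (i, j) in enumerate(pairs):
                for c, s in enumerate(splits):
                    if (i in s) != (j in s):
                        A[r, c] = 1.0
            x, _ = nnls(A, y)
            total = x.sum()
            if total < best_len - 1e-9:
                best_len = total
                ref_label = min(labels)
                tops = set()
                for s in (frozenset(cherry1), frozenset(cherry2)):
                    side = frozenset(labels[i] for i in s)
                    if ref_label in side:
                        side = frozenset(labels) - side
                    tops.add(side)
                best_top = tops
    return best_top


class TestBootstrap:
    msa = [
        ("A", "MKVLWAALLV" * 4),
        ("B", "MKVLWAALLV" * 4),
        ("C", "MKILWGALLV" * 4),
        ("D", "MKILWGALLV" * 4),
        ("E", "QSVLWAPLLV" * 4),
    ]

    def test_identical_clades_get_full_support(self):
        njt = bootstrap(self.msa, n_reps=100, seed=5)
        assert njt.supports  # at least one internal edge
        # A,B identical and C,D identical: their cherries are certain
        for bp, s in njt.supports.items():
            if bp in ({"A", "B"}, {"C", "D"}, frozenset("AB"), frozenset("CD")):
                assert s == 100.0

    def test_same_seed_reproducible(self):
        s1 = bootstrap(self.msa, n_reps=60, seed=9).supports
        s2 = bootstrap(self.msa, n_reps=60, seed=9).supports
        assert s1 == s2

    def test_supports_bounded_and_order_invariant(self, rng):
        # all-distinct sequences -> no distance ties, so the topology
        # (and hence the supported bipartitions) must not depend on
        # taxon input order
        msa = [
            ("A", "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQ"),
            ("B", "MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRH"),
            ("C", "MKLLWAGLLVTFLAGCHAKVEQAVETEPEPELGQ"),
            ("D", "MRVLWTALLVAFLAGCQARVEQAVEPEPEPQLRQ"),
            ("E", "MRVLWTALLVAFLTGCQARVEQGVEPEPEPQLRT"),
        ]
        njt = bootstrap(msa, n_reps=50, seed=3)
        assert all(0.0 <= s <= 100.0 for s in njt.supports.values())
        shuffled = list(msa)
        rng.shuffle(shuffled)
        njt2 = bootstrap(shuffled, n_reps=50, seed=3)
        assert set(njt.supports) == set(njt2.supports)


class TestNewick:
    def test_round_trip(self, tmp_path, rng):
        _, dm = random_additive_matrix(rng, 6)
        njt = neighbor_joining(dm)
        p = tmp_path / "t.nwk"
        write_newick(njt, p)
        back = read_newick(p)
        assert topology_key(back) == topology_key(njt.tree)
        orig = tree_distances(njt)
        pdm = back.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in back.taxon_namespace}
        for (a, b), val in orig.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                val, abs=1e-9
            )
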