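import numpy as np
import pytest

from barcodekit import (
    SimulationParams,
    bootstrap_support,
    complete_deletion,
    is_monophyletic,
    neighbor_joining,
    pairwise_matrix,
    simulate_dataset,
)
from barcodekit.distances import DistanceMatrix
from barcodekit.njtree import TreeError
from barcodekit.seqio import SequenceRecord, build_alignment


def dm(ids, values):
    n = len(ids)
    return DistanceMatrix(
        ids=ids,
        values=np.asarray(values, dtype=float),
        overlaps=np.full((n, n), 100),
        model="p",
    )


def random_additive_matrix(n, rng):
    """Random binary tree with random branch lengths -> its path metric."""
    import collections

    adj = collections.defaultdict(list)
    pool = list(range(n))
    nxt = n
    while len(pool) > 1:
        a = pool.pop(rng.integers(0, len(pool)))
        b = pool.pop(rng.integers(0, len(pool)))
        for x in (a, b):
            w = float(rng.uniform(0.1, 2.0))
            adj[x].append((nxt, w))
            adj[nxt].append((x, w))
        pool.append(nxt)
        nxt += 1

    def path(u, v):
        stack = [(u, -1, 0.0)]
        while stack:
            x, p, acc = stack.pop()
            if x == v:
                return acc
            for y, w in adj[x]:
                if y != p:
                    stack.append((y, x, acc + w))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = path(i, j)
    return D


class TestCompleteDeletion:
    def test_gap_free_unchanged(self, small_dataset):
        aln, _ = small_dataset
        out = complete_deletion(aln)
        assert out.n_columns == aln.n_columns

    def test_single_gap_removes_column_for_all(self):
        aln = build_alignment(
            [
                SequenceRecord(id="a", residues="ACGTA"),
                SequenceRecord(id="b", residues="AC-TA"),
            ]
        )
        out = complete_deletion(aln)
        assert out.n_columns == 4
        assert out.records[0].residues == "ACTA"

    def test_matches_brute_force_column_scan(self):
        aln, _ = simulate_dataset(
            SimulationParams(
                n_species=4, individuals_per_species=2, n_columns=100,
                indel_column_rate=0.05, seed=8,
            )
        )
        out = complete_deletion(aln)
        expected = sum(
            all(r.residues[c] in "ACGT" for r in aln.records)
            for c in range(aln.n_columns)
        )
        assert out.n_columns == expected

    def test_all_columns_removed_errors(self):
        aln = build_alignment(
            [
                SequenceRecord(id="a", residues="-C"),
                SequenceRecord(id="b", residues="A-"),
            ]
        )
        with pytest.raises(TreeError):
            complete_deletion(aln)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        t = neighbor_joining(
            dm(["A", "B", "C"], [[0, 2, 4], [2, 0, 6], [4, 6, 0]])
        )
        assert t.path_length("A", "B") == pytest.approx(2)
        assert t.path_length("A", "C") == pytest.approx(4)
        assert t.path_length("B", "C") == pytest.approx(6)

    def test_four_taxon_additive_topology_and_lengths(self):
        # additive: AB|CD with leaf branches 1,2,3,4 and internal branch 1
        D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        # four-point condition: verify additivity before building
        assert D[0][1] + D[2][3] <= D[0][2] + D[1][3] == D[0][3] + D[1][2]
        t = neighbor_joining(dm(["A", "B", "C", "D"], D))
        assert {frozenset(bp) for bp in t.bipartitions()} == {
            frozenset({"C", "D"})
        }
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert t.path_length(a, b) == pytest.approx(D[i][j])

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = 6
            D = random_additive_matrix(n, rng)
            ids = [f"t{i}" for i in range(n)]
            t = neighbor_joining(dm(ids, D))
            for i in range(n):
                for j in range(i + 1, n):
                    assert t.path_length(ids[i], ids[j]) == pytest.approx(
                        D[i, j], abs=1e-8
                    )

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(2)
        n = 8
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"t{i}" for i in range(n)]
        t1 = neighbor_joining(dm(ids, D))
        perm = list(rng.permutation(n))
        t2 = neighbor_joining(
            dm([ids[i] for i in perm], D[np.ix_(perm, perm)])
        )
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        for i in range(n):
            for j in range(i + 1, n):
                assert t1.path_length(ids[i], ids[j]) == pytest.approx(
                    t2.path_length(ids[i], ids[j]), abs=1e-9
                )

    def test_matches_independent_nj_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        n = 7
        D = random_additive_matrix(n, rng)
        D += rng.normal(0, 0.01, D.shape) ** 2  # slight non-additive noise
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(dm(ids, D))
        other = skbio_nj(SkDM(D, ids))
        leaves = set(ids)
        anchor = min(leaves)
        other_bps = set()
        for node in other.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= n - 2:
                other_bps.add(side)
        assert set(mine.bipartitions()) == other_bps

    def test_undefined_distance_errors(self):
        D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(TreeError, match="complete_deletion"):
            neighbor_joining(dm(["A", "B", "C"], D))

    def test_newick_is_parseable(self):
        import dendropy

        t = neighbor_joining(
            dm(["A", "B", "C", "D"],
               [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
        )
        parsed = dendropy.Tree.get(data=t.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "A", "B", "C", "D"
        }


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, small_dataset):
        aln, _ = small_dataset
        t1 = bootstrap_support(aln, replicates=10, seed=3, min_overlap=1)
        t2 = bootstrap_support(aln, replicates=10, seed=3, min_overlap=1)
        s1 = {bp: e.support for bp, e in t1.bipartitions().items()}
        s2 = {bp: e.support for bp, e in t2.bipartitions().items()}
        assert s1 == s2

    def test_supports_bounded(self, small_dataset):
        aln, _ = small_dataset
        t = bootstrap_support(aln, replicates=20, seed=1, min_overlap=1)
        sup = [e.support for e in t.bipartitions().values()]
        assert sup and all(0 <= s <= 100 for s in sup)

    def test_separated_clades_get_high_support(self):
        aln, truth = simulate_dataset(
            SimulationParams(
                n_species=4, individuals_per_species=3, n_columns=500,
                intra_divergence=0.001, inter_divergence=0.1,
                indel_column_rate=0.0, seed=13,
            )
        )
        tree = bootstrap_support(aln, replicates=100, seed=7, min_overlap=1)
        leaves = tree.leaves
        anchor = min(leaves)
        bps = tree.bipartitions()
        for sp in sorted(set(truth.label_map.values())):
            ids = frozenset(i for i, s in truth.label_map.items() if s == sp)
            assert is_monophyletic(tree, set(ids))
            canon = ids if anchor not in ids else frozenset(leaves - ids)
            assert bps[canon].support >= 95


class TestMonophyly:
    @pytest.fixture(scope="class")
    def tree(self, small_dataset):
        aln, _ = small_dataset
        return neighbor_joining(pairwise_matrix(aln, min_overlap=1))

    def test_all_leaves_true(self, tree):
        assert is_monophyletic(tree, tree.leaves)

    def test_single_leaf_true(self, tree):
        assert is_monophyletic(tree, {next(iter(tree.leaves))})

    def test_species_clades_true_mixed_sets_false(self, tree, small_dataset):
        _, truth = small_dataset
        species = sorted(set(truth.label_map.values()))
        by_sp = {
            sp: {i for i, s in truth.label_map.items() if s == sp}
            for sp in species
        }
        for sp in species:
            assert is_monophyletic(tree, by_sp[sp])
        # one individual from each of two species is not a clade
        mixed = {next(iter(by_sp[species[0]])), next(iter(by_sp[species[1]]))}
        assert not is_monophyletic(tree, mixed)

    def test_unknown_id_errors(self, tree):
        with pytest.raises(TreeError):
            is_monophyletic(tree, {"not-a-leaf"})
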