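"""Distances, neighbor joining (vs enumeration oracle and skbio),
bootstrap supports and Newick round-trips."""

import itertools
import math

import numpy as np
import pytest

from phagesig import (
    GenomeRecord,
    bootstrap_support,
    evolve_genome,
    jc_distance,
    neighbor_joining,
    pairwise_p,
    read_newick,
    reference_anchored_alignment,
    write_newick,
)
from phagesig.phylo import bipartitions, distance_matrix


# ---------------------------------------------------------------------------
# oracle: enumerate all unrooted topologies + least-squares branch fit
# ---------------------------------------------------------------------------

def all_topologies(labels):
    """All unrooted binary topologies as nested tuples (start from a
    3-star, insert each further taxon on every edge)."""
    if len(labels) == 3:
        return [tuple(labels)]
    trees = []
    for sub in all_topologies(labels[:-1]):
        for t in _insert_everywhere(sub, labels[-1]):
            trees.append(t)
    return trees


def _insert_everywhere(tree, leaf):
    # tree is a tuple of 3 subtrees (unrooted); insertion on any edge
    out = []
    for i, child in enumerate(tree):
        for new_child in _insert_into(child, leaf):
            out.append(tuple(new_child if j == i else c
                             for j, c in enumerate(tree)))
    return out

def _insert_into(node, leaf):
    yield (node, leaf)
    if isinstance(node, tuple):
        for i, child in enumerate(node):
            for sub in _insert_into(child, leaf):
                yield tuple(sub if j == i else c
                            for j, c in enumerate(node))


def topology_splits(tree, all_labels):
    def leaves(n):
        if isinstance(n, tuple):
            return frozenset().union(*(leaves(c) for c in n))
        return frozenset([n])
    splits = set()
    def walk(n):
        if isinstance(n, tuple):
            for c in n:
                side = leaves(c)
                if 1 < len(side) < len(all_labels) - 1:
                    other = frozenset(all_labels) - side
                    splits.add(min(side, other,
                                   key=lambda s: (len(s), sorted(s))))
                walk(c)
    walk(tree)
    return splits


def edges_of(tree):
    """Edges as (frozenset-of-leaves-below, edge index) incidence rows."""
    edges = []
    def leaves(n):
        if isinstance(n, tuple):
            return frozenset().union(*(leaves(c) for c in n))
        return frozenset([n])
    def walk(n):
        if isinstance(n, tuple):
            for c in n:
                edges.append(leaves(c))
                walk(c)
    walk(tree)
    return edges


def least_squares_fit(tree, labels, d):
    edges = edges_of(tree)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, below in enumerate(edges):
            # edge on the path iff it separates i from j
            if (labels[i] in below) != (labels[j] in below):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(((A @ x - y) ** 2).sum())
    return resid


def random_additive_matrix(labels, rng):
    """Distances from a random unrooted topology with random lengths."""
    topos = all_topologies(labels)
    tree = topos[rng.integers(0, len(topos))]
    edges = edges_of(tree)
    lens = rng.uniform(0.05, 1.0, size=len(edges))
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist = sum(l for below, l in zip(edges, lens)
                   if (labels[i] in below) != (labels[j] in below))
        d[i, j] = d[j, i] = dist
    return d, tree


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestJukesCantor:
    def test_closed_form_spot_checks(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.3) == pytest.approx(0.383119, abs=1e-6)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            jc_distance(0.75)

    def test_strictly_increasing_and_convex(self):
        ps = np.linspace(0.0, 0.74, 100)
        ds = [jc_distance(p) for p in ps]
        diffs = np.diff(ds)
        assert (diffs > 0).all()
        assert (np.diff(diffs) > 0).all()

    def test_pairwise_p(self):
        assert pairwise_p("ACGT", "ACGT") == 0.0
        assert pairwise_p("ACGT", "ACGA") == 0.25
        assert pairwise_p("A-GT", "A-GA") == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            pairwise_p("--", "--")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(labels, d)
        for a, b in itertools.combinations(labels, 2):
            i, j = labels.index(a), labels.index(b)
            assert tree.find(a).distance(tree.find(b)) == \
                pytest.approx(d[i, j], abs=1e-9)
        assert bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = neighbor_joining(labels, d)
        la = tree.find("A").length
        lb = tree.find("B").length
        lc = tree.find("C").length
        assert la == pytest.approx(0.5 * (2 + 3 - 4))
        assert lb == pytest.approx(0.5 * (2 + 4 - 3))
        assert lc == pytest.approx(0.5 * (3 + 4 - 2))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["A", "B"], np.zeros((2, 2)))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_vs_enumeration_oracle(self, n):
        labels = [chr(65 + i) for i in range(n)]
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d, true_tree = random_additive_matrix(labels, rng)
            tree = neighbor_joining(labels, d)
            # path lengths reproduce the matrix exactly
            for i, j in itertools.combinations(range(n), 2):
                assert tree.find(labels[i]).distance(
                    tree.find(labels[j])) == pytest.approx(d[i, j], abs=1e-9)
            # topology equals the best least-squares topology
            assert bipartitions(tree) == topology_splits(true_tree, labels)
            best = min(all_topologies(labels),
                       key=lambda t: least_squares_fit(t, labels, d))
            assert topology_splits(best, labels) == bipartitions(tree)

    def test_matches_skbio_on_random_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        labels = list("ABCDEF")
        rng = np.random.default_rng(17)
        d, _ = random_additive_matrix(labels, rng)
        ours = neighbor_joining(labels, d)
        theirs = skbio_nj(DistanceMatrix(d, labels))
        assert bipartitions(ours) == bipartitions(theirs)

    def test_equal_distances_deterministic(self):
        labels = list("ABCD")
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(labels, d)
        t2 = neighbor_joining(labels, d)
        assert str(t1) == str(t2)
        for node in t1.traverse():
            if node.length is not None:
                assert node.length >= 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _clade_alignment(seed=4, length=2000):
    from phagesig import simulate_sequences_on_tree
    rng = np.random.default_rng(0)
    root = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
    tree = ("(((A:0.01,B:0.01):0.04,C:0.05):0.15,"
            "((D:0.01,E:0.01):0.04,F:0.05):0.15);")
    return simulate_sequences_on_tree(root, tree, seed=seed)


class TestBootstrap:
    def test_well_separated_clades_high_support(self):
        aln = _clade_alignment()
        tree = bootstrap_support(aln, n_replicates=100, seed=1)
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert supports and all(s >= 95 for s in supports)

    def test_identical_sequences_star_without_supports(self):
        aln = {lbl: "ACGTACGTAC" for lbl in "ABCD"}
        tree = bootstrap_support(aln, n_replicates=10, seed=2)
        assert {t.name for t in tree.tips()} == set("ABCD")
        assert all(n.name is None for n in tree.non_tips(include_self=False))

    def test_same_seed_identical_supports(self):
        aln = _clade_alignment()
        t1 = bootstrap_support(aln, 50, seed=3)
        t2 = bootstrap_support(aln, 50, seed=3)
        assert str(t1) == str(t2)

    def test_leaf_order_permutation_invariant(self):
        aln = _clade_alignment()
        rev = dict(reversed(list(aln.items())))
        def sup(tree):
            out = {}
            leaves = frozenset(aln)
            for n in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in n.tips())
                key = min(side, leaves - side,
                          key=lambda s: (len(s), sorted(s)))
                out[key] = n.name
            return out
        assert sup(bootstrap_support(aln, 50, seed=5)) == \
            sup(bootstrap_support(rev, 50, seed=5))


# ---------------------------------------------------------------------------
# Newick and anchored alignment
# ---------------------------------------------------------------------------

class TestNewick:
    def test_round_trip(self, tmp_path):
        aln = _clade_alignment()
        tree = bootstrap_support(aln, 20, seed=6)
        p = write_newick(tree, tmp_path / "t.nwk")
        back = read_newick(p)
        assert {t.name for t in back.tips()} == set(aln)
        assert bipartitions(back) == bipartitions(tree)

    def test_parse_structure(self, tmp_path):
        p = tmp_path / "s.nwk"
        p.write_text("(A:1,B:2,(C:3,D:4):5);\n")
        tree = read_newick(p)
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C", "D"]


class TestAnchoredAlignment:
    def test_rows_share_reference_length(self, small_parts):
        ref, relatives, _, _ = small_parts
        aln = reference_anchored_alignment([ref] + relatives, ref)
        assert all(len(row) == len(ref.seq) for row in aln.values())

    def test_distances_recover_planted_divergence(self, big_reference):
        _, ref = big_reference
        genomes = [ref] + [evolve_genome(ref, d, seed=s, record_id=f"g{d}")
                           for s, d in ((1, 0.01), (2, 0.05))]
        aln = reference_anchored_alignment(genomes, ref)
        labels, dm = distance_matrix(aln)
        for gid, d_true in (("g0.01", 0.01), ("g0.05", 0.05)):
            i, j = labels.index(ref.id), labels.index(gid)
            d_jc = -0.75 * math.log(1 - 4 * d_true / 3)
            assert dm[i, j] == pytest.approx(d_jc, rel=0.15)
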