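"""Jukes–Cantor distances, neighbor joining, bootstrap, Newick I/O.

Distances use the one-parameter Jukes–Cantor correction

    d = -(3/4) · ln(1 - (4/3)·p)

of the observed proportion p of differing sites, with pairwise deletion
of gap columns.  Tree building is the Saitou–Nei neighbor-joining
algorithm with the Studier–Keppler Q-criterion, deterministic
tie-breaking by smallest label pair, and negative branch lengths clamped
to zero.  On additive matrices the reconstruction is exact.  Bootstrap
support resamples alignment columns with replacement and reports, for
each internal edge of the original tree, the percentage of replicate
trees containing the same bipartition.

Trees are scikit-bio ``TreeNode`` objects; supports are serialized as
internal node labels in Newick.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

import edlib


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jc_distance(p: float) -> float:
    """Jukes–Cantor distance for observed difference proportion p."""
    if not 0.0 <= p:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        raise ValueError(f"p = {p} is at or beyond JC saturation (0.75)")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def pairwise_p(a: str, b: str) -> float:
    """Observed difference proportion with pairwise deletion of gaps."""
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    used = diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        used += 1
        if x != y:
            diff += 1
    if used == 0:
        raise ValueError("no ungapped columns shared by the pair")
    return diff / used


def distance_matrix(alignment: Mapping[str, str]
                    ) -> tuple[list[str], np.ndarray]:
    """JC distance matrix from a multiple alignment (label -> row)."""
    labels = list(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(
                pairwise_p(alignment[labels[i]], alignment[labels[j]]))
    return labels, d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(labels: Sequence[str], d: np.ndarray) -> TreeNode:
    """Saitou–Nei NJ; exact on additive matrices, deterministic ties.

    Returns an unrooted tree represented with a trifurcating root.
    Negative branch-length estimates are clamped to zero.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(d, dtype=float).copy()
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.diag(d).any():
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]
    names = list(labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # smallest (name_i, name_j) pair among the minimizers
        cand = [(min(names[i], names[j]), max(names[i], names[j]), i, j)
                for i, j in zip(*np.nonzero(np.isclose(q, qmin)))
                if i < j]
        _, _, i, j = min(cand)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        d = new_d
        nodes = [nodes[x] for x in keep] + [parent]
        names = [names[x] for x in keep] + [min(names[i], names[j])]

    a, b, c = nodes
    la = max(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]), 0.0)
    lb = max(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]), 0.0)
    lc = max(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]), 0.0)
    a.length, b.length, c.length = la, lb, lc
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# bipartitions and bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each as its smaller-side set
    (canonicalized against the full leaf set)."""
    leaves = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(alignment: Mapping[str, str],
                      n_replicates: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate alignment is rebuilt into a JC distance matrix and NJ
    tree, and support is the percentage of replicates whose tree
    contains the original internal bipartition.  An alignment of
    identical sequences degenerates to an unresolved star with no
    supports.
    """
    labels = list(alignment)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    ncols = len(next(iter(alignment.values())))
    if ncols < 1:
        raise ValueError("empty alignment")
    _, d = distance_matrix(alignment)
    if not d.any():
        star = TreeNode(children=[TreeNode(name=l, length=0.0)
                                  for l in labels])
        return star
    tree = neighbor_joining(labels, d)
    original = bipartitions(tree)
    counts = {part: 0 for part in original}
    rng = np.random.default_rng(seed)
    rows = {lbl: np.frombuffer(alignment[lbl].encode(), dtype=np.uint8)
            for lbl in labels}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep = {lbl: rows[lbl][cols].tobytes().decode() for lbl in labels}
        try:
            rep_labels, rep_d = distance_matrix(rep)
            if not rep_d.any():
                continue
            rep_parts = bipartitions(neighbor_joining(rep_labels, rep_d))
        except ValueError:     # e.g. a saturated replicate
            continue
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    leaves = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        if key in counts:
            node.name = str(round(100.0 * counts[key] / n_replicates))
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> Path:
    """Write Newick with 6-decimal branch lengths; supports are the
    internal node labels already set on the tree."""
    path = Path(path)
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(float(node.length), 6)
    tree.write(str(path), format="newick")
    return path


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# reference-anchored alignment of near-identical genomes
# ---------------------------------------------------------------------------

def reference_anchored_alignment(genomes: Sequence, reference
                                 ) -> dict[str, str]:
    """Project each genome onto reference columns via pairwise alignment.

    Every genome is globally aligned to the reference; bases are placed
    in the reference's coordinate columns, with '-' where the genome has
    a deletion.  Insertions relative to the reference are dropped, so
    all rows share the reference's length.  At the >99% identities of a
    tight genus this column mapping is equivalent to a full multiple
    alignment for distance purposes.
    """
    ref_seq = reference.seq
    out = {reference.id: ref_seq}
    for g in genomes:
        if g.id == reference.id:
            continue
        res = edlib.align(g.seq, ref_seq, mode="NW", task="path")
        row = []
        qi = 0
        import re as _re
        for n, op in ((int(x), o) for x, o in
                      _re.findall(r"(\d+)([=XID])", res["cigar"])):
            if op in "=X":
                row.append(g.seq[qi:qi + n])
                qi += n
            elif op == "I":            # extra bases in genome: dropped
                qi += n
            else:                      # deletion vs reference
                row.append("-" * n)
        out[g.id] = "".join(row)
    return out
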