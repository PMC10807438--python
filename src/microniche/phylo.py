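"""Tajima-Nei distances, neighbor-joining, and patristic distances.

The Tajima-Nei (1984) estimator corrects the raw proportion of differing
sites for unequal base composition:

    d = -b ln(1 - p / b)

with p the proportion of differing comparable sites and

    b = (1 - sum_i g_i^2 + p^2 / h) / 2,
    h = sum_{i<j} x_ij^2 / (2 g_i g_j),

where g_i are the base frequencies pooled over both sequences and x_ij the
per-site frequencies of each unordered mismatching base pair.  With equal
base frequencies and a uniform mismatch spectrum b reduces to 3/4 and d to
the Jukes-Cantor form.  Saturated pairs (p >= b) have no finite estimate
and are flagged NaN.

Neighbor joining follows the Saitou-Nei agglomeration with the standard
Q-criterion, a deterministic lexicographic tie-break, and negative branch
lengths clamped to zero with the excess moved to the sibling branch so the
joined pair's distance is preserved.
"""

from __future__ import annotations

import io
import itertools
import math

import numpy as np
import pandas as pd
from Bio import Phylo

_VALID = frozenset("ACGT")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _comparable(seq1: str, seq2: str) -> tuple[np.ndarray, np.ndarray]:
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    s1 = np.frombuffer(seq1.upper().encode(), dtype="S1")
    s2 = np.frombuffer(seq2.upper().encode(), dtype="S1")
    valid = np.array([c.encode() for c in _VALID])
    keep = np.isin(s1, valid) & np.isin(s2, valid)
    return s1[keep], s2[keep]


def tajima_nei(seq1: str, seq2: str) -> float:
    """Tajima-Nei distance between two aligned sequences.

    Sites where either sequence has a gap or ambiguity code are deleted
    pairwise.  Returns NaN when the estimator is undefined (saturation,
    p >= b); raises if no comparable sites remain.
    """
    s1, s2 = _comparable(seq1, seq2)
    n = s1.size
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    diff = s1 != s2
    p = diff.sum() / n
    if p == 0.0:
        return 0.0

    codes1 = np.char.decode(s1, "ascii")
    codes2 = np.char.decode(s2, "ascii")
    g = np.zeros(4)
    for arr in (codes1, codes2):
        for base, idx in _BASE_INDEX.items():
            g[idx] += np.count_nonzero(arr == base)
    g /= 2.0 * n

    # unordered mismatch-pair frequencies x_ij
    h = 0.0
    for (b1, i1), (b2, i2) in itertools.combinations(_BASE_INDEX.items(), 2):
        x = (
            np.count_nonzero((codes1 == b1) & (codes2 == b2))
            + np.count_nonzero((codes1 == b2) & (codes2 == b1))
        ) / n
        if x:
            h += x * x / (2.0 * g[i1] * g[i2])
    b = 0.5 * (1.0 - float(g @ g) + p * p / h)
    if p >= b:
        return float("nan")
    return -b * math.log(1.0 - p / b)


def tajima_nei_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """All-pairs Tajima-Nei distances (NaN marks saturated pairs)."""
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tajima_nei(sequences[ids[i]], sequences[ids[j]])
    return pd.DataFrame(mat, index=ids, columns=ids)


def _check_distance_matrix(d: pd.DataFrame) -> None:
    if d.shape[0] != d.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    vals = d.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("distance matrix contains undefined (non-finite) cells")
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")


def _fmt(x: float) -> str:
    return format(max(x, 0.0), ".17g")


def neighbor_joining(d: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick text) from a distance matrix.

    Agglomerates by the Q-criterion Q_ij = (n-2) d_ij - r_i - r_j; ties are
    broken by the lexicographically smallest taxon-pair (each cluster is
    represented by its smallest member label).  The two final joins leave a
    trifurcating root, the conventional unrooted NJ output.  Negative
    branch-length estimates are clamped to zero and the excess moved to the
    sibling so the pair's joined distance is preserved.
    """
    _check_distance_matrix(d)
    n0 = len(d.index)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least three taxa")

    dist: dict[frozenset, float] = {}
    labels = list(d.index.astype(str))
    for i, j in itertools.combinations(range(n0), 2):
        dist[frozenset((labels[i], labels[j]))] = float(d.iat[i, j])
    # node key -> (newick subtree, representative label for tie-breaks)
    nodes: dict[str, tuple[str, str]] = {lab: (lab, lab) for lab in labels}
    if len(nodes) != n0:
        raise ValueError("duplicate taxon labels")

    while len(nodes) > 3:
        active = sorted(nodes, key=lambda k: nodes[k][1])
        n = len(active)
        r = {
            k: sum(dist[frozenset((k, m))] for m in active if m != k)
            for k in active
        }
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
            key = (q, tuple(sorted((nodes[a][1], nodes[b][1]))))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la = 0.5 * d_ab + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d_ab - la
        if la < 0.0:
            lb += la
            la = 0.0
        if lb < 0.0:
            la += lb
            lb = 0.0
        new_rep = min(nodes[a][1], nodes[b][1])
        new_key = f"__u{len(nodes)}_{new_rep}"
        newick = f"({nodes[a][0]}:{_fmt(la)},{nodes[b][0]}:{_fmt(lb)})"
        for k in active:
            if k in (a, b):
                continue
            dist[frozenset((new_key, k))] = 0.5 * (
                dist[frozenset((a, k))] + dist[frozenset((b, k))] - d_ab
            )
        for k in active:
            dist.pop(frozenset((a, k)), None)
            dist.pop(frozenset((b, k)), None)
        del nodes[a], nodes[b]
        nodes[new_key] = (newick, new_rep)

    (a, b, c) = sorted(nodes, key=lambda k: nodes[k][1])
    d_ab = dist[frozenset((a, b))]
    d_ac = dist[frozenset((a, c))]
    d_bc = dist[frozenset((b, c))]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    return (
        f"({nodes[a][0]}:{_fmt(la)},{nodes[b][0]}:{_fmt(lb)},"
        f"{nodes[c][0]}:{_fmt(lc)});"
    )


def patristic(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path-length (patristic) distance matrix of a tree.

    Branch lengths must be present on every branch below the root; a
    missing length raises.
    """
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = tree.get_terminals()
    names = [leaf.name for leaf in leaves]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names")
    for clade in tree.find_clades():
        if clade is tree.root:
            if clade.branch_length is None:
                clade.branch_length = 0.0
            continue
        if clade.branch_length is None:
            # a rootward child without a length is conventionally zero
            # (unrooted trees written with a bifurcating root)
            if clade in tree.root.clades:
                clade.branch_length = 0.0
            else:
                raise ValueError("tree has branches without lengths")

    # depth of every clade from the root, then d(u,v) = depth(u) + depth(v)
    # - 2 depth(lca)
    depths = tree.depths()
    n = len(leaves)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lca = tree.common_ancestor(leaves[i], leaves[j])
            dij = depths[leaves[i]] + depths[leaves[j]] - 2.0 * depths[lca]
            mat[i, j] = mat[j, i] = dij
    order = np.argsort(names)
    names_sorted = [names[k] for k in order]
    return pd.DataFrame(mat[np.ix_(order, order)],
                        index=names_sorted, columns=names_sorted)


def nj_patristic(d: pd.DataFrame) -> pd.DataFrame:
    """Patristic distances of the NJ tree built from ``d`` — the default
    "phylogenetic distance" handed to the interaction regressions."""
    return patristic(neighbor_joining(d))
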