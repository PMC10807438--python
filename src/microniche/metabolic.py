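"""Functional (metabolic-network) similarity and distance.

Strains are summarised by the metabolite-node sets of their inferred
metabolic networks.  Functional similarity of a pair is the node overlap
divided by the arithmetic mean of the two node counts,

    similarity(A, B) = |A ∩ B| / ((|A| + |B|) / 2)

and functional distance is one minus that.  The mean denominator (not the
minimum) matters when one network nests inside a larger one.  The distance
lies in [0, 1], is symmetric with zero diagonal, but is not guaranteed to
satisfy the triangle inequality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def functional_similarity(a: set, b: set) -> float:
    if not a or not b:
        raise ValueError("node sets must be nonempty")
    return len(set(a) & set(b)) / ((len(a) + len(b)) / 2.0)


def functional_distance(a: set, b: set) -> float:
    return 1.0 - functional_similarity(a, b)


def functional_distance_matrix(node_sets: dict[str, set]) -> pd.DataFrame:
    """All-pairs functional distance as a square symmetric frame with zero
    diagonal, strains ordered by id."""
    ids = sorted(node_sets)
    if len(ids) < 2:
        raise ValueError("need at least two strains")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = functional_distance(node_sets[ids[i]], node_sets[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)
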