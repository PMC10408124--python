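"""Domain phylogenies and the genus-vs-serogroup clustering pattern.

The central biological claim operationalized here: neighbor-joining trees
of the N-terminal anchors cluster by phage genus while trees of the
C-terminal RBDs cluster by host serogroup — the signature of receptor-
binding domains travelling horizontally across genera.

Distances are ``1 - identity/100`` from pairwise global-alignment identity
matrices.  Clustering agreement is quantified as nearest-neighbor label
concordance, a deterministic statistic that needs no clade-extraction
convention: the fraction of taxa whose nearest neighbor carries the same
label, singleton labels excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np


class PhyloError(ValueError):
    """Raised for invalid distance matrices or label sets."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distances in [0, 1] with a zero diagonal."""

    ids: Tuple[str, ...]
    data: np.ndarray
    region: str = "full"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise PhyloError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise PhyloError("distance matrix diagonal is not zero")
        if np.any(self.data < -1e-12):
            raise PhyloError("negative distances")


def distances_from_identity(
    ids: Sequence[str], identity: np.ndarray, region: str = "full"
) -> DistanceMatrix:
    """Map a percent-identity matrix to distances d = 1 - identity/100."""
    return DistanceMatrix(tuple(ids), 1.0 - np.asarray(identity, float) / 100.0,
                          region)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string with the input ids as leaves.

    Standard Saitou-Nei agglomeration; negative branch lengths are clamped
    to zero with the deficit moved to the sister branch (the pair sum is
    preserved).  Ties in the Q-criterion break on the smaller (i, j) index
    pair, making the tree invariant to taxon order up to relabeling.
    """
    n = len(dm.ids)
    if n < 2:
        raise PhyloError("nj_tree needs >= 2 taxa")
    # leaf labels are quoted so underscores survive Newick parsing
    leaves = [f"'{name}'" for name in dm.ids]
    if n == 2:
        d = float(dm.data[0, 1])
        return f"({leaves[0]}:{d / 2:.6f},{leaves[1]}:{d / 2:.6f});"

    # active nodes as (newick fragment) with a working copy of distances
    labels: List[str] = leaves
    mat = dm.data.astype(float).copy()

    while len(labels) > 2:
        m = len(labels)
        totals = mat.sum(axis=1)
        q = (m - 2) * mat - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        dij = mat[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj, li = lj + li, 0.0
        if lj < 0.0:
            li, lj = li + lj, 0.0
        merged = f"({labels[i]}:{li:.6f},{labels[j]}:{lj:.6f})"

        dnew = 0.5 * (mat[i, :] + mat[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = dnew[keep]
        mat = new_mat
        labels = [labels[k] for k in keep] + [merged]

    d = max(float(mat[0, 1]), 0.0)
    return f"({labels[0]}:{d:.6f},{labels[1]}:0.000000);"


def label_concordance(dm: DistanceMatrix, labels: Mapping[str, str]) -> float:
    """Fraction of taxa whose nearest neighbor shares their label.

    Nearest neighbor = smallest off-diagonal distance, ties broken by
    lexicographically smallest taxon id.  Taxa whose label occurs only
    once are excluded from the denominator; if every label is a
    singleton the statistic is undefined and an error is raised.
    """
    missing = [t for t in dm.ids if t not in labels]
    if missing:
        raise PhyloError(f"unlabeled taxa: {missing}")
    counts: Dict[str, int] = {}
    for t in dm.ids:
        counts[labels[t]] = counts.get(labels[t], 0) + 1
    evaluable = [t for t in dm.ids if counts[labels[t]] >= 2]
    if not evaluable:
        raise PhyloError("all labels are singletons; concordance undefined")

    idx = {t: k for k, t in enumerate(dm.ids)}
    agree = 0
    for t in evaluable:
        row = dm.data[idx[t]]
        best = None
        for other in sorted(dm.ids):
            if other == t:
                continue
            d = row[idx[other]]
            if best is None or d < best[0] - 1e-15:
                best = (d, other)
        assert best is not None
        if labels[best[1]] == labels[t]:
            agree += 1
    return agree / len(evaluable)
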