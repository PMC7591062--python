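"""Family-relationship tree from consensus-monomer distances.

Monomers of different families have arbitrary phase and very different
lengths (21-170 bp), where a global multiple alignment is ill-posed; pairwise
distances therefore come from a best circular-rotation, free-end-gap
substitution alignment of the shorter consensus against the longer
(distance = mismatches / aligned columns).  The tree is estimated with
neighbor joining (the standard agglomerative minimum-evolution estimator),
with deterministic label-order tie-breaking and negative branch lengths
clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .families import best_rotation_identity

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    def to_tsv(self, path, phylip: bool = False) -> None:
        with open(path, "w") as fh:
            if phylip:
                fh.write(f"{len(self.labels)}\n")
                for lab, row in zip(self.labels, self.values):
                    fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
            else:
                fh.write("\t" + "\t".join(self.labels) + "\n")
                for lab, row in zip(self.labels, self.values):
                    fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def pairwise_distance(consensi: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """p-distance matrix over consensus monomers.

    For each pair the shorter sequence is circularly rotated and slid over
    the longer with free end gaps; distance = mismatches / aligned columns
    (the shorter length) at the best alignment.
    """
    labels = [lab for lab, _ in consensi]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = best_rotation_identity(consensi[i][1], consensi[j][1])
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(labels, d)


class _Node:
    __slots__ = ("label", "children", "min_leaf")

    def __init__(self, label=None, children=None, min_leaf=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)
        self.min_leaf = min_leaf if min_leaf is not None else label

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def _clamp(x: float) -> float:
    if x < 0:
        logger.info("negative branch length %.4g clamped to 0", x)
        return 0.0
    return x


def build_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string (unrooted; trifurcating root).

    Q-criterion ties are broken by the smallest leaf label of each cluster so
    the topology is deterministic.  Matrices with fewer than 3 taxa give the
    trivial edge/leaf tree.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return f"{labels[0]};"
    if n == 2:
        h = matrix.values[0, 1] / 2
        return f"({labels[0]}:{h:.6f},{labels[1]}:{h:.6f});"

    nodes = [_Node(label=lab) for lab in labels]
    D = matrix.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                key = (
                    q,
                    *sorted(
                        (nodes[active[ai]].min_leaf, nodes[active[aj]].min_leaf)
                    ),
                )
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = _clamp(dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2)))
        lj = _clamp(dij / 2 + (r[aj] - r[ai]) / (2 * (m - 2)))
        new = _Node(
            children=[(nodes[i], li), (nodes[j], lj)],
            min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        # distances from the new node to the remaining clusters
        knew = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in range(m):
            if ak in (ai, aj):
                continue
            k = active[ak]
            D[knew, k] = D[k, knew] = (D[i, k] + D[j, k] - dij) / 2
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [knew]

    # final three-way join with the closed-form three-point branch lengths
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = _clamp((dab + dac - dbc) / 2)
    lb = _clamp((dab + dbc - dac) / 2)
    lc = _clamp((dac + dbc - dab) / 2)
    parts = ",".join(
        f"{nodes[k].newick()}:{bl:.6f}" for k, bl in ((a, la), (b, lb), (c, lc))
    )
    return f"({parts});"
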