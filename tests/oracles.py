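"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (plain loops, exhaustive enumeration)
and shares no code with the package's optimized paths.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_find_positions(seq: str, pattern: str) -> list[int]:
    """Quadratic exact search; N in the sequence never matches A/C/G/T."""
    out = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] == pattern[j] for j in range(len(pattern))):
            out.append(i)
    return out


def naive_period_candidates(
    seq: str, max_period: int, floor: float = 0.6, tol: float = 0.03
) -> list[tuple[int, float]]:
    """Plain-python period ranking: identity autocorrelation, local maxima
    above the floor, harmonics suppressed in favor of the fundamental."""
    n = len(seq)
    mp = min(max_period, n // 2)
    scores = {}
    for p in range(1, mp + 1):
        matches = sum(1 for i in range(n - p) if seq[i] == seq[i + p])
        scores[p] = matches / (n - p)
    cands = []
    for p in range(1, mp + 1):
        s = scores[p]
        if s < floor:
            continue
        if s >= scores.get(p - 1, -1) and s >= scores.get(p + 1, -1):
            cands.append(p)
    kept = []
    for p in cands:
        if any(p % q == 0 and scores[p] - scores[q] <= tol for q in kept):
            continue
        kept.append(p)
    return sorted(((p, scores[p]) for p in kept), key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# tree oracles: unrooted topology enumeration + OLS branch fitting


def enumerate_topologies(taxa: list[str]):
    """All unrooted binary topologies, as frozensets of bipartitions
    (each bipartition = frozenset of the smaller side's taxa)."""
    # represent a tree as edge list over nodes; grow by attaching each new
    # leaf to every existing edge
    def grow(edges, next_internal, leaves_left):
        if not leaves_left:
            yield edges
            return
        leaf = leaves_left[0]
        for idx in range(len(edges)):
            a, b = edges[idx]
            mid = f"_i{next_internal}"
            new_edges = edges[:idx] + edges[idx + 1 :] + [
                (a, mid),
                (mid, b),
                (mid, leaf),
            ]
            yield from grow(new_edges, next_internal + 1, leaves_left[1:])

    if len(taxa) < 4:
        raise ValueError("topology enumeration needs >= 4 taxa")
    start = [(taxa[0], "_i0"), (taxa[1], "_i0"), (taxa[2], "_i0")]
    yield from grow(start, 1, list(taxa[3:]))


def edges_to_splits(edges, taxa) -> frozenset:
    """Nontrivial bipartitions of an edge-list tree."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    taxa_set = frozenset(taxa)
    splits = set()
    for a, b in edges:
        # leaves on b's side when the edge (a,b) is cut
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            node = stack.pop()
            if not node.startswith("_i"):
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(side)
        other = taxa_set - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return frozenset(splits)


def ols_fit_ssq(edges, taxa, dist) -> float:
    """Least-squares residual of fitting branch lengths to the distances."""
    edge_index = {tuple(sorted(e)): k for k, e in enumerate(edges)}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def path_edges(u, v):
        # BFS path between two leaves
        prev = {u: None}
        stack = [u]
        while stack:
            node = stack.pop()
            if node == v:
                break
            for nb in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        path = []
        node = v
        while prev[node] is not None:
            path.append(edge_index[tuple(sorted((node, prev[node])))])
            node = prev[node]
        return path

    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (u, v) in enumerate(pairs):
        for k in path_edges(u, v):
            A[r, k] = 1.0
        y[r] = dist[(u, v)]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ x - y
    return float(resid @ resid)


def best_topology_splits(taxa, dist) -> frozenset:
    """Exhaustive search: the topology with the smallest OLS residual."""
    best = None
    for edges in enumerate_topologies(list(taxa)):
        ssq = ols_fit_ssq(edges, taxa, dist)
        if best is None or ssq < best[0] - 1e-12:
            best = (ssq, edges_to_splits(edges, taxa))
    return best[1]


def random_additive_distances(rng: np.random.Generator, taxa: list[str]):
    """Random binary topology with positive branch lengths; returns
    ({pair: distance}, true splits)."""
    edges = [(taxa[0], "_i0"), (taxa[1], "_i0"), (taxa[2], "_i0")]
    nxt = 1
    for leaf in taxa[3:]:
        idx = int(rng.integers(len(edges)))
        a, b = edges.pop(idx)
        mid = f"_i{nxt}"
        nxt += 1
        edges += [(a, mid), (mid, b), (mid, leaf)]
    lengths = {tuple(sorted(e)): float(rng.uniform(0.05, 1.0)) for e in edges}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def dist(u, v):
        prev = {u: None}
        stack = [u]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb not in prev:
                    prev[nb] = node
                    stack.append(nb)
        total = 0.0
        node = v
        while prev[node] is not None:
            total += lengths[tuple(sorted((node, prev[node])))]
            node = prev[node]
        return total

    d = {(u, v): dist(u, v) for u, v in itertools.combinations(taxa, 2)}
    return d, edges_to_splits(edges, taxa)


def newick_splits(newick: str) -> frozenset:
    """Nontrivial bipartitions of a newick tree (dendropy-based)."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(l.taxon.label for l in t.leaf_node_iter())
    splits = set()
    for node in t.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return frozenset(splits)
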