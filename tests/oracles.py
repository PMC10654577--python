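"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: the edit
distance is the textbook recursion with memoization, directional UMI
clustering builds the full pairwise graph, and Delaunay edges come
from the empty-circumcircle predicate evaluated over all point
triples.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Dict, List, Set, Tuple

import numpy as np


def lev_recursive(x: str, y: str) -> int:
    """Edit distance by the plain recursion (memoized)."""

    @lru_cache(maxsize=None)
    def rec(a: str, b: str) -> int:
        if not b:
            return len(a)
        if not a:
            return len(b)
        if a[0] == b[0]:
            return rec(a[1:], b[1:])
        return 1 + min(rec(a[1:], b), rec(a, b[1:]), rec(a[1:], b[1:]))

    return rec(x, y)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def brute_directional_clusters(counts: Dict[str, int]) -> List[Tuple[str, int, Tuple[str, ...]]]:
    """Directional UMI clustering via the full pairwise graph.

    Builds every directed edge u->v with Hamming(u,v)=1 and
    count(u) >= 2*count(v)-1, then greedily BFS-expands from nodes in
    descending-count (lexicographic tie-break) order.
    Returns (representative, merged count, sorted members) tuples.
    """
    edges: Dict[str, List[str]] = {u: [] for u in counts}
    for u, v in itertools.permutations(counts, 2):
        if hamming(u, v) == 1 and counts[u] >= 2 * counts[v] - 1:
            edges[u].append(v)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    seen: Set[str] = set()
    clusters = []
    for root in order:
        if root in seen:
            continue
        members = [root]
        seen.add(root)
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in sorted(edges[u]):
                if v not in seen:
                    seen.add(v)
                    members.append(v)
                    queue.append(v)
        clusters.append(
            (root, sum(counts[m] for m in members), tuple(sorted(members)))
        )
    return clusters


def _in_circumcircle(a, b, c, d) -> bool:
    """True if d lies strictly inside the circumcircle of (a, b, c).

    Classic InCircle predicate: rows are the triangle vertices
    relative to the query point d; positive determinant means
    "inside" when (a, b, c) is counterclockwise.
    """
    dx, dy = d
    mat = np.array(
        [
            [a[0] - dx, a[1] - dy, (a[0] - dx) ** 2 + (a[1] - dy) ** 2],
            [b[0] - dx, b[1] - dy, (b[0] - dx) ** 2 + (b[1] - dy) ** 2],
            [c[0] - dx, c[1] - dy, (c[0] - dx) ** 2 + (c[1] - dy) ** 2],
        ]
    )
    det = np.linalg.det(mat)
    orient = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    return det * np.sign(orient) > 1e-12


def brute_delaunay_edges(points: np.ndarray) -> Set[Tuple[int, int]]:
    """Delaunay edges by the empty-circumcircle test over all triples.

    Edge (i, j) is Delaunay iff some third point k forms a triangle
    whose circumcircle contains no other point.
    """
    n = len(points)
    edges: Set[Tuple[int, int]] = set()
    for i, j in itertools.combinations(range(n), 2):
        for k in range(n):
            if k in (i, j):
                continue
            if all(
                m in (i, j, k) or not _in_circumcircle(points[i], points[j], points[k], points[m])
                for m in range(n)
            ):
                edges.add((i, j))
                break
    return edges
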