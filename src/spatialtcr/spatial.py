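"""Spatial repertoire analytics on the Delaunay spot graph.

The spot neighborhood graph is the edge set of the Delaunay
triangulation of in-tissue spot coordinates, with border artifacts
pruned (edges longer than ``prune_factor`` times the median
nearest-neighbor distance are removed).  On that graph:

* the clonality index of a clone is the mean, over its occupied
  spots, of the number of Delaunay neighbors sharing the clone
  (m = |NN_b ∩ support|, with m = 0 where no neighbor shares it);
* the per-spot CDR3-diversity index DI is the mean over resident
  CDR3s of the average Levenshtein distance to the other resident
  CDR3s;
* spots are classified as expansion / diversity / none / ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.spatial

from .model import Clone, SpotTable
from .repertoire import levenshtein


class GeometryError(ValueError):
    """Degenerate spot geometry (e.g. all points collinear)."""


@dataclass
class SpatialGraph:
    """Undirected Delaunay adjacency over spot barcodes."""

    barcodes: List[str]
    coords: np.ndarray  # (n, 2)
    edges: Set[Tuple[str, str]]  # ordered pairs (a < b)
    _adj: Dict[str, Set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._adj:
            self._adj = {b: set() for b in self.barcodes}
            for a, b in self.edges:
                self._adj[a].add(b)
                self._adj[b].add(a)

    def neighbors(self, barcode: str) -> Set[str]:
        return self._adj[barcode]

    def degree(self, barcode: str) -> int:
        return len(self._adj[barcode])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["source", "target"])


def delaunay_edges(coords: np.ndarray) -> Set[Tuple[int, int]]:
    """Unique index edges of the Delaunay triangulation."""
    try:
        tri = scipy.spatial.Delaunay(coords)
    except scipy.spatial.QhullError as exc:
        raise GeometryError(
            "Delaunay triangulation failed (points collinear or degenerate); "
            "consider a k-nearest-neighbor graph instead"
        ) from exc
    edges: Set[Tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    return edges


def delaunay_graph(
    spot_table: SpotTable,
    prune_factor: float = 3.0,
) -> SpatialGraph:
    """Delaunay spot graph over in-tissue spots.

    Duplicate coordinates are jittered by 1e-9 x median spacing before
    triangulation.  Edges longer than ``prune_factor`` times the
    median nearest-neighbor distance are removed (pass ``inf`` to keep
    all).
    """
    spots = spot_table.in_tissue()
    if len(spots) < 3:
        raise GeometryError("need at least 3 in-tissue spots")
    barcodes = list(spots["barcode"])
    coords = spots[["x", "y"]].to_numpy(dtype=float)

    # degenerate-input guard: jitter exact duplicates deterministically
    _, inverse, counts = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if (counts > 1).any():
        kd = scipy.spatial.cKDTree(np.unique(coords, axis=0))
        d, _ = kd.query(np.unique(coords, axis=0), k=min(2, len(counts)))
        spacing = float(np.median(d[:, -1])) or 1.0
        rng = np.random.default_rng(0)
        dup_rows = np.flatnonzero(counts[inverse] > 1)
        coords = coords.copy()
        coords[dup_rows] += rng.normal(scale=1e-9 * spacing, size=(len(dup_rows), 2))

    idx_edges = delaunay_edges(coords)
    kd = scipy.spatial.cKDTree(coords)
    nn_dist, _ = kd.query(coords, k=2)
    median_nn = float(np.median(nn_dist[:, 1]))
    edges: Set[Tuple[str, str]] = set()
    for i, j in idx_edges:
        length = float(np.linalg.norm(coords[i] - coords[j]))
        if np.isfinite(prune_factor) and length > prune_factor * median_nn:
            continue
        a, b = sorted((barcodes[i], barcodes[j]))
        edges.add((a, b))
    return SpatialGraph(barcodes=barcodes, coords=coords, edges=edges)


@dataclass
class CloneSpatialStats:
    clone_id: str
    per_spot_m: Dict[str, int]
    clonality_index: float
    clonality_sum: int
    n_spots: int


def clonality_index(
    graph: SpatialGraph, clones: Iterable[Clone]
) -> List[CloneSpatialStats]:
    """Per-clone co-clonal neighbor statistics on the spot graph.

    For each clone and each occupied spot b, m_b is the number of
    Delaunay neighbors of b that also carry the clone; the clonality
    index is the mean of m_b over occupied spots (the sum is also
    reported).
    """
    node_set = set(graph.barcodes)
    out = []
    for clone in clones:
        support = set(clone.spot_umis)
        stray = support - node_set
        if stray:
            raise KeyError(f"{clone.clone_id}: spots not in graph: {sorted(stray)[:5]}")
        per_spot = {
            b: len(graph.neighbors(b) & support) for b in sorted(support)
        }
        values = list(per_spot.values())
        out.append(
            CloneSpatialStats(
                clone_id=clone.clone_id,
                per_spot_m=per_spot,
                clonality_index=float(np.mean(values)) if values else 0.0,
                clonality_sum=int(np.sum(values)) if values else 0,
                n_spots=len(support),
            )
        )
    return out


def spot_diversity(cdr3s: Sequence[str], reciprocal: bool = False) -> float:
    """CDR3-diversity index of one spot.

    DI = mean over resident distinct CDR3s j of the mean Levenshtein
    distance from j to every other resident CDR3; 0 with fewer than
    two distinct CDR3s.  ``reciprocal`` averages 1/distance instead
    (an alternative reading of the index; not the default).
    """
    distinct = sorted(set(cdr3s))
    n = len(distinct)
    if n < 2:
        return 0.0
    means = []
    for j, a in enumerate(distinct):
        dists = [levenshtein(a, b) for i, b in enumerate(distinct) if i != j]
        if reciprocal:
            dists = [1.0 / d if d else 0.0 for d in dists]
        means.append(float(np.mean(dists)))
    return float(np.mean(means))


def spot_summaries(
    clones: Iterable[Clone],
    spot_table: Optional[SpotTable] = None,
    min_umi: int = 5,
) -> pd.DataFrame:
    """Per-spot total TCR UMIs and clone counts.

    ``n_clones`` counts clones supported by at least ``min_umi`` UMIs
    at the spot.  When a spot table is given, spots without any clone
    appear with zeros.
    """
    totals: Dict[str, int] = {}
    n_clones: Dict[str, int] = {}
    for c in clones:
        for b, n in c.spot_umis.items():
            totals[b] = totals.get(b, 0) + n
            if n >= min_umi:
                n_clones[b] = n_clones.get(b, 0) + 1
    barcodes = (
        spot_table.barcodes if spot_table is not None else sorted(totals)
    )
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "total_tcr_umis": [totals.get(b, 0) for b in barcodes],
            "n_clones": [n_clones.get(b, 0) for b in barcodes],
        }
    )


def spot_metrics(
    clones: Sequence[Clone],
    spot_table: Optional[SpotTable] = None,
    min_umi: int = 5,
    reciprocal: bool = False,
) -> pd.DataFrame:
    """Spot summaries plus the CDR3-diversity index per spot."""
    summaries = spot_summaries(clones, spot_table=spot_table, min_umi=min_umi)
    at_spot: Dict[str, List[str]] = {}
    for c in clones:
        for b in c.spot_umis:
            at_spot.setdefault(b, []).append(c.representative_cdr3_aa)
    summaries["diversity_index"] = [
        spot_diversity(at_spot.get(b, []), reciprocal=reciprocal)
        for b in summaries["barcode"]
    ]
    return summaries


def classify_spots(
    metrics: pd.DataFrame,
    clone_stats: Sequence[CloneSpatialStats],
    clones: Sequence[Clone],
    umi_threshold: int = 5,
    clonality_threshold: float = 1.0,
    diversity_threshold: float = 3.0,
    min_clones_diverse: int = 2,
) -> pd.DataFrame:
    """Label spots as expansion / diversity / none / ambiguous.

    none: no TCR UMIs at the spot.  expansion: the spot carries at
    least one clone with total UMIs > ``umi_threshold`` and clonality
    index > ``clonality_threshold``.  diversity: not expansion, at
    least ``min_clones_diverse`` clones and DI >=
    ``diversity_threshold``.  Otherwise ambiguous.  The four labels
    are exhaustive and mutually exclusive.
    """
    stats_by_id = {s.clone_id: s for s in clone_stats}
    expanded_spots: Set[str] = set()
    for c in clones:
        stat = stats_by_id.get(c.clone_id)
        if stat is None:
            continue
        if c.total_umis > umi_threshold and stat.clonality_index > clonality_threshold:
            expanded_spots.update(c.spot_umis)
    labels = []
    for _, row in metrics.iterrows():
        if row["total_tcr_umis"] == 0:
            labels.append("none")
        elif row["barcode"] in expanded_spots:
            labels.append("expansion")
        elif (
            row["n_clones"] >= min_clones_diverse
            and row["diversity_index"] >= diversity_threshold
        ):
            labels.append("diversity")
        else:
            labels.append("ambiguous")
    out = metrics.copy()
    out["label"] = labels
    return out
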