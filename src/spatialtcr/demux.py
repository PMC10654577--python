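"""Spot demultiplexing and UMI deduplication.

Reads are assigned to spot barcodes by locating the Read1 adapter on
either strand (best semi-global match, edit distance <= 4, leftmost on
ties), taking the 16 bases after the match as the candidate barcode
and the following 12 as the UMI, then matching the candidate against
the whitelist at up to ``max_dist`` (default 2) edits.  Equidistant
whitelist hits leave the read unassigned — demultiplexing stays
conservative.

UMIs are deduplicated with the directional clustering rule: a
higher-count UMI u absorbs v when Hamming(u, v) = 1 and
count(u) >= 2*count(v) - 1, expanding transitively from local maxima.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .model import BARCODE_LEN, R1_ADAPTER, UMI_LEN, Read, TcrRecord, revcomp

MAX_ADAPTER_DIST = 4


@dataclass
class BarcodeAssignment:
    read_id: str
    barcode: str = ""  # empty = unassigned
    umi: str = ""
    edit_distance: int = -1
    anchor_strand: str = ""  # "fwd" | "rev"

    @property
    def assigned(self) -> bool:
        return bool(self.barcode)


def _locate_adapter(seq: str, adapter: str, max_dist: int) -> Optional[Tuple[int, int, int]]:
    """Best leftmost semi-global match of adapter in seq.

    Returns (start, end_exclusive, distance) or None.
    """
    res = edlib.align(adapter, seq, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[1], loc[0]))
    return start, end + 1, res["editDistance"]


def extract_barcode_umi(
    read: Read,
    whitelist: Sequence[str],
    max_dist: int = 2,
    adapter: str = R1_ADAPTER,
    max_adapter_dist: int = MAX_ADAPTER_DIST,
) -> BarcodeAssignment:
    """Assign one read to a whitelist barcode and extract its UMI."""
    if not whitelist:
        raise ValueError("empty whitelist")
    hits = []
    for strand, seq in (("fwd", read.seq), ("rev", revcomp(read.seq))):
        hit = _locate_adapter(seq, adapter, max_adapter_dist)
        if hit is not None:
            hits.append((hit[2], 0 if strand == "fwd" else 1, hit, strand, seq))
    if not hits:
        return BarcodeAssignment(read.read_id)
    _, _, (start, end, _dist), strand, oriented = min(hits)
    candidate = oriented[end : end + BARCODE_LEN]
    umi = oriented[end + BARCODE_LEN : end + BARCODE_LEN + UMI_LEN]
    if len(candidate) < BARCODE_LEN or len(umi) < UMI_LEN:
        return BarcodeAssignment(read.read_id, anchor_strand=strand)

    best_d, best_bc, n_best = max_dist + 1, "", 0
    for bc in whitelist:
        res = edlib.align(candidate, bc, mode="NW", k=max_dist)
        d = res["editDistance"]
        if d < 0:
            continue
        if d < best_d:
            best_d, best_bc, n_best = d, bc, 1
        elif d == best_d:
            n_best += 1
    if n_best != 1 or best_d > max_dist:
        return BarcodeAssignment(read.read_id, anchor_strand=strand)
    return BarcodeAssignment(read.read_id, best_bc, umi, best_d, strand)


def demux_reads(
    reads: Iterable[Read], whitelist: Sequence[str], max_dist: int = 2
) -> List[BarcodeAssignment]:
    return [extract_barcode_umi(r, whitelist, max_dist=max_dist) for r in reads]


def assignments_to_frame(assignments: Iterable[BarcodeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "barcode": a.barcode,
                "umi": a.umi,
                "edit_distance": a.edit_distance,
                "strand": a.anchor_strand,
            }
            for a in assignments
        ],
        columns=["read_id", "barcode", "umi", "edit_distance", "strand"],
    )


# ---------------------------------------------------------------------------
# Directional UMI clustering


@dataclass
class UmiCluster:
    representative: str
    count: int
    members: List[str] = field(default_factory=list)


def _hamming1_neighbors(umi: str, universe: set) -> List[str]:
    out = []
    for i, base in enumerate(umi):
        for alt in "ACGT":
            if alt != base:
                cand = umi[:i] + alt + umi[i + 1 :]
                if cand in universe:
                    out.append(cand)
    return sorted(set(out))


def directional_umi_cluster(umi_counts: Dict[str, int]) -> List[UmiCluster]:
    """Directional clustering of UMI counts.

    Directed edge u -> v iff Hamming(u, v) = 1 and
    count(u) >= 2*count(v) - 1.  Clusters are the nodes reachable from
    local maxima processed in descending count order (ties broken by
    lexicographic UMI); each UMI lands in exactly one cluster, whose
    representative is its highest-count member.
    """
    if not umi_counts:
        return []
    lengths = {len(u) for u in umi_counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    if any(c < 1 for c in umi_counts.values()):
        raise ValueError("UMI counts must be >= 1")
    universe = set(umi_counts)
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    assigned: set = set()
    clusters: List[UmiCluster] = []
    for root in order:
        if root in assigned:
            continue
        members = [root]
        assigned.add(root)
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in _hamming1_neighbors(u, universe):
                if v in assigned:
                    continue
                if umi_counts[u] >= 2 * umi_counts[v] - 1:
                    assigned.add(v)
                    members.append(v)
                    queue.append(v)
        clusters.append(
            UmiCluster(
                representative=root,
                count=sum(umi_counts[m] for m in members),
                members=sorted(members),
            )
        )
    return clusters


def collapse_to_umis(
    assignments: Iterable[BarcodeAssignment],
    annotations: Iterable[TcrRecord],
) -> pd.DataFrame:
    """UMI-collapsed counts per (barcode, locus, CDR3).

    Reads sharing (barcode, locus, cdr3_nt) have their UMIs
    directional-clustered; the group's count is the number of UMI
    clusters.  Calls and identities are summarized per group (modal
    call, mean identity).  Only assigned reads with a called CDR3
    contribute.
    """
    amap = {a.read_id: a for a in assignments if a.assigned}
    groups: Dict[Tuple[str, str, str], List[TcrRecord]] = {}
    for rec in annotations:
        a = amap.get(rec.read_id)
        if a is None or not rec.cdr3_nt:
            continue
        groups.setdefault((a.barcode, rec.locus, rec.cdr3_nt), []).append(rec)
    rows = []
    for (barcode, locus, cdr3_nt), recs in sorted(groups.items()):
        umis = Counter(amap[r.read_id].umi for r in recs)
        clusters = directional_umi_cluster(dict(umis))
        modal = lambda vals: Counter(v for v in vals if v).most_common(1)[0][0] if any(vals) else ""
        rows.append(
            {
                "barcode": barcode,
                "locus": locus,
                "v_call": modal([r.v_call for r in recs]),
                "j_call": modal([r.j_call for r in recs]),
                "c_call": modal([r.c_call for r in recs]),
                "cdr3_nt": cdr3_nt,
                "cdr3_aa": modal([r.cdr3_aa for r in recs]),
                "v_identity": float(np.nanmean([r.v_identity for r in recs])),
                "j_identity": float(np.nanmean([r.j_identity for r in recs])),
                "umi_count": len(clusters),
            }
        )
    from .repertoire import RECORD_COLUMNS

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
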