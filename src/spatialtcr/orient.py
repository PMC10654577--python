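"""Read orientation, splitting of adapter-fused reads, and trimming.

Nanopore reads lose their strand; a structurally valid cDNA read runs
R1-adapter ... revcomp(TSO) on the forward strand (or its mirror on
the reverse strand).  All semi-global adapter matches on both strands
(edit distance <= 4) are collected greedily best-first without
overlap; every valid segment is emitted reoriented to start at the R1
adapter, with the synthetic regions (adapters plus the 28 nt
barcode+UMI window) trimmed away, so downstream annotation sees pure
transcript.  Reads with no valid segment yield no output and are
counted in run statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import edlib

from .model import BARCODE_LEN, R1_ADAPTER, TSO, UMI_LEN, Read, revcomp

MAX_ADAPTER_DIST = 4
_BCUMI = BARCODE_LEN + UMI_LEN


@dataclass
class OrientedInsert:
    """One transcript insert restored to 5'->3' orientation."""

    parent_read_id: str
    segment_index: int
    seq: str
    strand_applied: str  # "as-is" | "revcomp"

    @property
    def insert_id(self) -> str:
        return f"{self.parent_read_id}/{self.segment_index}"


def _all_matches(seq: str, pattern: str, max_dist: int) -> List[Tuple[int, int, int]]:
    """All non-overlapping semi-global matches, greedy best-first.

    Iteratively takes the best (lowest-distance, leftmost) match and
    masks it out.  Returns (start, end_exclusive, distance) tuples.
    """
    work = seq
    out = []
    while True:
        res = edlib.align(pattern, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            break
        start, end = min(res["locations"], key=lambda loc: (loc[1], loc[0]))
        out.append((start, end + 1, res["editDistance"]))
        work = work[:start] + "#" * (end + 1 - start) + work[end + 1 :]
    return out


def orient_and_split(
    read: Read,
    r1_adapter: str = R1_ADAPTER,
    tso: str = TSO,
    max_dist: int = MAX_ADAPTER_DIST,
    trim_barcode_umi: bool = True,
) -> List[OrientedInsert]:
    """Extract every structurally valid insert from a read.

    Candidate adapter hits of all four kinds (R1 and revcomp(TSO) for
    forward structures; TSO and revcomp(R1) for reverse structures)
    are resolved non-overlapping by score then position; consecutive
    R1 -> revcomp(TSO) hits bound a forward segment, consecutive
    TSO -> revcomp(R1) hits a reverse segment (emitted
    reverse-complemented).
    """
    if not r1_adapter or not tso:
        raise ValueError("adapters must be non-empty")
    # canonical orientation (lexicographic min of the two strands) so
    # that a read and its reverse complement resolve tie-breaks
    # identically and yield the same insert multiset
    rc = revcomp(read.seq)
    flipped = rc < read.seq
    seq = rc if flipped else read.seq
    kinds = {
        "R1+": r1_adapter,
        "TSO-": revcomp(tso),
        "TSO+": tso,
        "R1-": revcomp(r1_adapter),
    }
    candidates = []  # (dist, start, end, kind)
    for kind, pattern in kinds.items():
        for start, end, dist in _all_matches(seq, pattern, max_dist):
            candidates.append((dist, start, end, kind))
    # greedy best-first, non-overlapping footprints
    chosen: List[Tuple[int, int, int, str]] = []
    for cand in sorted(candidates, key=lambda c: (c[0], c[1], c[3])):
        if all(cand[2] <= s or cand[1] >= e for _, s, e, _ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[1])  # read order

    inserts: List[OrientedInsert] = []
    seg_index = 0
    for (d1, s1, e1, k1), (d2, s2, e2, k2) in zip(chosen, chosen[1:]):
        if k1 == "R1+" and k2 == "TSO-":
            core = seq[e1:s2]
            strand = "revcomp" if flipped else "as-is"
        elif k1 == "TSO+" and k2 == "R1-":
            core = revcomp(seq[e1:s2])
            strand = "as-is" if flipped else "revcomp"
        else:
            continue
        if trim_barcode_umi:
            core = core[_BCUMI:]
        if core:
            inserts.append(OrientedInsert(read.read_id, seg_index, core, strand))
            seg_index += 1
    if flipped:  # restore original read order of the segments
        inserts.reverse()
        for i, ins in enumerate(inserts):
            ins.segment_index = i
    return inserts


def orient_reads(
    reads: Iterable[Read], **kwargs
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Orient a stream of reads.

    Returns (insert_id -> sequence, run stats with input/emitted/
    dropped counts).
    """
    inserts: Dict[str, str] = {}
    stats = {"reads_in": 0, "reads_with_insert": 0, "inserts_out": 0, "reads_dropped": 0}
    for read in reads:
        stats["reads_in"] += 1
        found = orient_and_split(read, **kwargs)
        if found:
            stats["reads_with_insert"] += 1
            stats["inserts_out"] += len(found)
            for ins in found:
                inserts[ins.insert_id] = ins.seq
        else:
            stats["reads_dropped"] += 1
    return inserts, stats
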