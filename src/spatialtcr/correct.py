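"""Partitioned consensus error correction and error measurement.

Within each (V, C) partition, reads are clustered greedily around
centroids and each cluster is collapsed to a consensus by iterative
align-and-vote; members are then replaced by the consensus (so UMI
counting downstream is unaffected).  Error rates are measured before
and after by aligning reads to the known constant-region references —
only constant segments are assessed, since V(D)J recombination alters
the variable/joining germline.

Clustering similarity: reads in the same partition share V and C by
construction, so the informative signal is the junction.  When a
read's CDR3 junction is annotated, membership is decided by junction
edit identity against the cluster centroid's junction; reads without
an annotated junction fall back to whole-insert k-mer Jaccard.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .annotate import SegmentReference, VcPartition
from .model import TcrRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadCluster:
    """A similarity cluster within one (V, C) partition."""

    key: Tuple[str, str]
    member_ids: List[str]
    consensus: str = ""

    @property
    def size(self) -> int:
        return len(self.member_ids)


def kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _junction_identity(a: str, b: str) -> float:
    """1 - edit distance / max length, on two junction sequences."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_partition(
    inserts: Dict[str, str],
    junctions: Optional[Dict[str, str]] = None,
    k: int = 11,
    min_jaccard: float = 0.35,
    min_junction_identity: float = 0.7,
    key: Tuple[str, str] = ("", ""),
) -> List[ReadCluster]:
    """Greedy centroid clustering of one partition's inserts.

    Inserts are visited by descending length (ties broken by id); each
    joins the first existing cluster it matches, else founds one.  A
    match means junction identity >= ``min_junction_identity`` when
    both the insert and the centroid carry an annotated junction,
    otherwise whole-insert k-mer Jaccard >= ``min_jaccard`` against
    the centroid.  Deterministic given the input.
    """
    if not inserts:
        raise ValueError("empty partition")
    junctions = junctions or {}
    order = sorted(inserts, key=lambda i: (-len(inserts[i]), i))
    clusters: List[ReadCluster] = []
    centroid_kmers: List[set] = []
    for iid in order:
        seq = inserts[iid]
        junc = junctions.get(iid, "")
        kmers = None
        placed = False
        for ci, cl in enumerate(clusters):
            cent_id = cl.member_ids[0]
            cent_junc = junctions.get(cent_id, "")
            if junc and cent_junc:
                ok = _junction_identity(junc, cent_junc) >= min_junction_identity
            else:
                if kmers is None:
                    kmers = kmer_set(seq, k)
                ok = kmer_jaccard(kmers, centroid_kmers[ci]) >= min_jaccard
            if ok:
                cl.member_ids.append(iid)
                placed = True
                break
        if not placed:
            clusters.append(ReadCluster(key=key, member_ids=[iid]))
            centroid_kmers.append(kmer_set(seq, k))
    return clusters


# ---------------------------------------------------------------------------
# Consensus


def _parse_cigar(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def build_consensus(member_seqs: Sequence[str], n_refine: int = 2) -> str:
    """Consensus by iterative global alignment and per-column vote.

    The longest member seeds the consensus; each member is aligned to
    the running consensus and votes per column over {A, C, G, T, gap}
    (a gap never wins a tie; base ties fall back to the current
    consensus base, then lexicographic order).  Insertions relative to
    the consensus are applied only where a strict majority of members
    inserts, taking the most common inserted sequence.  ``n_refine``
    additional passes stabilize the result.  Singletons pass through.
    """
    if not member_seqs:
        raise ValueError("empty cluster")
    if len(member_seqs) == 1:
        return member_seqs[0]
    consensus = max(sorted(member_seqs), key=len)
    for _ in range(1 + n_refine):
        new = _vote_pass(consensus, member_seqs)
        if new == consensus:
            break
        consensus = new
    return consensus


def _vote_pass(consensus: str, member_seqs: Sequence[str]) -> str:
    L = len(consensus)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    votes = np.zeros((L, 5), dtype=np.int32)
    ins_votes: Dict[int, Dict[str, int]] = {}
    n = len(member_seqs)
    for seq in member_seqs:
        res = edlib.align(seq, consensus, mode="NW", task="path")
        ci = 0  # consensus column
        si = 0  # member position
        for length, op in _parse_cigar(res["cigar"]):
            if op in "=XM":
                for _ in range(length):
                    votes[ci, base_idx.get(seq[si], 0)] += 1
                    ci += 1
                    si += 1
            elif op == "D":  # gap in member against consensus columns
                votes[ci : ci + length, 4] += 1
                ci += length
            elif op == "I":  # member inserts before consensus column ci
                frag = seq[si : si + length]
                slot = ins_votes.setdefault(ci, {})
                slot[frag] = slot.get(frag, 0) + 1
                si += length
    out: List[str] = []
    for ci in range(L + 1):
        slot = ins_votes.get(ci)
        if slot and sum(slot.values()) > n / 2:
            frag = min(slot, key=lambda f: (-slot[f], f))
            out.append(frag)
        if ci == L:
            break
        col = votes[ci]
        best = int(col.max())
        winners = [b for b, v in zip("ACGT-", col) if v == best]
        if len(winners) > 1 and "-" in winners:
            winners.remove("-")  # gap loses ties
        if len(winners) > 1 and consensus[ci] in winners:
            choice = consensus[ci]
        else:
            choice = winners[0] if winners != ["-"] else "-"
        if choice != "-":
            out.append(choice)
    return "".join(out)


def correct_inserts(
    inserts: Dict[str, str],
    records: Iterable[TcrRecord],
    partitions: Optional[List[VcPartition]] = None,
    k: int = 11,
    min_jaccard: float = 0.35,
    min_junction_identity: float = 0.7,
    n_refine: int = 2,
) -> Tuple[Dict[str, str], List[ReadCluster]]:
    """Run clustering + consensus across all (V, C) partitions.

    Returns (corrected insert map, clusters).  Inserts outside any
    partition (off-target) are passed through uncorrected.
    """
    from .annotate import group_by_vc

    records = list(records)
    if partitions is None:
        partitions = group_by_vc(records)
    junctions = {r.read_id: r.cdr3_nt for r in records}
    corrected = dict(inserts)
    all_clusters: List[ReadCluster] = []
    for part in partitions:
        member_map = {i: inserts[i] for i in part.member_ids if i in inserts}
        if not member_map:
            continue
        clusters = cluster_partition(
            member_map,
            junctions=junctions,
            k=k,
            min_jaccard=min_jaccard,
            min_junction_identity=min_junction_identity,
            key=part.key,
        )
        for cl in clusters:
            cl.consensus = build_consensus(
                [member_map[i] for i in cl.member_ids], n_refine=n_refine
            )
            for iid in cl.member_ids:
                corrected[iid] = cl.consensus
        all_clusters.extend(clusters)
    return corrected, all_clusters


# ---------------------------------------------------------------------------
# Error measurement


class ConfigError(ValueError):
    pass


@dataclass
class ErrorReport:
    """Per-read error rates vs constant-region references, pre and post."""

    pre_rates: Dict[str, float]
    post_rates: Dict[str, float]
    pre_excluded: List[str]
    post_excluded: List[str]
    pre_mean_length: float
    post_mean_length: float

    @property
    def pre_mean(self) -> float:
        return float(np.mean(list(self.pre_rates.values()))) if self.pre_rates else math.nan

    @property
    def post_mean(self) -> float:
        return float(np.mean(list(self.post_rates.values()))) if self.post_rates else math.nan

    @property
    def pre_sd(self) -> float:
        return float(np.std(list(self.pre_rates.values()))) if self.pre_rates else math.nan

    @property
    def post_sd(self) -> float:
        return float(np.std(list(self.post_rates.values()))) if self.post_rates else math.nan

    def summary(self) -> Dict[str, float]:
        return {
            "pre_mean_error": self.pre_mean,
            "pre_sd_error": self.pre_sd,
            "post_mean_error": self.post_mean,
            "post_sd_error": self.post_sd,
            "pre_mean_length": self.pre_mean_length,
            "post_mean_length": self.post_mean_length,
            "n_pre": len(self.pre_rates),
            "n_post": len(self.post_rates),
            "n_pre_excluded": len(self.pre_excluded),
            "n_post_excluded": len(self.post_excluded),
        }


def c_region_error_rate(
    seq: str, refs: SegmentReference, max_error: float = 0.35
) -> Optional[float]:
    """Error rate of the best constant-segment alignment in a read.

    The full C reference is aligned semi-globally inside the read;
    error rate = (mismatches + inserted + deleted bases) / alignment
    columns.  Returns None when no C segment aligns under
    ``max_error`` (read excluded from the report).
    """
    c_segs = refs.by_role("C")
    if not c_segs:
        raise ConfigError("reference contains no C-role segments")
    best: Optional[float] = None
    for seg in c_segs:
        res = edlib.align(seg.seq, seq, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        ops = _parse_cigar(res["cigar"])
        columns = sum(n for n, _ in ops)
        errors = sum(n for n, op in ops if op in "XID")
        rate = errors / columns if columns else 1.0
        if best is None or rate < best:
            best = rate
    if best is None or best > max_error:
        return None
    return best


def measure_error(
    pre: Dict[str, str],
    post: Dict[str, str],
    refs: SegmentReference,
    max_error: float = 0.35,
) -> ErrorReport:
    """Measure per-read error rates before and after correction."""

    def run(seqs: Dict[str, str]) -> Tuple[Dict[str, float], List[str]]:
        rates, excluded = {}, []
        for iid, seq in sorted(seqs.items()):
            rate = c_region_error_rate(seq, refs, max_error=max_error)
            if rate is None:
                excluded.append(iid)
            else:
                rates[iid] = rate
        return rates, excluded

    pre_rates, pre_excl = run(pre)
    post_rates, post_excl = run(post)
    return ErrorReport(
        pre_rates=pre_rates,
        post_rates=post_rates,
        pre_excluded=pre_excl,
        post_excluded=post_excl,
        pre_mean_length=float(np.mean([len(s) for s in pre.values()])) if pre else math.nan,
        post_mean_length=float(np.mean([len(s) for s in post.values()])) if post else math.nan,
    )
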