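"""Ground-truthed synthetic spatial repertoires and nanopore-like reads.

Every downstream stage is testable without a download: spots sit on a
hexagonal lattice, planted clones occupy either a contiguous
Delaunay-connected patch ("expanded") or uniformly sampled spots
("dispersed"), and each cDNA molecule is emitted as a long read laid
out as

    R1 adapter + 16 nt barcode + 12 nt UMI + transcript + revcomp(TSO)

then corrupted by an iid per-base substitution/insertion/deletion
channel and reverse-complemented with probability one half.

Transcripts are built from a closed toy V/J/C reference set (4 V, 3 J,
2 C per locus for TRA/TRB) with a per-V 5' leader so that transcript
lengths land near the ~800 nt regime typical of captured full-length
TCR cDNA.  The default error rates sum to a 4.74% mean per-base error,
split substitution-heavy (60/20/20) as in R9-pore nanopore data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import Segment, SegmentReference
from .model import (
    BARCODE_LEN,
    R1_ADAPTER,
    TSO,
    UMI_LEN,
    Read,
    SpotTable,
    ValidationError,
    revcomp,
    translate_nt,
)
from .repertoire import levenshtein

# Default error channel: 4.74% mean per-base error, substitution-heavy.
DEFAULT_SUB_RATE = 0.02844
DEFAULT_INS_RATE = 0.00948
DEFAULT_DEL_RATE = 0.00948

TOY_REF_SEED = 20240517
_NON_STOP_CODONS = [
    c
    for c in (
        a + b + d
        for a in "ACGT"
        for b in "ACGT"
        for d in "ACGT"
    )
    if translate_nt(c) != "*"
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def toy_references(seed: int = TOY_REF_SEED) -> SegmentReference:
    """Deterministic toy V/J/C reference set for TRA and TRB.

    Per locus: 4 V segments (200-300 nt, ending in the conserved Cys
    codon TGT), 3 J segments (50 nt, starting with a Phe-Gly anchor
    motif) and 2 C segments (150 nt).  Shipped as a FASTA fixture and
    regenerated bit-identically from this function.
    """
    rng = np.random.default_rng(seed)
    segments: List[Segment] = []
    j_motifs = ["TTTGGC", "TTCGGA", "TTTGGG"]
    for locus in ("TRA", "TRB"):
        for i in range(1, 5):
            length = int(rng.integers(200, 301))
            seq = _random_dna(rng, length - 3) + "TGT"
            segments.append(
                Segment(f"{locus}V{i}", locus, "V", seq, cys_offset=length - 3)
            )
        for i in range(1, 4):
            seq = j_motifs[i - 1] + _random_dna(rng, 44)
            segments.append(
                Segment(f"{locus}J{i}", locus, "J", seq, motif_offset=0)
            )
        for i in range(1, 3):
            segments.append(Segment(f"{locus}C{i}", locus, "C", _random_dna(rng, 150)))
    return SegmentReference(segments)


@dataclass
class CloneTruth:
    """Ground truth for one planted clone."""

    clone_id: str
    locus: str
    v_id: str
    j_id: str
    c_id: str
    cdr3_nt: str
    cdr3_aa: str
    transcript: str
    pattern: str  # "expanded" | "dispersed"
    spot_umis: Dict[str, int]


@dataclass
class TruthBundle:
    """A complete simulated study: clones, spots, whitelist, channel."""

    clone_truths: List[CloneTruth]
    spot_table: SpotTable
    whitelist: List[str]
    error_params: Tuple[float, float, float]  # sub, ins, del
    seed: int
    refs: SegmentReference
    mean_reads_per_umi: float = 3.0
    reads_per_clone: Optional[Tuple[int, int]] = None
    hex_neighbors: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        in_tissue = set(self.spot_table.in_tissue()["barcode"])
        for ct in self.clone_truths:
            if not ct.transcript:
                raise ValidationError(f"{ct.clone_id}: empty transcript")
            stray = set(ct.spot_umis) - in_tissue
            if stray:
                raise ValidationError(
                    f"{ct.clone_id}: planted UMIs on non-tissue spots {sorted(stray)}"
                )
        if any(r >= 0.5 for r in self.error_params):
            raise ValidationError("error rates must each be < 0.5")


def hex_lattice(n_spots: int, spacing: float = 100.0) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """First ``n_spots`` positions of a hexagonal lattice, row-major.

    Returns (coordinates, (row, col) indices).
    """
    side = int(np.ceil(np.sqrt(n_spots)))
    coords, idx = [], []
    for r in range(side + 1):
        for c in range(side + 1):
            if len(coords) == n_spots:
                return np.array(coords), idx
            x = spacing * (c + 0.5 * (r % 2))
            y = spacing * (np.sqrt(3) / 2) * r
            coords.append((x, y))
            idx.append((r, c))
    return np.array(coords), idx


def _hex_adjacency(idx: List[Tuple[int, int]]) -> Dict[int, List[int]]:
    """Neighbor lists on the offset hex lattice (6-neighborhood)."""
    pos = {rc: i for i, rc in enumerate(idx)}
    adj: Dict[int, List[int]] = {i: [] for i in range(len(idx))}
    for (r, c), i in pos.items():
        shift = 0 if r % 2 == 0 else 1
        for dr, dc in ((0, 1), (0, -1), (1, shift - 1), (1, shift), (-1, shift - 1), (-1, shift)):
            j = pos.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)
    return adj


def _make_junction(rng: np.random.Generator) -> Tuple[str, str]:
    """Random CDR3 junction: TGT + 4..19 non-stop codons (15-60 nt).

    Junction lengths stay inside the default repertoire length filter
    (5-30 aa) so that planted clones are recoverable end to end.
    """
    n_codons = int(rng.integers(4, 20))
    body = "".join(
        _NON_STOP_CODONS[int(k)]
        for k in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    )
    nt = "TGT" + body
    return nt, translate_nt(nt)


def simulate_repertoire(
    n_spots: int = 100,
    n_clones: int = 20,
    pattern_mix: Optional[Dict[str, float]] = None,
    mean_reads_per_umi: float = 3.0,
    seed: int = 0,
    *,
    sub_rate: float = DEFAULT_SUB_RATE,
    ins_rate: float = DEFAULT_INS_RATE,
    del_rate: float = DEFAULT_DEL_RATE,
    refs: Optional[SegmentReference] = None,
    leader_len: int = 350,
    expanded_patch: Tuple[int, int] = (3, 8),
    dispersed_spots: Tuple[int, int] = (4, 12),
    umi_lambda: float = 1.0,
    reads_per_clone: Optional[Tuple[int, int]] = None,
    min_cdr3_dist: int = 2,
) -> TruthBundle:
    """Plant ``n_clones`` clones on a hexagonal lattice of ``n_spots``.

    ``pattern_mix`` gives the fraction of clones per spatial pattern
    (default half expanded, half dispersed) and must sum to 1.
    Planted CDR3 amino-acid sequences are pairwise at Levenshtein
    distance >= ``min_cdr3_dist`` so clonotype recovery is well posed.
    Deterministic given ``seed``.
    """
    if n_spots < 9:
        raise ConfigError("n_spots must be >= 9")
    if n_clones < 0:
        raise ConfigError("n_clones must be >= 0")
    pattern_mix = pattern_mix or {"expanded": 0.5, "dispersed": 0.5}
    if set(pattern_mix) - {"expanded", "dispersed"}:
        raise ConfigError(f"unknown patterns in mix: {sorted(pattern_mix)}")
    if abs(sum(pattern_mix.values()) - 1.0) > 1e-9:
        raise ConfigError("pattern_mix fractions must sum to 1")
    refs = refs or toy_references()
    rng = np.random.default_rng(seed)

    coords, idx = hex_lattice(n_spots)
    adj = _hex_adjacency(idx)
    barcodes = []
    seen = set()
    while len(barcodes) < n_spots:
        bc = _random_dna(rng, BARCODE_LEN)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    n_cells = rng.poisson(5, size=n_spots) + 1
    total_umis = rng.poisson(n_cells * 200)
    spot_table = SpotTable(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "x": coords[:, 0],
                "y": coords[:, 1],
                "in_tissue": True,
                "n_cells": n_cells,
                "total_umis": total_umis,
            }
        )
    )

    # deterministic per-pattern clone counts
    n_expanded = int(round(pattern_mix.get("expanded", 0.0) * n_clones))
    patterns = ["expanded"] * n_expanded + ["dispersed"] * (n_clones - n_expanded)

    # per-V leader sequences emulate the 5' UTR of the captured cDNA
    leaders = {
        v.segment_id: _random_dna(rng, leader_len) for v in refs.by_role("V")
    }

    clone_truths: List[CloneTruth] = []
    used_cdr3: List[str] = []
    for ci, pattern in enumerate(patterns):
        locus = "TRA" if rng.random() < 0.5 else "TRB"
        v = refs.by_role("V", locus)[int(rng.integers(0, 4))]
        j = refs.by_role("J", locus)[int(rng.integers(0, 3))]
        c = refs.by_role("C", locus)[int(rng.integers(0, 2))]
        for _ in range(1000):
            cdr3_nt, cdr3_aa = _make_junction(rng)
            if all(levenshtein(cdr3_aa, other) >= min_cdr3_dist for other in used_cdr3):
                break
        else:  # pragma: no cover - 1000 rejections at these sizes
            raise ConfigError("could not place pairwise-distinct CDR3s")
        used_cdr3.append(cdr3_aa)
        # V already ends in the Cys codon; the junction repeats it, so
        # splice the junction body after V and keep J/C downstream.
        transcript = leaders[v.segment_id] + v.seq + cdr3_nt[3:] + j.seq + c.seq

        if pattern == "expanded":
            target = int(rng.integers(expanded_patch[0], expanded_patch[1] + 1))
            start = int(rng.integers(0, n_spots))
            patch = [start]
            frontier = [start]
            while len(patch) < target and frontier:
                nxt = sorted(
                    {n for f in frontier for n in adj[f]} - set(patch)
                )
                if not nxt:
                    break
                take = min(len(nxt), target - len(patch))
                chosen = rng.choice(len(nxt), size=take, replace=False)
                frontier = [nxt[int(k)] for k in sorted(chosen)]
                patch.extend(frontier)
            spots = patch
        else:
            k = int(rng.integers(dispersed_spots[0], min(dispersed_spots[1], n_spots) + 1))
            spots = sorted(rng.choice(n_spots, size=k, replace=False).tolist())

        spot_umis = {
            barcodes[s]: 1 + int(rng.poisson(umi_lambda)) for s in spots
        }
        clone_truths.append(
            CloneTruth(
                clone_id=f"clone{ci:04d}",
                locus=locus,
                v_id=v.segment_id,
                j_id=j.segment_id,
                c_id=c.segment_id,
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                transcript=transcript,
                pattern=pattern,
                spot_umis=spot_umis,
            )
        )

    hex_neighbors = {
        barcodes[i]: [barcodes[j] for j in js] for i, js in adj.items()
    }
    return TruthBundle(
        clone_truths=clone_truths,
        spot_table=spot_table,
        whitelist=list(barcodes),
        error_params=(sub_rate, ins_rate, del_rate),
        seed=seed,
        refs=refs,
        mean_reads_per_umi=mean_reads_per_umi,
        reads_per_clone=reads_per_clone,
        hex_neighbors=hex_neighbors,
    )


def corrupt(
    seq: str, rng: np.random.Generator, sub_rate: float, ins_rate: float, del_rate: float
) -> Tuple[str, int]:
    """Apply the position-independent error channel.

    Per input base: delete with ``del_rate``; otherwise emit it,
    substituted with ``sub_rate``; after each emitted/considered base,
    insert a random base with ``ins_rate``.  Returns (sequence,
    number of planted error operations).
    """
    bases = "ACGT"
    n = len(seq)
    dels = rng.random(n) < del_rate
    subs = rng.random(n) < sub_rate
    inss = rng.random(n) < ins_rate
    sub_choice = rng.integers(0, 3, size=n)
    ins_choice = rng.integers(0, 4, size=n)
    out = []
    n_err = 0
    for i, base in enumerate(seq):
        if dels[i]:
            n_err += 1
        else:
            if subs[i]:
                alternatives = bases.replace(base, "") if base in bases else bases[:3]
                base = alternatives[int(sub_choice[i])]
                n_err += 1
            out.append(base)
        if inss[i]:
            out.append(bases[int(ins_choice[i])])
            n_err += 1
    return "".join(out), n_err


def emit_reads(bundle: TruthBundle) -> Tuple[List[Read], pd.DataFrame]:
    """Emit noisy reads for every planted molecule, plus a truth table.

    The truth table maps read_id -> (clone_id, barcode, umi, strand,
    planted error count).  Roughly half the reads are emitted
    reverse-complemented.  Deterministic given the bundle seed.
    """
    rng = np.random.default_rng([bundle.seed, 1])
    sub, ins, dele = bundle.error_params
    reads: List[Read] = []
    truth_rows = []
    serial = 0
    for ct in bundle.clone_truths:
        molecules: List[Tuple[str, str]] = []  # (barcode, umi)
        for barcode, n_umis in sorted(ct.spot_umis.items()):
            spot_umis: set = set()
            while len(spot_umis) < n_umis:
                spot_umis.add(_random_dna(rng, UMI_LEN))
            molecules.extend((barcode, u) for u in sorted(spot_umis))
        if bundle.reads_per_clone is not None:
            lo, hi = bundle.reads_per_clone
            total = int(rng.integers(lo, hi + 1))
            total = max(total, len(molecules))
            counts = np.ones(len(molecules), dtype=int)
            extra = rng.choice(len(molecules), size=total - len(molecules), replace=True)
            for e in extra:
                counts[e] += 1
        else:
            counts = 1 + rng.poisson(
                max(bundle.mean_reads_per_umi - 1.0, 0.0), size=len(molecules)
            )
        for (barcode, umi), n_reads in zip(molecules, counts):
            for _ in range(int(n_reads)):
                forward = R1_ADAPTER + barcode + umi + ct.transcript + revcomp(TSO)
                seq, n_err = corrupt(forward, rng, sub, ins, dele)
                strand = "rev" if rng.random() < 0.5 else "fwd"
                if strand == "rev":
                    seq = revcomp(seq)
                read_id = f"r{serial:07d}"
                serial += 1
                reads.append(Read(read_id, seq, "I" * len(seq)))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "clone_id": ct.clone_id,
                        "barcode": barcode,
                        "umi": umi,
                        "strand": strand,
                        "n_errors": n_err,
                    }
                )
    return reads, pd.DataFrame(
        truth_rows,
        columns=["read_id", "clone_id", "barcode", "umi", "strand", "n_errors"],
    )


# ---------------------------------------------------------------------------
# Synthetic expression matrices (for the ecosystem stage)

from .ecosystem import (  # noqa: E402
    CLONAL_MARKERS,
    DEFAULT_RL_PAIRS,
    EXHAUSTION_MARKERS,
)


def simulate_expression(
    bundle: TruthBundle,
    n_background_genes: int = 40,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Genes x spots counts matrix with marker structure.

    Marker genes (cytotoxic/exhaustion panels plus the default
    receptor-ligand genes) are Poisson-expressed with rates scaled by
    the spot's TCR UMI mass, so spots carrying T cells light up;
    background genes are flat Poisson noise.
    """
    seed = bundle.seed if seed is None else seed
    rng = np.random.default_rng([seed, 2])
    barcodes = bundle.spot_table.barcodes
    tcr_mass = pd.Series(0.0, index=barcodes)
    for ct in bundle.clone_truths:
        for bc, n in ct.spot_umis.items():
            tcr_mass[bc] += n
    scale = 1.0 + tcr_mass / max(tcr_mass.max(), 1.0)

    rl_genes = sorted({g for pair in DEFAULT_RL_PAIRS for g in pair})
    markers = sorted(set(CLONAL_MARKERS) | set(EXHAUSTION_MARKERS) | set(rl_genes))
    genes = markers + [f"BG{i:03d}" for i in range(n_background_genes)]
    rates = np.empty((len(genes), len(barcodes)))
    for gi, g in enumerate(genes):
        base = 2.0 + 8.0 * rng.random()
        rates[gi] = base * (scale.values if g in markers else np.ones(len(barcodes)))
    M = pd.DataFrame(
        rng.poisson(rates).astype(float), index=genes, columns=barcodes
    )
    return M
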