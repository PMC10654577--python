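"""Core domain types shared across the pipeline.

The pipeline moves data through a small set of containers: raw long
reads (:class:`Read`), spot geometry and per-spot covariates
(:class:`SpotTable`), AIRR-style rearrangement records
(:class:`TcrRecord`) and clonotypes after Levenshtein merging
(:class:`Clone`).  Expression matrices are plain pandas DataFrames with
genes as the index and spot barcodes as columns; validation lives in
:mod:`spatialtcr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd

# Library-preparation constants: Illumina TruSeq Read1 primer site used
# as the demultiplexing anchor, and the 10x template-switch oligo that
# marks the 3' end of the insert (reverse-complemented on the forward
# strand of the cDNA).
R1_ADAPTER = "CTACACGACGCTCTTCCGATCT"
TSO = "AAGCAGTGGTATCAACGCAGAG"
BARCODE_LEN = 16
UMI_LEN = 12

LOCI = ("TRA", "TRB", "TRG", "TRD")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard codon table (DNA, '*' = stop).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_nt(seq: str) -> str:
    """Translate a DNA string whose length is a multiple of 3.

    Codons containing characters outside ACGT translate to ``X``.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    aa = []
    for i in range(0, len(seq), 3):
        aa.append(CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(aa)


class ValidationError(ValueError):
    """An input record violates a type invariant."""


@dataclass
class Read:
    """One long read: identifier, nucleotides and Phred+33 qualities."""

    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValidationError("read_id must be non-empty")
        if not self.seq:
            raise ValidationError(f"{self.read_id}: empty sequence")
        if len(self.qual) != len(self.seq):
            raise ValidationError(
                f"{self.read_id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def revcomp(self) -> "Read":
        return Read(self.read_id, revcomp(self.seq), self.qual[::-1])


@dataclass
class TcrRecord:
    """AIRR-style rearrangement row for one read or insert."""

    read_id: str
    barcode: str = ""
    umi: str = ""
    locus: str = ""
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    c_call: str = ""
    v_identity: float = float("nan")
    j_identity: float = float("nan")
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    complete_vdj: bool = False
    extra: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.locus and self.locus not in LOCI:
            raise ValidationError(f"{self.read_id}: unknown locus {self.locus!r}")
        if self.complete_vdj and not (self.v_call and self.j_call):
            raise ValidationError(
                f"{self.read_id}: complete_vdj requires v_call and j_call"
            )


class SpotTable:
    """Spot barcodes with planar coordinates and per-spot covariates.

    Backed by a DataFrame with columns
    ``barcode, x, y, in_tissue, n_cells, total_umis``.  Coordinates are
    abstract planar floats; downstream geometry is scale-free apart
    from edge pruning, which uses data-derived spacing.
    """

    COLUMNS = ["barcode", "x", "y", "in_tissue", "n_cells", "total_umis"]

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        for col, default in (("in_tissue", True), ("n_cells", 0), ("total_umis", 0)):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"spot table missing columns: {missing}")
        df = df[self.COLUMNS].reset_index(drop=True)
        dup = df["barcode"][df["barcode"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate spot barcodes: {sorted(set(dup))[:5]}")
        if (df["n_cells"] < 0).any() or (df["total_umis"] < 0).any():
            raise ValidationError("n_cells and total_umis must be non-negative")
        df["in_tissue"] = df["in_tissue"].astype(bool)
        self.df = df
        # Geometry consumers need >= 3 non-collinear in-tissue spots;
        # readers only flag the count here, collinearity is checked at
        # triangulation time.
        self.geometry_warning = int(df["in_tissue"].sum()) < 3

    def __len__(self) -> int:
        return len(self.df)

    @property
    def barcodes(self) -> List[str]:
        return list(self.df["barcode"])

    def in_tissue(self) -> pd.DataFrame:
        return self.df[self.df["in_tissue"]].reset_index(drop=True)

    def row(self, barcode: str) -> pd.Series:
        hit = self.df[self.df["barcode"] == barcode]
        if hit.empty:
            raise KeyError(barcode)
        return hit.iloc[0]


@dataclass
class Clone:
    """A clonotype: CDR3 amino-acid sequences merged under a
    Levenshtein radius, with per-spot UMI support."""

    clone_id: str
    locus: str
    representative_cdr3_aa: str
    members: Set[str]
    mean_v_identity: float
    mean_j_identity: float
    spot_umis: Dict[str, int]

    def __post_init__(self) -> None:
        if self.representative_cdr3_aa not in self.members:
            raise ValidationError(
                f"{self.clone_id}: representative not among members"
            )
        if any(v < 1 for v in self.spot_umis.values()):
            raise ValidationError(f"{self.clone_id}: per-spot UMI counts must be >= 1")

    @property
    def total_umis(self) -> int:
        return sum(self.spot_umis.values())

    @property
    def n_spots(self) -> int:
        return len(self.spot_umis)


def validate_expression(M: pd.DataFrame, spot_table: Optional[SpotTable] = None) -> pd.DataFrame:
    """Validate a genes x spots expression matrix."""
    if M.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression matrix")
    if (M.values < 0).any():
        raise ValidationError("expression matrix has negative entries")
    if spot_table is not None:
        unknown = set(M.columns) - set(spot_table.barcodes)
        if unknown:
            raise ValidationError(
                f"expression columns not in spot table: {sorted(unknown)[:5]}"
            )
    return M
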