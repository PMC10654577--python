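"""Readers and writers for the standard formats the pipeline touches.

FASTQ (4-line, Phred+33), FASTA references, AIRR Rearrangement TSV,
spot-position CSV (Visium ``tissue_positions`` dialect or a simple
``barcode,x,y`` dialect), and genes x spots expression matrices as TSV
or MatrixMarket.  All readers validate against the type invariants in
:mod:`spatialtcr.model` and raise located errors.
"""

from __future__ import annotations

import gzip
import io as _io
import math
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Union

import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    Read,
    SpotTable,
    TcrRecord,
    ValidationError,
    translate_nt,
    validate_expression,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed record in an input file, located by line number."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


def _open_text(path: PathLike):
    """Open a text file, transparently decompressing gzip.

    Detection is by magic bytes, not file extension.
    """
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return _io.TextIOWrapper(fh)


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield reads from a 4-line FASTQ file in file order."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno + 2}: expected '+' separator")
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            read_id = header[1:].rstrip("\n").split()[0]
            try:
                yield Read(read_id, seq, qual)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            lineno += 3


def write_fastq(reads: Iterable[Read], path: PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV

# AIRR schema column -> TcrRecord field
_AIRR_COLUMNS = {
    "sequence_id": "read_id",
    "locus": "locus",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_identity": "v_identity",
    "j_identity": "j_identity",
    "cell_id": "barcode",
    "umi": "umi",
    "complete_vdj": "complete_vdj",
}


def read_airr(path: PathLike) -> List[TcrRecord]:
    """Read an AIRR Rearrangement TSV into TcrRecords.

    Unknown columns are preserved per record in ``extra``; missing
    optional columns default to empty.  A junction without a
    ``junction_aa`` is translated when its length is a multiple of 3.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sequence_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'sequence_id'")
    known = [c for c in df.columns if c in _AIRR_COLUMNS]
    unknown = [c for c in df.columns if c not in _AIRR_COLUMNS]
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in known:
            field = _AIRR_COLUMNS[col]
            val = row[col]
            if field in ("v_identity", "j_identity"):
                kwargs[field] = float(val) if val != "" else float("nan")
            elif field == "complete_vdj":
                kwargs[field] = val.strip().upper() in ("T", "TRUE", "1")
            else:
                kwargs[field] = val
        rec = TcrRecord(**kwargs)
        if rec.cdr3_nt and not rec.cdr3_aa and len(rec.cdr3_nt) % 3 == 0:
            rec.cdr3_aa = translate_nt(rec.cdr3_nt)
        rec.extra = {c: row[c] for c in unknown}
        records.append(rec)
    return records


def write_airr(records: Iterable[TcrRecord], path: PathLike) -> int:
    rows = []
    for rec in records:
        row = {
            "sequence_id": rec.read_id,
            "locus": rec.locus,
            "v_call": rec.v_call,
            "d_call": rec.d_call,
            "j_call": rec.j_call,
            "c_call": rec.c_call,
            "junction": rec.cdr3_nt,
            "junction_aa": rec.cdr3_aa,
            "v_identity": "" if math.isnan(rec.v_identity) else f"{rec.v_identity:.6g}",
            "j_identity": "" if math.isnan(rec.j_identity) else f"{rec.j_identity:.6g}",
            "cell_id": rec.barcode,
            "umi": rec.umi,
            "complete_vdj": "T" if rec.complete_vdj else "F",
        }
        row.update(rec.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return len(rows)


# ---------------------------------------------------------------------------
# Spot tables

_VISIUM_HEADER = {"barcode", "in_tissue", "array_row", "array_col"}


def read_spot_table(path: PathLike) -> SpotTable:
    """Read a spot-position CSV in either supported dialect.

    Visium ``tissue_positions`` dialect (coordinates taken from the
    pixel columns) or the simple ``barcode,x,y[,in_tissue][,n_cells]
    [,total_umis]`` dialect, detected by header.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if _VISIUM_HEADER <= cols:
        pxl_row = next((c for c in df.columns if c.startswith("pxl_row")), None)
        pxl_col = next((c for c in df.columns if c.startswith("pxl_col")), None)
        if pxl_row is None or pxl_col is None:
            raise SchemaError(f"{path}: Visium dialect without pxl_row/pxl_col columns")
        out = pd.DataFrame(
            {
                "barcode": df["barcode"],
                "x": df[pxl_col].astype(float),
                "y": df[pxl_row].astype(float),
                "in_tissue": df["in_tissue"].astype(int).astype(bool),
            }
        )
        for opt in ("n_cells", "total_umis"):
            if opt in cols:
                out[opt] = df[opt].astype(int)
    elif {"barcode", "x", "y"} <= cols:
        out = df
    else:
        raise SchemaError(
            f"{path}: header matches neither the Visium nor the simple spot dialect"
        )
    return SpotTable(out)


def write_spot_table(spots: SpotTable, path: PathLike) -> None:
    spots.df.to_csv(path, index=False)


def read_whitelist(path: PathLike) -> List[str]:
    """Read a barcode whitelist, one 16-mer per line."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            bc = line.strip()
            if not bc:
                continue
            if len(bc) != 16 or set(bc) - set("ACGT"):
                raise ParseError(f"{path}:{lineno}: invalid barcode {bc!r}")
            out.append(bc)
    return out


def write_whitelist(barcodes: Sequence[str], path: PathLike) -> None:
    Path(path).write_text("".join(b + "\n" for b in barcodes))


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_tsv(path: PathLike, spot_table: Optional[SpotTable] = None) -> pd.DataFrame:
    """Read a genes x spots TSV (first column = gene id)."""
    M = pd.read_csv(path, sep="\t", index_col=0)
    return validate_expression(M.astype(float), spot_table)


def write_expression_tsv(M: pd.DataFrame, path: PathLike) -> None:
    M.to_csv(path, sep="\t")


def read_expression_mtx(
    mtx_path: PathLike,
    genes_path: PathLike,
    barcodes_path: PathLike,
    spot_table: Optional[SpotTable] = None,
) -> pd.DataFrame:
    """Read a MatrixMarket expression matrix with gene/barcode sidecars."""
    mat = scipy.io.mmread(str(mtx_path))
    genes = [l.strip().split("\t")[0] for l in _open_text(genes_path) if l.strip()]
    barcodes = [l.strip().split("\t")[0] for l in _open_text(barcodes_path) if l.strip()]
    dense = mat.toarray() if scipy.sparse.issparse(mat) else mat
    if dense.shape != (len(genes), len(barcodes)):
        raise SchemaError(
            f"{mtx_path}: shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    M = pd.DataFrame(dense, index=genes, columns=barcodes, dtype=float)
    return validate_expression(M, spot_table)


def write_expression_mtx(
    M: pd.DataFrame, mtx_path: PathLike, genes_path: PathLike, barcodes_path: PathLike
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(M.values))
    Path(genes_path).write_text("".join(g + "\n" for g in M.index))
    Path(barcodes_path).write_text("".join(b + "\n" for b in M.columns))
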