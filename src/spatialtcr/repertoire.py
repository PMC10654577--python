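"""Clonotype calling and normalization.

Annotated, UMI-collapsed TCR records are filtered on CDR3 length and
UMI support, merged into clonotypes by connected components of the
CDR3 amino-acid Levenshtein graph, and normalized per spot by the
UMIs-per-cell factor UMI_c = (total spot UMIs) / (cells in the spot).

The merge radius follows the "minimal distance = 2" convention: two
CDR3s belong to the same clone when their edit distance is strictly
below 2 (i.e. at most one edit), which is exactly the complement of
treating CDR3s at distance >= 2 as unique clonotypes.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .model import Clone, SpotTable


class JoinError(KeyError):
    """A barcode required for normalization is absent from the spot table."""


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by dynamic programming.

    Implements the classic recursion (|y| when x is empty, |x| when y
    is empty, otherwise 1 + min over delete/insert/substitute, with a
    free step on equal heads) iteratively, row by row.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,  # delete from a
                    cur[j - 1] + 1,  # insert into a
                    prev[j - 1] + (ca != cb),  # substitute / match
                )
            )
        prev = cur
    return prev[-1]


#: Expected columns of a UMI-collapsed record table (one row per
#: (barcode, locus, cdr3_nt) group; see demux.collapse_to_umis).
RECORD_COLUMNS = [
    "barcode",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "cdr3_nt",
    "cdr3_aa",
    "v_identity",
    "j_identity",
    "umi_count",
]


def preprocess_tcr(
    records: pd.DataFrame,
    min_len: int = 5,
    max_len: int = 30,
    min_umi: int = 1,
    require_vj: bool = True,
) -> pd.DataFrame:
    """Filter collapsed records on CDR3 length, UMI support and calls.

    CDR3s containing a stop (``*``) or ambiguous (``X``) residue are
    dropped, as are empty CDR3s.
    """
    df = records.copy()
    aa = df["cdr3_aa"].fillna("")
    keep = (
        aa.str.len().between(min_len, max_len)
        & ~aa.str.contains(r"[*X]", regex=True)
        & (df["umi_count"] >= min_umi)
    )
    if require_vj:
        keep &= df["v_call"].fillna("").ne("") & df["j_call"].fillna("").ne("")
    return df[keep].reset_index(drop=True)


def cluster_cdr3(
    records: pd.DataFrame,
    min_dist: int = 2,
    require_same_v: bool = False,
) -> List[Clone]:
    """Merge CDR3s into clones by single-linkage at ``lev < min_dist``.

    Clustering is per locus (TRA and TRB never merge); with
    ``require_same_v`` the V call joins the grouping key as well.
    Per-clone identities are averaged over member records, per-spot
    UMI counts summed, and the representative is the longest member
    CDR3 (ties broken lexicographically).
    """
    clones: List[Clone] = []
    if records.empty:
        return clones
    group_cols = ["locus"] + (["v_call"] if require_same_v else [])
    for group_key, grp in records.groupby(group_cols, sort=True):
        locus = group_key[0] if isinstance(group_key, tuple) else group_key
        cdr3s = sorted(grp["cdr3_aa"].unique())
        G = nx.Graph()
        G.add_nodes_from(cdr3s)
        for i, a in enumerate(cdr3s):
            for b in cdr3s[i + 1 :]:
                if levenshtein(a, b) < min_dist:
                    G.add_edge(a, b)
        components = sorted(
            (sorted(comp) for comp in nx.connected_components(G)),
            key=lambda comp: comp[0],
        )
        for comp in components:
            members = set(comp)
            sub = grp[grp["cdr3_aa"].isin(members)]
            spot_umis: Dict[str, int] = (
                sub.groupby("barcode")["umi_count"].sum().astype(int).to_dict()
            )
            representative = max(sorted(members), key=len)
            clones.append(
                Clone(
                    clone_id="",  # assigned below, deterministically
                    locus=locus,
                    representative_cdr3_aa=representative,
                    members=members,
                    mean_v_identity=float(np.nanmean(sub["v_identity"].astype(float))),
                    mean_j_identity=float(np.nanmean(sub["j_identity"].astype(float))),
                    spot_umis=spot_umis,
                )
            )
    clones.sort(key=lambda c: (c.locus, -c.total_umis, c.representative_cdr3_aa))
    for i, c in enumerate(clones):
        c.clone_id = f"{c.locus}-{i:04d}"
    return clones


def clones_to_frame(clones: Iterable[Clone]) -> pd.DataFrame:
    """Summary table, one row per clone."""
    return pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "locus": c.locus,
                "representative_cdr3_aa": c.representative_cdr3_aa,
                "members": ";".join(sorted(c.members)),
                "mean_v_identity": c.mean_v_identity,
                "mean_j_identity": c.mean_j_identity,
                "total_umis": c.total_umis,
                "n_spots": c.n_spots,
            }
            for c in clones
        ]
    )


def clone_spot_counts(clones: Iterable[Clone]) -> pd.DataFrame:
    """Long-format per-spot UMI counts."""
    rows = [
        {"clone_id": c.clone_id, "barcode": b, "umi_count": n}
        for c in clones
        for b, n in sorted(c.spot_umis.items())
    ]
    return pd.DataFrame(rows, columns=["clone_id", "barcode", "umi_count"])


def normalize_tcr(
    clones: Iterable[Clone],
    spot_table: SpotTable,
    min_expr: int = 1,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Normalize per-spot clone UMI counts by UMIs-per-cell.

    UMI_c(b) = total_umis(b) / n_cells(b); normalized = raw / UMI_c.
    Spots with raw count below ``min_expr`` are excluded; spots with
    zero cells are excluded and tallied.  Returns (long table, tally).
    """
    meta = spot_table.df.set_index("barcode")
    rows = []
    tally = {"zero_cell_spots": 0, "below_min_expr": 0}
    for c in clones:
        for barcode, raw in sorted(c.spot_umis.items()):
            if barcode not in meta.index:
                raise JoinError(f"barcode {barcode!r} missing from spot table")
            if raw < min_expr:
                tally["below_min_expr"] += 1
                continue
            n_cells = int(meta.at[barcode, "n_cells"])
            if n_cells == 0:
                tally["zero_cell_spots"] += 1
                continue
            umi_c = float(meta.at[barcode, "total_umis"]) / n_cells
            rows.append(
                {
                    "clone_id": c.clone_id,
                    "barcode": barcode,
                    "raw": int(raw),
                    "normalized": raw / umi_c if umi_c > 0 else float("nan"),
                }
            )
    return (
        pd.DataFrame(rows, columns=["clone_id", "barcode", "raw", "normalized"]),
        tally,
    )
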