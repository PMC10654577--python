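"""Local cellular-ecosystem analytics around T-cell clones.

* Delaunay cell graph over (deconvolved) cell positions;
* cell-type-specific expression enhancement: per significant gene g
  an enhancer factor e_g = avg_log2FC_g + 1 scales the gene's row
  (M <- M + |M|*e_g), then a per-spot factor f' = f + (f-1)*e_bar with
  f = exp(cell-type score) rescales every gene (M <- M + |M|*(f'-1)),
  clipped at zero.  The neutral spec (e = 0, x = 0) is exactly the
  identity;
* clone x state matrices: a clone's column is the state-score vector
  of its single spot, or the sum over its spots;
* receptor-ligand spatial co-localization by Kullback-Leibler
  divergence between normalized spatial profiles (ligand as p,
  natural log), ranked ascending with the 100 lowest retained;
* a composite cytotoxic-vs-exhausted spot score from z-scored marker
  panels, evaluated only where TCRs are present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import Clone, SpotTable
from .spatial import SpatialGraph, delaunay_graph

CLONAL_MARKERS = [
    "IL2", "IFNG", "PRF1", "GZMB", "GZMK", "GZMA", "CD69", "CD25", "CD38",
]
EXHAUSTION_MARKERS = [
    "HAVCR2", "PDCD1", "CTLA4", "CXCL8", "LAG3", "EOMES", "TOX", "TIGIT",
    "CD244", "NR4A1",
]


#: Default ligand-receptor pairs (also shipped as data/rl_pairs.tsv,
#: user-editable; a custom table can be passed to rank_rl instead).
DEFAULT_RL_PAIRS: List[Tuple[str, str]] = [
    ("CD274", "PDCD1"),
    ("LGALS9", "HAVCR2"),
    ("CD80", "CTLA4"),
    ("IL2", "IL2RA"),
    ("IFNG", "IFNGR1"),
    ("CXCL8", "CXCR1"),
]


def load_rl_pairs(path=None) -> List[Tuple[str, str]]:
    """Load a ligand-receptor pair table (TSV: ligand, receptor)."""
    if path is None:
        from importlib.resources import files

        path = files("spatialtcr.data") / "rl_pairs.tsv"
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["ligand"], df["receptor"]))


class ConfigError(ValueError):
    pass


class ProfileError(ValueError):
    """A spatial expression profile is identically zero."""


def create_cell_graph(
    cells: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    prune_factor: float = 3.0,
) -> SpatialGraph:
    """Delaunay cell graph over cells of the selected feature labels.

    ``cells`` needs columns barcode, x, y and (if ``features`` is
    given) feature.  Each edge carries its barcode pair.
    """
    df = cells.copy()
    if features is not None:
        df = df[df["feature"].isin(list(features))]
    table = SpotTable(
        pd.DataFrame(
            {"barcode": df["barcode"], "x": df["x"], "y": df["y"], "in_tissue": True}
        )
    )
    return delaunay_graph(table, prune_factor=prune_factor)


def enhance_celltype_expression(
    M: pd.DataFrame,
    enhancer: Dict[str, float],
    celltype_scores: Union[pd.Series, pd.DataFrame],
    mode: str = "single",
) -> pd.DataFrame:
    """Enhance cell-type-specific expression in a genes x spots matrix.

    ``enhancer`` maps each significant gene to its avg_log2FC (the
    factor applied is e = avg_log2FC + 1).  ``celltype_scores`` is a
    per-spot score vector (single mode) or a cell-types x spots frame
    (multi mode, where f is the mean of exp(score) over cell types).
    The result is clipped at zero.
    """
    missing = sorted(set(enhancer) - set(M.index))
    if missing:
        raise ConfigError(f"enhancer genes absent from matrix: {missing}")
    if mode not in ("single", "multi"):
        raise ConfigError(f"unknown mode {mode!r}")
    out = M.astype(float).copy()
    e = pd.Series({g: fc + 1.0 for g, fc in enhancer.items()}, dtype=float)

    # step 1: row scaling of the significant genes
    genes = list(e.index)
    sub = out.loc[genes]
    out.loc[genes] = sub + sub.abs().mul(e, axis=0)

    # step 2: per-spot scaling of every gene
    if mode == "single":
        x = pd.Series(celltype_scores, dtype=float).reindex(out.columns)
        if x.isna().any():
            raise ConfigError("celltype_scores missing spots present in matrix")
        f = np.exp(x)
    else:
        scores = pd.DataFrame(celltype_scores).reindex(columns=out.columns)
        if scores.isna().any().any():
            raise ConfigError("celltype_scores missing spots present in matrix")
        f = np.exp(scores.astype(float)).mean(axis=0)
    e_bar = float(e.mean()) if len(e) else 0.0
    f_prime = f + (f - 1.0) * e_bar
    out = out + out.abs().mul(f_prime - 1.0, axis=1)
    return out.clip(lower=0.0)


def clone_state_matrix(
    state_scores: pd.DataFrame, clones: Sequence[Clone]
) -> pd.DataFrame:
    """States x clones matrix of summed state scores over clone spots.

    A clone detected in a single spot inherits that spot's state
    scores exactly; a multi-spot clone sums scores over its spots.
    """
    missing = sorted(
        {b for c in clones for b in c.spot_umis} - set(state_scores.columns)
    )
    if missing:
        raise ConfigError(f"clone spots without state scores: {missing[:5]}")
    cols = {}
    for c in clones:
        support = sorted(c.spot_umis)
        cols[c.clone_id] = state_scores[support].sum(axis=1)
    return pd.DataFrame(cols, index=state_scores.index)


def rl_kld(
    ligand_profile: pd.Series,
    receptor_profile: pd.Series,
    pseudocount: float = 1e-9,
) -> float:
    """KLD (nats) between ligand and receptor spatial profiles.

    Profiles are shifted by the pseudocount and normalized to sum 1;
    KL(p || q) with the ligand as p.  Zero iff the normalized
    profiles are identical.
    """
    p = pd.Series(ligand_profile, dtype=float)
    q = pd.Series(receptor_profile, dtype=float).reindex(p.index)
    if q.isna().any():
        raise ProfileError("profiles cover different spot sets")
    for name, prof in (("ligand", p), ("receptor", q)):
        if float(prof.sum()) == 0.0:
            gene = prof.name or name
            raise ProfileError(f"all-zero spatial profile for {gene}")
    p = (p + pseudocount) / (p + pseudocount).sum()
    q = (q + pseudocount) / (q + pseudocount).sum()
    return float(np.sum(p * np.log(p / q)))


def rank_rl(
    pairs: Iterable[Tuple[str, str]],
    M: pd.DataFrame,
    pseudocount: float = 1e-9,
    top: int = 100,
) -> pd.DataFrame:
    """Score and rank ligand-receptor pairs by ascending KLD.

    Pairs whose genes are absent from the matrix are dropped and
    counted in the ``n_skipped`` attribute of the result.  Ties are
    broken by the lexicographic (ligand, receptor) pair; the first
    ``top`` rows are returned (all, if fewer).
    """
    rows = []
    skipped = 0
    for ligand, receptor in pairs:
        if ligand not in M.index or receptor not in M.index:
            skipped += 1
            continue
        kld = rl_kld(M.loc[ligand], M.loc[receptor], pseudocount=pseudocount)
        rows.append({"ligand": ligand, "receptor": receptor, "kld": kld})
    out = pd.DataFrame(rows, columns=["ligand", "receptor", "kld"])
    out = out.sort_values(
        ["kld", "ligand", "receptor"], kind="mergesort"
    ).head(top).reset_index(drop=True)
    out.attrs["n_skipped"] = skipped
    return out


def composite_tcell_score(
    M: pd.DataFrame,
    tcr_presence: pd.Series,
    clonal_markers: Sequence[str] = tuple(CLONAL_MARKERS),
    exhaustion_markers: Sequence[str] = tuple(EXHAUSTION_MARKERS),
) -> pd.DataFrame:
    """Composite cytotoxic/exhausted spot classification.

    Every marker row is z-scored across spots (constant rows are
    skipped and tallied); the clonal and exhaustion scores are the
    unweighted means of the z-scores over the respective panels.
    Spots without TCR presence are unscored; otherwise a spot is
    productive when its clonal score exceeds its exhaustion score and
    exhausted otherwise (ties included).
    """

    def z_rows(markers: Sequence[str]) -> Tuple[pd.DataFrame, List[str]]:
        present = [g for g in markers if g in M.index]
        absent = [g for g in markers if g not in M.index]
        if absent:
            warnings.warn(f"markers absent from matrix, skipped: {absent}")
        rows, flat = [], []
        for g in present:
            row = M.loc[g].astype(float)
            sd = float(row.std(ddof=0))
            if sd == 0.0:
                flat.append(g)
                continue
            rows.append((row - row.mean()) / sd)
        return pd.DataFrame(rows), flat

    clonal_z, clonal_flat = z_rows(clonal_markers)
    exhaust_z, exhaust_flat = z_rows(exhaustion_markers)
    if clonal_z.empty and exhaust_z.empty:
        raise ConfigError("no usable marker genes found in matrix")
    presence = pd.Series(tcr_presence).reindex(M.columns).fillna(False).astype(bool)
    clonal_score = clonal_z.mean(axis=0) if not clonal_z.empty else pd.Series(0.0, index=M.columns)
    exhaustion_score = exhaust_z.mean(axis=0) if not exhaust_z.empty else pd.Series(0.0, index=M.columns)
    labels = np.where(
        ~presence,
        "unscored",
        np.where(clonal_score > exhaustion_score, "productive", "exhausted"),
    )
    out = pd.DataFrame(
        {
            "clonal_score": clonal_score,
            "exhaustion_score": exhaustion_score,
            "label": labels,
        },
        index=M.columns,
    )
    out.attrs["skipped_constant_markers"] = clonal_flat + exhaust_flat
    return out


def plot_spots(
    spot_table: SpotTable,
    values: pd.Series,
    path=None,
    title: str = "",
):  # pragma: no cover - convenience plotting
    """Minimal spatial scatter of a per-spot quantity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = spot_table.in_tissue()
    v = pd.Series(values).reindex(df["barcode"]).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(df["x"], df["y"], c=v, s=25, cmap="viridis")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_aspect("equal")
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
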