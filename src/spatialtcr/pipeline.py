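"""End-to-end pipeline: simulate -> demux -> orient -> annotate ->
correct -> repertoire -> spatial -> ecosystem.

Every stage consumes only files/objects produced by the previous
stage or the run configuration; stage-by-stage record counts are
logged into a waterfall table and the run is idempotent given the
seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import correct as _correct
from . import demux as _demux
from . import ecosystem as _ecosystem
from . import io as _io
from . import orient as _orient
from . import repertoire as _repertoire
from . import simulate as _simulate
from . import spatial as _spatial

logger = logging.getLogger("spatialtcr")


class ConfigError(ValueError):
    pass


#: Allowed configuration keys per section, with defaults where they
#: differ from the library-function defaults.
_SCHEMA: Dict[str, Dict[str, Any]] = {
    "simulate": {
        "n_spots": 100,
        "n_clones": 20,
        "pattern_mix": {"expanded": 0.5, "dispersed": 0.5},
        "mean_reads_per_umi": 3.0,
        "sub_rate": _simulate.DEFAULT_SUB_RATE,
        "ins_rate": _simulate.DEFAULT_INS_RATE,
        "del_rate": _simulate.DEFAULT_DEL_RATE,
        "leader_len": 350,
        "umi_lambda": 1.0,
        "reads_per_clone": None,
    },
    "demux": {"max_dist": 2},
    "orient": {"max_dist": 4},
    "annotate": {"score_threshold": _annotate.SCORE_THRESHOLD},
    "correct": {
        "k": 11,
        "min_jaccard": 0.35,
        "min_junction_identity": 0.7,
        "n_refine": 2,
        "max_error": 0.35,
    },
    "repertoire": {
        "min_len": 5,
        "max_len": 30,
        "min_umi": 1,
        "require_vj": True,
        "min_dist": 2,
        "require_same_v": False,
        "min_expr": 1,
    },
    "spatial": {
        "prune_factor": 3.0,
        "min_umi": 5,
        "umi_threshold": 5,
        "clonality_threshold": 1.0,
        "diversity_threshold": 3.0,
        "min_clones_diverse": 2,
        "reciprocal": False,
    },
    "ecosystem": {"n_background_genes": 40},
}


@dataclass
class RunConfig:
    """Validated nested run configuration; unknown keys are rejected."""

    seed: int
    sections: Dict[str, Dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ConfigError("config requires a 'seed'")
        seed = int(raw.pop("seed"))
        sections: Dict[str, Dict[str, Any]] = {}
        for name, params in raw.items():
            if name not in _SCHEMA:
                raise ConfigError(f"unknown config section {name!r}")
            params = dict(params or {})
            unknown = set(params) - set(_SCHEMA[name])
            if unknown:
                raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
            sections[name] = params
        return cls(seed=seed, sections=sections)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def section(self, name: str) -> Dict[str, Any]:
        merged = dict(_SCHEMA[name])
        merged.update(self.sections.get(name, {}))
        return merged

    def resolved(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {"seed": self.seed}
        for name in _SCHEMA:
            out[name] = self.section(name)
        return out


def run_all(config: RunConfig, outdir) -> Dict[str, Any]:
    """Execute the full pipeline into ``outdir``; returns the report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {"seed": config.seed, "stages": {}, "waterfall": {}}
    t0 = time.time()

    def stage_done(name: str, count: int) -> None:
        dt = time.time() - t0
        report["stages"][name] = {"seconds": round(dt, 2)}
        report["waterfall"][name] = count
        logger.info("stage %s done: %d records (%.1fs)", name, count, dt)

    # --- simulate
    sim = config.section("simulate")
    reads_per_clone = sim.pop("reads_per_clone")
    if reads_per_clone is not None:
        reads_per_clone = tuple(int(v) for v in reads_per_clone)
    bundle = _simulate.simulate_repertoire(
        seed=config.seed, reads_per_clone=reads_per_clone, **sim
    )
    reads, truth = _simulate.emit_reads(bundle)
    _io.write_fastq(reads, out / "reads.fastq")
    _io.write_spot_table(bundle.spot_table, out / "spots.csv")
    _io.write_whitelist(bundle.whitelist, out / "whitelist.txt")
    bundle.refs.to_fasta(out / "references.fasta")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    stage_done("simulate", len(reads))

    # --- demux
    assignments = _demux.demux_reads(
        reads, bundle.whitelist, **config.section("demux")
    )
    _demux.assignments_to_frame(assignments).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    assigned_parents = {a.read_id for a in assignments if a.assigned}
    stage_done("demux", len(assigned_parents))

    # --- orient
    inserts, orient_stats = _orient.orient_reads(
        reads, max_dist=config.section("orient")["max_dist"]
    )
    report["orient_stats"] = orient_stats
    _io.write_fastq(
        (
            _io.Read(iid, seq, "I" * len(seq))
            for iid, seq in sorted(inserts.items())
        ),
        out / "inserts.fastq",
    )
    # waterfall tracks reads surviving every stage so far (assigned AND
    # oriented); all reads are still carried forward for correction
    n_surviving = len(
        {iid.split("/")[0] for iid in inserts} & assigned_parents
    )
    stage_done("orient", n_surviving)

    # --- annotate (pre-correction)
    records = _annotate.annotate_inserts(
        inserts, bundle.refs, **config.section("annotate")
    )
    _io.write_airr(records, out / "airr_uncorrected.tsv")
    n_vdj = len(
        {r.read_id.split("/")[0] for r in records if r.complete_vdj}
        & assigned_parents
    )
    stage_done("annotate", n_vdj)

    # --- correct
    corr_cfg = config.section("correct")
    max_error = corr_cfg.pop("max_error")
    corrected, clusters = _correct.correct_inserts(inserts, records, **corr_cfg)
    error_report = _correct.measure_error(
        inserts, corrected, bundle.refs, max_error=max_error
    )
    (out / "error_report.json").write_text(
        json.dumps(error_report.summary(), indent=2)
    )
    corrected_records = _annotate.annotate_inserts(
        corrected, bundle.refs, **config.section("annotate")
    )
    _io.write_airr(corrected_records, out / "airr_corrected.tsv")
    stage_done("correct_clusters", len(clusters))

    # --- collapse + repertoire
    by_insert = []
    amap = {a.read_id: a for a in assignments}
    for rec in corrected_records:
        parent = rec.read_id.split("/")[0]
        a = amap.get(parent)
        if a is not None and a.assigned:
            by_insert.append(
                _demux.BarcodeAssignment(
                    rec.read_id, a.barcode, a.umi, a.edit_distance, a.anchor_strand
                )
            )
    collapsed = _demux.collapse_to_umis(by_insert, corrected_records)
    collapsed.to_csv(out / "umi_counts.tsv", sep="\t", index=False)
    rep_cfg = config.section("repertoire")
    filtered = _repertoire.preprocess_tcr(
        collapsed,
        min_len=rep_cfg["min_len"],
        max_len=rep_cfg["max_len"],
        min_umi=rep_cfg["min_umi"],
        require_vj=rep_cfg["require_vj"],
    )
    clones = _repertoire.cluster_cdr3(
        filtered, min_dist=rep_cfg["min_dist"], require_same_v=rep_cfg["require_same_v"]
    )
    _repertoire.clones_to_frame(clones).to_csv(
        out / "clones.tsv", sep="\t", index=False
    )
    _repertoire.clone_spot_counts(clones).to_csv(
        out / "clone_spot_counts.tsv", sep="\t", index=False
    )
    normalized, norm_tally = _repertoire.normalize_tcr(
        clones, bundle.spot_table, min_expr=rep_cfg["min_expr"]
    )
    normalized.to_csv(out / "clone_counts_normalized.tsv", sep="\t", index=False)
    report["normalize_tally"] = norm_tally
    stage_done("clones", len(clones))

    # --- spatial
    sp_cfg = config.section("spatial")
    graph = _spatial.delaunay_graph(
        bundle.spot_table, prune_factor=sp_cfg["prune_factor"]
    )
    graph.to_frame().to_csv(out / "spot_graph.tsv", sep="\t", index=False)
    stats = _spatial.clonality_index(graph, clones)
    pd.DataFrame(
        [
            {
                "clone_id": s.clone_id,
                "clonality_index": s.clonality_index,
                "clonality_sum": s.clonality_sum,
                "n_spots": s.n_spots,
            }
            for s in stats
        ]
    ).to_csv(out / "clone_spatial_stats.tsv", sep="\t", index=False)
    metrics = _spatial.spot_metrics(
        clones,
        spot_table=bundle.spot_table,
        min_umi=sp_cfg["min_umi"],
        reciprocal=sp_cfg["reciprocal"],
    )
    labeled = _spatial.classify_spots(
        metrics,
        stats,
        clones,
        umi_threshold=sp_cfg["umi_threshold"],
        clonality_threshold=sp_cfg["clonality_threshold"],
        diversity_threshold=sp_cfg["diversity_threshold"],
        min_clones_diverse=sp_cfg["min_clones_diverse"],
    )
    labeled.to_csv(out / "spot_metrics.tsv", sep="\t", index=False)
    stage_done("spots_labeled", int((labeled["label"] != "none").sum()))

    # --- ecosystem
    eco_cfg = config.section("ecosystem")
    M = _simulate.simulate_expression(
        bundle, n_background_genes=eco_cfg["n_background_genes"]
    )
    _io.write_expression_tsv(M, out / "expression.tsv")
    presence = labeled.set_index("barcode")["total_tcr_umis"] > 0
    composite = _ecosystem.composite_tcell_score(M, presence)
    composite.to_csv(out / "composite_scores.tsv", sep="\t")
    state_scores = pd.DataFrame(
        {
            "cytotoxic": composite["clonal_score"].clip(lower=0.0),
            "exhausted": composite["exhaustion_score"].clip(lower=0.0),
        }
    ).T
    if clones:
        csm = _ecosystem.clone_state_matrix(state_scores, clones)
        csm.to_csv(out / "clone_state_matrix.tsv", sep="\t")
    rl = _ecosystem.rank_rl(_simulate.DEFAULT_RL_PAIRS, M)
    rl.to_csv(out / "rl_scores.tsv", sep="\t", index=False)
    stage_done("ecosystem_rl_pairs", len(rl))

    report["error_summary"] = error_report.summary()
    report["config"] = config.resolved()
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
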