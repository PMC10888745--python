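"""File-based pipeline orchestration.

A single YAML config drives the end-to-end run: per-cell contrasts and
DEG selection, the cross-cell Venn partition, library scoring, drug
ranking, target extraction and over-representation analysis. Every stage
reads and writes plain text (TSV / JSON), so each is independently
re-runnable from its serialized inputs, and an identical config plus
identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .connectivity import ORDERED, ConnectivityRecord, build_query, records_to_frame, score_library
from .differential import ContrastTable, DEGSet, contrast, overlap_degs, select_degs
from .enrichment import merge_gene_sets, ora
from .errors import PipelineError, ValidationError
from .io import (
    DrugTargetTable,
    filter_library,
    read_drug_targets,
    read_expression_gct,
    read_gmt,
    read_signature_library,
)
from .repositioning import (
    REQUIRE_ALL_CELLS,
    DrugScore,
    aggregate_by_drug,
    extract_targets,
    scores_to_frame,
    top_k,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (see ``from_yaml``)."""

    expression: dict[str, str]  # cell line -> matrix path
    library_matrix: str
    library_meta: str
    drug_targets: str
    gene_sets: str
    out_dir: str
    groups: dict[str, dict[str, str]] = field(default_factory=dict)
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    mode: str = ORDERED
    k: int = 10
    policy: str = REQUIRE_ALL_CELLS
    match_dose: str | None = None
    match_time: str | None = None
    approved_only: bool = False
    m_max: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValidationError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def input_paths(self) -> list[str]:
        return [
            *self.expression.values(),
            self.library_matrix,
            self.library_meta,
            self.drug_targets,
            self.gene_sets,
        ]

    def validate_paths(self) -> None:
        missing = [p for p in self.input_paths() if not Path(p).exists()]
        if missing:
            raise PipelineError("config", f"missing input paths: {missing}")


def _infer_groups(cfg: RunConfig, cell: str, sample_ids: list[str]) -> dict[str, str]:
    if cell in cfg.groups:
        return cfg.groups[cell]
    inferred = {}
    for s in sample_ids:
        if "_ctrl" in s:
            inferred[s] = "control"
        elif "_trt" in s:
            inferred[s] = "treated"
        else:
            raise PipelineError(
                "contrast",
                f"cannot infer group of sample {s!r} for {cell}; provide cfg.groups",
            )
    return inferred


def _read_sample_header(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#1."):
            fh.readline()
            header = fh.readline()
            return header.rstrip("\n").split("\t")[2:]
        return first.rstrip("\n").split("\t")[1:]


# ---------------------------------------------------------------------------
# stages (file -> file, independently re-runnable)
# ---------------------------------------------------------------------------

def stage_contrast(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for cell, path in sorted(cfg.expression.items()):
        groups = _infer_groups(cfg, cell, _read_sample_header(path))
        mat = read_expression_gct(path, groups, cell_line=cell)
        ct = contrast(mat, cell)
        ct.to_tsv(out / f"contrasts_{cell}.tsv")
        degs = select_degs(ct, cfg.fc_cutoff, cfg.p_cutoff)
        frame = pd.DataFrame(
            {
                "gene_id": degs.up + degs.down,
                "direction": ["up"] * len(degs.up) + ["down"] * len(degs.down),
            }
        )
        frame.to_csv(out / f"degs_{cell}.tsv", sep="\t", index=False, lineterminator="\n")
        counts[cell] = {"genes": len(ct.table), "up": len(degs.up), "down": len(degs.down)}
        logger.info("contrast %s: %d up, %d down", cell, len(degs.up), len(degs.down))
    return counts


def _load_degsets(cfg: RunConfig) -> list[DEGSet]:
    out = Path(cfg.out_dir)
    sets = []
    for cell in sorted(cfg.expression):
        frame = pd.read_csv(out / f"degs_{cell}.tsv", sep="\t", dtype=str)
        up = frame.loc[frame["direction"] == "up", "gene_id"].tolist()
        down = frame.loc[frame["direction"] == "down", "gene_id"].tolist()
        sets.append(DEGSet(cell, up, down, cfg.fc_cutoff, cfg.p_cutoff))
    return sets


def stage_venn(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    degsets = _load_degsets(cfg)
    counts = {}
    for direction in ("up", "down"):
        regions = overlap_degs(degsets, direction)
        payload = {
            "direction": direction,
            "regions": regions,
            "counts": {k: len(v) for k, v in regions.items()},
        }
        with open(out / f"venn_{direction}.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        counts[direction] = payload["counts"]
    return counts


def _load_contrast(cfg: RunConfig, cell: str) -> ContrastTable:
    frame = pd.read_csv(
        Path(cfg.out_dir) / f"contrasts_{cell}.tsv", sep="\t", index_col=0
    )
    frame["flag"] = frame["flag"].fillna("")
    return ContrastTable(frame, cell)


def stage_score(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    lib = read_signature_library(cfg.library_matrix, cfg.library_meta)
    drug_table = read_drug_targets(cfg.drug_targets)
    counts = {}
    for cell in sorted(cfg.expression):
        ct = _load_contrast(cfg, cell)
        query = build_query(
            ct, lib.landmark_genes, m_max=cfg.m_max,
            fc_cutoff=cfg.fc_cutoff, p_cutoff=cfg.p_cutoff, mode=cfg.mode,
        )
        sub = filter_library(
            lib, cell_line=cell, dose=cfg.match_dose, time=cfg.match_time,
            approved_only=cfg.approved_only,
            drug_map=drug_table if cfg.approved_only else None,
        )
        records = score_library(sub, query)
        records_to_frame(records).to_csv(
            out / f"scores_{cell}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        counts[cell] = {"query_size": query.m, "signatures": len(records)}
    return counts


def _load_records(cfg: RunConfig) -> list[ConnectivityRecord]:
    records = []
    for cell in sorted(cfg.expression):
        frame = pd.read_csv(Path(cfg.out_dir) / f"scores_{cell}.tsv", sep="\t")
        for row in frame.itertuples(index=False):
            records.append(
                ConnectivityRecord(
                    row.signature_id, row.perturbagen_id, row.cell_line,
                    float(row.c), int(row.m_eff), bool(row.ok),
                )
            )
    return records


def stage_rank(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    drug_table = read_drug_targets(cfg.drug_targets)
    scores = aggregate_by_drug(
        _load_records(cfg), drug_table, policy=cfg.policy,
        cell_lines=sorted(cfg.expression),
    )
    scores_to_frame(scores).to_csv(
        out / "ranked_drugs.tsv", sep="\t", index=False, lineterminator="\n"
    )
    return {"drugs_ranked": len(scores)}


def _load_scores(cfg: RunConfig) -> list[DrugScore]:
    frame = pd.read_csv(Path(cfg.out_dir) / "ranked_drugs.tsv", sep="\t")
    cell_cols = [c for c in frame.columns if c.startswith("score_")]
    scores = []
    for row in frame.itertuples(index=False):
        cells = {c[len("score_"):]: getattr(row, c) for c in cell_cols}
        cells = {k: float(v) for k, v in cells.items() if pd.notna(v)}
        scores.append(DrugScore(row.drug_id, row.drug_name, cells, float(row.mean_score), int(row.rank)))
    return scores


def stage_targets(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    drug_table = read_drug_targets(cfg.drug_targets)
    top = top_k(_load_scores(cfg), cfg.k)
    targets = extract_targets(top, drug_table)
    targets.to_json(out / "targets.json")
    return {"top_drugs": len(top), "unique_targets": targets.size}


def stage_enrich(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    sets = read_gmt(cfg.gene_sets)
    degsets = _load_degsets(cfg)
    universe = sorted(
        set().union(*(
            pd.read_csv(out / f"contrasts_{cell}.tsv", sep="\t", index_col=0).index
            for cell in sorted(cfg.expression)
        ))
    )
    counts = {}
    for direction in ("up", "down"):
        merged = merge_gene_sets(degsets, direction)
        if merged:
            table = ora(merged, sets, universe)
        else:
            table = pd.DataFrame()
            logger.warning("enrich: no %s-regulated genes to test", direction)
        table.to_csv(
            out / f"enrichment_{direction}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        counts[direction] = {
            "merged_genes": len(merged),
            "significant_sets": int((table["p_value"] < 0.05).sum()) if len(table) else 0,
        }
    return counts


_STAGES = [
    ("contrast", stage_contrast),
    ("venn", stage_venn),
    ("score", stage_score),
    ("rank", stage_rank),
    ("targets", stage_targets),
    ("enrich", stage_enrich),
]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order and write a machine-readable report.

    Returns the report dict (also written to ``<out_dir>/report.json``);
    any stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg.validate_paths()
    report: dict = {
        "sigconn_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": [],
    }
    for name, fn in _STAGES:
        try:
            counts = fn(cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        report["stages"].append({"stage": name, "counts": counts})
        logger.info("stage %s done: %s", name, counts)
    report["stages"].append(
        {"stage": "report", "counts": {"n_stages": len(_STAGES)}}
    )
    with open(Path(cfg.out_dir) / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
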