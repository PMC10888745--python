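"""Cross-cell-line drug ranking and target extraction.

Connectivity records are aggregated per drug: replicate signatures within
one cell line collapse to their arithmetic mean, then the per-cell scores
average across cell lines. Drugs are ranked by descending mean score, the
top k taken, and the unique antagonist/inhibitor target proteins of those
drugs extracted from a drug–target table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityRecord
from .errors import ParameterError, ValidationError
from .io import DrugTargetTable

logger = logging.getLogger(__name__)

REQUIRE_ALL_CELLS = "require_all_cells"
MEAN_AVAILABLE = "mean_available"
POLICIES = (REQUIRE_ALL_CELLS, MEAN_AVAILABLE)

#: Pharmacological actions treated as inhibition for target extraction.
INHIBITORY_ACTIONS = frozenset({"inhibitor", "antagonist"})


@dataclass
class DrugScore:
    """Aggregated connectivity of one drug across cell lines."""

    drug_id: str
    drug_name: str
    cell_scores: dict[str, float]
    mean_score: float
    rank: int = 0


@dataclass
class TargetEntry:
    gene_symbol: str
    uniprot_id: str
    protein_name: str
    source_drugs: list[str]


@dataclass
class TargetSet:
    """Unique target proteins of a set of drugs, keyed by gene symbol."""

    entries: list[TargetEntry]

    def __post_init__(self) -> None:
        symbols = [e.gene_symbol for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("target gene symbols must be unique")

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def to_json(self, path) -> None:
        payload = [
            {
                "gene_symbol": e.gene_symbol,
                "uniprot_id": e.uniprot_id,
                "protein_name": e.protein_name,
                "source_drugs": e.source_drugs,
            }
            for e in self.entries
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"size": self.size, "targets": payload}, fh, indent=2)


def aggregate_by_drug(
    records: list[ConnectivityRecord],
    drug_map: DrugTargetTable,
    policy: str = REQUIRE_ALL_CELLS,
    cell_lines: list[str] | None = None,
) -> list[DrugScore]:
    """Aggregate per-signature scores to ranked per-drug mean scores.

    Replicate signatures of a drug within one cell line collapse to their
    arithmetic mean first; the per-cell scores then average across cell
    lines. Under ``require_all_cells`` a drug missing any cell line (from
    ``cell_lines``, defaulting to all cell lines observed in the records)
    is excluded. Records whose perturbagen maps to no drug are excluded
    with a logged count, as are records flagged not-ok.
    """
    if policy not in POLICIES:
        raise ParameterError(f"policy must be one of {POLICIES}, got {policy!r}")
    usable = [r for r in records if r.ok]
    rows = []
    n_unmapped = 0
    for r in usable:
        drug_id = drug_map.drug_for_perturbagen(r.perturbagen_id)
        if drug_id is None:
            n_unmapped += 1
            continue
        rows.append((drug_id, r.cell_line, r.c))
    if n_unmapped:
        logger.info("aggregate_by_drug: %d records with unmapped perturbagens excluded", n_unmapped)
    if not rows:
        return []
    frame = pd.DataFrame(rows, columns=["drug_id", "cell_line", "c"])
    per_cell = frame.groupby(["drug_id", "cell_line"])["c"].mean()
    all_cells = cell_lines if cell_lines is not None else sorted(frame["cell_line"].unique())

    names = {}
    if "drug_name" in drug_map.table.columns:
        names = (
            drug_map.table.drop_duplicates("drug_id").set_index("drug_id")["drug_name"].to_dict()
        )

    scores: list[DrugScore] = []
    for drug_id, cell_map in per_cell.groupby(level=0):
        cells = {cl: float(v) for (_, cl), v in cell_map.items()}
        if policy == REQUIRE_ALL_CELLS and set(cells) != set(all_cells):
            logger.info(
                "aggregate_by_drug: drug %s missing cell lines %s; excluded",
                drug_id, sorted(set(all_cells) - set(cells)),
            )
            continue
        mean = float(np.mean(list(cells.values())))
        scores.append(DrugScore(drug_id, names.get(drug_id, drug_id), cells, mean))
    # descending mean score, ties broken by drug id for determinism
    scores.sort(key=lambda d: (-d.mean_score, d.drug_id))
    for i, d in enumerate(scores, start=1):
        d.rank = i
    return scores


def top_k(scores: list[DrugScore], k: int = 10) -> list[DrugScore]:
    """First k drugs by descending mean score (ties already broken by id)."""
    if k < 0:
        raise ParameterError("k must be >= 0")
    if k > len(scores):
        logger.warning("top_k: k=%d exceeds %d ranked drugs; returning all", k, len(scores))
    return scores[:k]


def extract_targets(
    top: list[DrugScore],
    table: DrugTargetTable,
    actions: frozenset[str] | set[str] = INHIBITORY_ACTIONS,
) -> TargetSet:
    """Unique target proteins of the top drugs, restricted by action.

    Targets deduplicate by gene symbol; each entry records which top drugs
    contribute it. A top drug absent from the table contributes nothing
    (logged).
    """
    entries: dict[str, TargetEntry] = {}
    known_drugs = set(table.table["drug_id"])
    for drug in top:
        if drug.drug_id not in known_drugs:
            logger.info("extract_targets: drug %s absent from the target table", drug.drug_id)
            continue
        for _, row in table.targets_of(drug.drug_id, actions).iterrows():
            sym = row["target_gene_symbol"]
            if sym in entries:
                if drug.drug_id not in entries[sym].source_drugs:
                    entries[sym].source_drugs.append(drug.drug_id)
            else:
                entries[sym] = TargetEntry(
                    gene_symbol=sym,
                    uniprot_id=row["target_uniprot_id"],
                    protein_name=row.get("target_protein_name", ""),
                    source_drugs=[drug.drug_id],
                )
    return TargetSet(sorted(entries.values(), key=lambda e: e.gene_symbol))


def scores_to_frame(scores: list[DrugScore]) -> pd.DataFrame:
    """Tabulate ranked drug scores for TSV serialization."""
    cells = sorted({cl for d in scores for cl in d.cell_scores})
    data = {
        "rank": [d.rank for d in scores],
        "drug_id": [d.drug_id for d in scores],
        "drug_name": [d.drug_name for d in scores],
        "mean_score": [d.mean_score for d in scores],
    }
    for cl in cells:
        data[f"score_{cl}"] = [d.cell_scores.get(cl, np.nan) for d in scores]
    return pd.DataFrame(data)
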