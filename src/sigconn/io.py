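"""Data model and text I/O for every tabular artifact the pipeline touches.

Formats supported:

* expression matrices — GCT 1.2 (``#1.2`` header) or a headerless TSV
  dialect with gene identifiers in column 1 and sample identifiers on the
  first row;
* reference signature libraries — a genes x signatures matrix (GCT or TSV)
  plus a signature metadata TSV (perturbagen, cell line, dose, time);
* gene-set collections — Broad GMT;
* drug–target tables — TSV with a closed pharmacological-action vocabulary.

All readers validate on construction; all I/O is UTF-8 with ``.`` as the
decimal separator regardless of locale.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
GROUPS = frozenset({CONTROL, TREATED})

#: Closed vocabulary of pharmacological actions for drug–target edges.
ACTIONS = frozenset({"inhibitor", "antagonist", "agonist", "other"})

#: DrugBank-style accession embedded in LINCS compound ids, e.g.
#: ``BRD-K33106058_DB00987`` maps implicitly to drug ``DB00987``.
_DRUGBANK_SUFFIX = re.compile(r"_(DB\d+)$")


# ---------------------------------------------------------------------------
# quantity (dose / time) normalization
# ---------------------------------------------------------------------------

_UNIT_ALIASES = {
    "um": "um", "µm": "um", "μm": "um", "micromolar": "um",
    "nm": "nm", "nanomolar": "nm",
    "mm": "mm", "millimolar": "mm",
    "h": "h", "hr": "h", "hrs": "h", "hour": "h", "hours": "h",
    "min": "min", "minute": "min", "minutes": "min",
}

_QUANTITY_RE = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*(\S+)\s*$")


def parse_quantity(text: str) -> tuple[float, str]:
    """Parse ``"10 uM"``-style value+unit strings.

    Units are normalized case-insensitively ("uM" == "µM", "h" == "hr").
    """
    m = _QUANTITY_RE.match(str(text))
    if m is None:
        raise FormatError(f"cannot parse quantity {text!r} (expected '<value> <unit>')")
    value = float(m.group(1))
    unit = m.group(2).lower()
    return value, _UNIT_ALIASES.get(unit, unit)


def quantities_equal(a: str, b: str, rel_tol: float = 1e-9) -> bool:
    va, ua = parse_quantity(a)
    vb, ub = parse_quantity(b)
    return ua == ub and math.isclose(va, vb, rel_tol=rel_tol, abs_tol=0.0)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples intensity table with control/treated group labels.

    Parameters
    ----------
    values
        DataFrame of non-negative finite intensities, genes on the index,
        samples on the columns.
    sample_groups
        Map sample id -> ``"control"`` or ``"treated"``; every sample must
        be labelled.
    cell_line
        Optional label for the cell line the samples came from.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    cell_line: str | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            raise ValidationError("duplicate sample ids")
        missing = [s for s in cols if s not in self.sample_groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        bad = set(self.sample_groups.values()) - GROUPS
        if bad:
            raise ValidationError(f"unknown group labels {sorted(bad)}; allowed: {sorted(GROUPS)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression intensities must be finite")
        if (arr < 0).any():
            raise ValidationError("expression intensities must be >= 0")
        groups = {self.sample_groups[s] for s in cols}
        if groups != GROUPS:
            raise ValidationError("need at least one control and one treated sample")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


def _read_gct_frame(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file or a headerless TSV into genes x columns."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1."):
        if first.split("\t")[0] not in ("#1.2",):
            raise FormatError(f"{path}: unsupported GCT version line {first!r}")
        with open(path, encoding="utf-8") as fh:
            fh.readline()
            dims = fh.readline().rstrip("\n").split("\t")
            if len(dims) < 2:
                raise FormatError(f"{path}: malformed GCT dimension line {dims!r}")
            try:
                n_rows, n_cols = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed GCT dimension line {dims!r}") from exc
            frame = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        if "Description" in frame.columns:
            frame = frame.drop(columns=["Description"])
        elif frame.shape[1] >= 1:
            # GCT 1.2 column 2 is always the description, whatever its header
            frame = frame.drop(columns=[frame.columns[0]])
        if frame.shape != (n_rows, n_cols):
            raise FormatError(
                f"{path}: GCT header declares {n_rows} x {n_cols} but data are "
                f"{frame.shape[0]} x {frame.shape[1]}"
            )
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    return frame


def read_expression_gct(
    path: str | Path,
    group_map: Mapping[str, str],
    cell_line: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix (GCT 1.2 or TSV) and attach group labels.

    Raises
    ------
    FormatError
        Malformed header or non-numeric values.
    ValidationError
        Duplicate gene ids, non-finite or negative intensities.
    KeyError
        A sample named in ``group_map`` is absent from the file.
    """
    frame = _read_gct_frame(path)
    absent = [s for s in group_map if s not in frame.columns]
    if absent:
        raise KeyError(f"samples in group_map absent from {path}: {absent}")
    return ExpressionMatrix(frame, dict(group_map), cell_line=cell_line)


def write_expression_gct(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as GCT 1.2."""
    _write_gct_frame(mat.values, path)


def _write_gct_frame(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{frame.shape[0]}\t{frame.shape[1]}\n")
        out = frame.copy()
        out.insert(0, "Description", "na")
        out.index.name = "NAME"
        out.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# SignatureLibrary
# ---------------------------------------------------------------------------

_META_COLUMNS = ("perturbagen_id", "cell_line", "dose", "time")


@dataclass
class SignatureLibrary:
    """A landmark-gene signature library with per-signature metadata.

    ``amplitudes`` holds level-5-style differential-expression amplitudes,
    landmark genes on the index, signature ids on the columns; ``meta`` is
    indexed by signature id with columns perturbagen_id, cell_line, dose,
    time.
    """

    amplitudes: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.amplitudes.index.has_duplicates:
            raise ValidationError("duplicate landmark gene ids")
        if self.amplitudes.columns.has_duplicates:
            raise ValidationError("duplicate signature ids")
        if not np.isfinite(self.amplitudes.to_numpy(dtype=float)).all():
            raise ValidationError("signature amplitudes must be finite")
        missing_cols = [c for c in _META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns {missing_cols}")
        sig_ids = list(self.amplitudes.columns)
        meta_ids = set(self.meta.index)
        lacking = [s for s in sig_ids if s not in meta_ids]
        if lacking:
            raise AlignmentError(f"signatures without metadata rows: {lacking}")
        extra = sorted(meta_ids - set(sig_ids))
        if extra:
            raise AlignmentError(f"metadata rows without signatures: {extra}")
        self.meta = self.meta.loc[sig_ids]

    @property
    def landmark_genes(self) -> list[str]:
        return list(self.amplitudes.index)

    @property
    def n_landmark(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def signature_ids(self) -> list[str]:
        return list(self.amplitudes.columns)

    def __len__(self) -> int:
        return self.amplitudes.shape[1]


def read_signature_library(
    matrix_path: str | Path,
    meta_path: str | Path,
    n_landmark: int | None = None,
) -> SignatureLibrary:
    """Read a signature matrix plus its metadata TSV.

    ``n_landmark``, if given, asserts the expected landmark-gene count
    (978 in the emulated level-5 schema).
    """
    frame = _read_gct_frame(matrix_path)
    if n_landmark is not None and frame.shape[0] != n_landmark:
        raise ValidationError(
            f"{matrix_path}: expected {n_landmark} landmark genes, found {frame.shape[0]}"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "signature_id" not in meta.columns:
        raise FormatError(f"{meta_path}: metadata must have a 'signature_id' column")
    meta = meta.set_index("signature_id")
    return SignatureLibrary(frame, meta)


def write_signature_library(
    lib: SignatureLibrary, matrix_path: str | Path, meta_path: str | Path
) -> None:
    _write_gct_frame(lib.amplitudes, matrix_path)
    out = lib.meta.copy()
    out.index.name = "signature_id"
    out.to_csv(meta_path, sep="\t", lineterminator="\n")


def filter_library(
    lib: SignatureLibrary,
    cell_line: str | None = None,
    dose: str | None = None,
    time: str | None = None,
    approved_only: bool = False,
    drug_map: "DrugTargetTable | None" = None,
) -> SignatureLibrary:
    """Keep only signatures matching every non-empty criterion.

    Dose and time match under unit normalization ("10 µM" == "10.0 uM").
    ``approved_only`` keeps signatures whose perturbagen maps to a drug id
    in ``drug_map``. An empty result is a warning, not an error.
    """
    keep = pd.Series(True, index=lib.meta.index)
    if cell_line is not None:
        keep &= lib.meta["cell_line"] == cell_line
    if dose is not None:
        keep &= lib.meta["dose"].map(lambda d: quantities_equal(d, dose))
    if time is not None:
        keep &= lib.meta["time"].map(lambda t: quantities_equal(t, time))
    if approved_only:
        if drug_map is None:
            raise ValidationError("approved_only requires a drug_map")
        keep &= lib.meta["perturbagen_id"].map(
            lambda p: drug_map.drug_for_perturbagen(p) is not None
        )
    kept = keep[keep].index.tolist()
    if not kept:
        logger.warning("filter_library: no signatures match the given criteria")
        empty_meta = lib.meta.iloc[0:0]
        return SignatureLibrary(lib.amplitudes.iloc[:, 0:0], empty_meta)
    return SignatureLibrary(lib.amplitudes[kept], lib.meta.loc[kept])


# ---------------------------------------------------------------------------
# DrugTargetTable
# ---------------------------------------------------------------------------

_DRUG_COLUMNS = ("drug_id", "drug_name", "target_gene_symbol", "target_uniprot_id", "action")


@dataclass
class DrugTargetTable:
    """Drug -> target-protein edges with pharmacological action.

    ``perturbagen_map`` gives explicit perturbagen id -> drug id links;
    perturbagen ids with a trailing ``_DBxxxxx`` accession also map
    implicitly to that drug id.
    """

    table: pd.DataFrame
    perturbagen_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _DRUG_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"drug-target table missing columns {missing}")
        bad = sorted(set(self.table["action"]) - ACTIONS)
        if bad:
            raise ValidationError(
                f"unknown action tokens {bad}; allowed vocabulary: {sorted(ACTIONS)}"
            )
        key = ["drug_id", "target_gene_symbol", "action"]
        if self.table.duplicated(subset=key).any():
            dupes = self.table.loc[self.table.duplicated(subset=key), key]
            raise ValidationError(f"duplicate (drug, target, action) rows:\n{dupes}")

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.table["drug_id"].unique())

    def drug_for_perturbagen(self, perturbagen_id: str) -> str | None:
        """Resolve a perturbagen id to a drug id, or None if unmapped."""
        if perturbagen_id in self.perturbagen_map:
            return self.perturbagen_map[perturbagen_id]
        m = _DRUGBANK_SUFFIX.search(str(perturbagen_id))
        if m:
            return m.group(1)
        return None

    def targets_of(self, drug_id: str, actions: Iterable[str] | None = None) -> pd.DataFrame:
        rows = self.table[self.table["drug_id"] == drug_id]
        if actions is not None:
            rows = rows[rows["action"].isin(set(actions))]
        return rows


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a drug–target TSV (5 required columns; extras are kept).

    A ``perturbagen_id`` column, if present, seeds the explicit
    perturbagen -> drug map.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    pmap: dict[str, str] = {}
    if "perturbagen_id" in table.columns:
        pmap = dict(zip(table["perturbagen_id"], table.get("drug_id", "")))
        pmap = {k: v for k, v in pmap.items() if isinstance(v, str) and v}
    return DrugTargetTable(table, pmap)


def write_drug_targets(tab: DrugTargetTable, path: str | Path) -> None:
    tab.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_top10_drug_targets() -> DrugTargetTable:
    """Load the packaged drug–target fixture for the ten top-ranked drugs.

    Ten approved drugs with their antagonist/inhibitor target proteins
    (gene symbol, UniProt accession) and cross-cell-line mean connectivity
    scores; 22 drug–target rows over 19 unique target proteins.
    """
    ref = resources.files("sigconn.data").joinpath("top10_drug_targets.tsv")
    with resources.as_file(ref) as path:
        return read_drug_targets(path)


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional explicit universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-convention GMT file: set id, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                )
            set_id, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {set_id!r} has 0 members")
            if set_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = members
            descriptions[set_id] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, members in coll.sets.items():
            desc = coll.descriptions.get(set_id, "na")
            fh.write("\t".join([set_id, desc, *members]) + "\n")
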