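"""Seeded generators for every input the pipeline needs.

The generators emulate the study design the pipeline targets: triplicate
control (DMSO) vs treated expression matrices per cell line with planted
directional DEGs at a stated fold change under multiplicative lognormal
noise, an L1000-level-5-like reference library of 978-landmark signatures
containing decoys plus planted "mimic" (and optionally "reverser")
perturbagens correlated with the planted query, a drug–target table with
mixed pharmacological actions, and GMT gene-set collections.

Every generator is a pure function of (spec, seed): the same spec yields
bit-identical artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io import (
    ACTIONS,
    CONTROL,
    TREATED,
    DrugTargetTable,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureLibrary,
)

# rng stream tags, so each artifact draws from an independent child stream
_TAG_TRUTH, _TAG_EXPR, _TAG_LIB, _TAG_DRUGS, _TAG_GMT = 11, 12, 13, 14, 15

#: Template amplitude floor for planted query genes in mimic signatures;
#: far above the max |N(0,1)| draw expected over ~1000 decoy genes, so the
#: planted genes occupy the top ranks whenever rho is high.
_TEMPLATE_BASE = 5.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: three cancer cell lines treated
    in triplicate at 10 µM for 6 h, a 978-landmark-gene signature space,
    a two-fold planted effect, and a reference library of decoy drugs
    plus a handful of planted mimics.
    """

    seed: int = 0
    n_genes: int = 1200
    n_landmark: int = 978
    replicates: int = 3
    n_up: int = 40
    n_down: int = 30
    effect_fc: float = 2.0
    noise_sd: float = 0.1
    n_drugs: int = 200
    n_mimics: int = 5
    n_reversers: int = 0
    mimic_correlation: float = 0.9
    cell_lines: tuple[str, ...] = ("A549", "PC3", "MCF7")
    dose: str = "10 uM"
    time: str = "6 h"
    actions: tuple[str, ...] = tuple(sorted(ACTIONS))

    def __post_init__(self) -> None:
        if self.n_landmark > self.n_genes:
            raise ParameterError("n_landmark cannot exceed n_genes")
        if self.n_up + self.n_down > self.n_landmark:
            raise ParameterError("planted DEG count exceeds the landmark space")
        if not 0.0 <= self.mimic_correlation <= 1.0:
            raise ParameterError("mimic_correlation must be in [0, 1]")
        if min(self.n_up, self.n_down, self.n_drugs, self.n_mimics, self.n_reversers) < 0:
            raise ParameterError("counts must be >= 0")
        if self.replicates < 2:
            raise ParameterError("need >= 2 replicates per group")
        if self.effect_fc < 1.0:
            raise ParameterError("effect_fc must be >= 1 (planted down genes use 1/effect_fc)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        bad = set(self.actions) - ACTIONS
        if bad:
            raise ParameterError(f"unknown actions {sorted(bad)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("cell_lines", "actions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# identifier spaces
# ---------------------------------------------------------------------------

def gene_ids(spec: SyntheticSpec) -> list[str]:
    return [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]


def landmark_genes(spec: SyntheticSpec) -> list[str]:
    return gene_ids(spec)[: spec.n_landmark]


def decoy_drug_ids(spec: SyntheticSpec) -> list[str]:
    return [f"DB{10000 + i}" for i in range(1, spec.n_drugs + 1)]


def mimic_drug_ids(spec: SyntheticSpec) -> list[str]:
    return [f"DB{90000 + i}" for i in range(1, spec.n_mimics + 1)]


def reverser_drug_ids(spec: SyntheticSpec) -> list[str]:
    return [f"DB{80000 + i}" for i in range(1, spec.n_reversers + 1)]


def _all_drug_ids(spec: SyntheticSpec) -> list[str]:
    return decoy_drug_ids(spec) + mimic_drug_ids(spec) + reverser_drug_ids(spec)


def perturbagen_id(drug_id: str) -> str:
    """LINCS-style compound id embedding the drug accession."""
    return f"BRD-S{drug_id[2:]:0>6}_{drug_id}"


def planted_truth(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """The planted up- and down-regulated gene lists (within the landmark
    space, so planted DEGs survive the landmark intersection)."""
    rng = np.random.default_rng([spec.seed, _TAG_TRUTH])
    lm = landmark_genes(spec)
    perm = rng.permutation(len(lm))
    up = sorted(lm[i] for i in perm[: spec.n_up])
    down = sorted(lm[i] for i in perm[spec.n_up : spec.n_up + spec.n_down])
    return up, down


def truth_direction_map(spec: SyntheticSpec) -> dict[str, int]:
    up, down = planted_truth(spec)
    return {**{g: 1 for g in up}, **{g: -1 for g in down}}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def gen_expression(
    spec: SyntheticSpec, cell_line: str
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Generate one cell line's triplicate control/treated matrix.

    Control intensities are lognormal around a per-gene baseline; treated
    intensities multiply the baseline by ``effect_fc`` for planted up
    genes and divide it for planted down genes. Both groups carry
    multiplicative noise exp(N(0, noise_sd^2)); when ``noise_sd`` is 0 an
    epsilon jitter (1e-9 relative) keeps within-group variance nonzero so
    the t-test stays defined.

    Returns the matrix plus the planted up and down gene lists.
    """
    if cell_line not in spec.cell_lines:
        raise ParameterError(f"unknown cell line {cell_line!r}; spec has {spec.cell_lines}")
    ci = spec.cell_lines.index(cell_line)
    rng = np.random.default_rng([spec.seed, _TAG_EXPR, ci])
    genes = gene_ids(spec)
    up, down = planted_truth(spec)

    baseline = rng.lognormal(mean=math.log(200.0), sigma=0.6, size=spec.n_genes)
    factor = np.ones(spec.n_genes)
    pos = {g: i for i, g in enumerate(genes)}
    factor[[pos[g] for g in up]] = spec.effect_fc
    factor[[pos[g] for g in down]] = 1.0 / spec.effect_fc

    sd = spec.noise_sd if spec.noise_sd > 0 else 1e-9
    r = spec.replicates
    ctrl = baseline[:, None] * np.exp(rng.normal(0.0, sd, size=(spec.n_genes, r)))
    trt = (baseline * factor)[:, None] * np.exp(rng.normal(0.0, sd, size=(spec.n_genes, r)))

    cols = [f"{cell_line}_ctrl_{i + 1}" for i in range(r)] + [
        f"{cell_line}_trt_{i + 1}" for i in range(r)
    ]
    values = pd.DataFrame(np.hstack([ctrl, trt]), index=pd.Index(genes, name="gene_id"), columns=cols)
    groups = {c: (CONTROL if "_ctrl_" in c else TREATED) for c in cols}
    return ExpressionMatrix(values, groups, cell_line=cell_line), up, down


# ---------------------------------------------------------------------------
# signature library
# ---------------------------------------------------------------------------

def _mimic_template(spec: SyntheticSpec, truth_query: dict[str, int]) -> np.ndarray:
    """Direction-aligned template: planted query genes sit at large
    |amplitude| with the matching sign; all other genes at 0."""
    lm = landmark_genes(spec)
    pos = {g: i for i, g in enumerate(lm)}
    template = np.zeros(spec.n_landmark)
    for j, g in enumerate(sorted(truth_query)):
        template[pos[g]] = truth_query[g] * (_TEMPLATE_BASE + 0.01 * j)
    return template


def gen_library(
    spec: SyntheticSpec, truth_query: dict[str, int] | None = None
) -> tuple[SignatureLibrary, list[str], list[str]]:
    """Generate the reference library: one signature per drug per cell line.

    Decoy amplitudes are i.i.d. standard normal. Each mimic signature is
    the convex mixture rho * template + (1 - rho) * noise of the
    direction-aligned template and fresh standard-normal noise, so the
    planted query genes occupy the top |amplitude| ranks with matching
    sign whenever rho is high; reversers use the negated template.

    Returns (library, mimic drug ids, reverser drug ids).
    """
    if truth_query is None:
        truth_query = truth_direction_map(spec)
    lm = landmark_genes(spec)
    outside = sorted(set(truth_query) - set(lm))
    if outside:
        raise ValidationError(f"truth query genes outside the landmark space: {outside[:5]}")
    rho = spec.mimic_correlation
    template = _mimic_template(spec, truth_query)
    mimics, reversers = set(mimic_drug_ids(spec)), set(reverser_drug_ids(spec))

    rng = np.random.default_rng([spec.seed, _TAG_LIB])
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for drug_id in _all_drug_ids(spec):
        pert = perturbagen_id(drug_id)
        for cell in spec.cell_lines:
            noise = rng.standard_normal(spec.n_landmark)
            if drug_id in mimics:
                amp = rho * template + (1.0 - rho) * noise
            elif drug_id in reversers:
                amp = rho * (-template) + (1.0 - rho) * noise
            else:
                amp = noise
            sig_id = f"{pert}:{cell}"
            columns[sig_id] = amp
            meta_rows.append(
                {
                    "signature_id": sig_id,
                    "perturbagen_id": pert,
                    "cell_line": cell,
                    "dose": spec.dose,
                    "time": spec.time,
                }
            )
    amplitudes = pd.DataFrame(columns, index=pd.Index(lm, name="gene_id"))
    meta = pd.DataFrame(meta_rows).set_index("signature_id")
    lib = SignatureLibrary(amplitudes, meta)
    return lib, sorted(mimics), sorted(reversers)


# ---------------------------------------------------------------------------
# drug-target table and gene sets
# ---------------------------------------------------------------------------

def gen_drug_targets(spec: SyntheticSpec) -> tuple[DrugTargetTable, dict[str, str]]:
    """Generate a drug–target table over all library drugs.

    Every drug gets 1–5 targets from a synthetic protein pool with
    actions sampled from ``spec.actions``. Each mimic drug additionally
    carries a designated true target with an inhibitory action, so
    end-to-end target recovery is checkable.

    Returns (table, map mimic drug id -> its true target symbol).
    """
    rng = np.random.default_rng([spec.seed, _TAG_DRUGS])
    pool = [f"TGT{i:04d}" for i in range(1, 301)]
    mimics = set(mimic_drug_ids(spec))
    true_action = "inhibitor" if "inhibitor" in spec.actions else (
        "antagonist" if "antagonist" in spec.actions else spec.actions[0]
    )
    rows = []
    true_targets: dict[str, str] = {}
    for drug_id in _all_drug_ids(spec):
        name = f"drug-{drug_id.lower()}"
        n_t = int(rng.integers(1, 6))
        picks = rng.choice(len(pool), size=n_t, replace=False)
        for p in sorted(picks):
            rows.append(
                {
                    "perturbagen_id": perturbagen_id(drug_id),
                    "drug_id": drug_id,
                    "drug_name": name,
                    "target_gene_symbol": pool[p],
                    "target_uniprot_id": f"P{p:05d}",
                    "action": str(rng.choice(spec.actions)),
                }
            )
        if drug_id in mimics:
            idx = len(true_targets) + 1
            sym = f"TRUETGT{idx:03d}"
            true_targets[drug_id] = sym
            rows.append(
                {
                    "perturbagen_id": perturbagen_id(drug_id),
                    "drug_id": drug_id,
                    "drug_name": name,
                    "target_gene_symbol": sym,
                    "target_uniprot_id": f"Q{idx:05d}",
                    "action": true_action,
                }
            )
    table = pd.DataFrame(rows).drop_duplicates(subset=["drug_id", "target_gene_symbol", "action"])
    pmap = dict(zip(table["perturbagen_id"], table["drug_id"]))
    return DrugTargetTable(table.reset_index(drop=True), pmap), true_targets


def write_inputs(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Materialize every synthetic input as the text files the readers eat.

    Writes one expression GCT per cell line, the library matrix GCT and
    metadata TSV, the drug–target TSV and the GMT collection into
    ``out_dir``; returns a map of artifact name -> path.
    """
    from pathlib import Path

    from .io import write_drug_targets, write_expression_gct, write_gmt, write_signature_library

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for cell in spec.cell_lines:
        mat, _, _ = gen_expression(spec, cell)
        p = out / f"expression_{cell}.gct"
        write_expression_gct(mat, p)
        paths[f"expression_{cell}"] = str(p)
    lib, _, _ = gen_library(spec)
    write_signature_library(lib, out / "library.gct", out / "library_meta.tsv")
    paths["library_matrix"] = str(out / "library.gct")
    paths["library_meta"] = str(out / "library_meta.tsv")
    table, _ = gen_drug_targets(spec)
    write_drug_targets(table, out / "drug_targets.tsv")
    paths["drug_targets"] = str(out / "drug_targets.tsv")
    write_gmt(gen_gmt(spec), out / "gene_sets.gmt")
    paths["gene_sets"] = str(out / "gene_sets.gmt")
    return paths


def gen_gmt(spec: SyntheticSpec, n_decoy_sets: int = 8) -> GeneSetCollection:
    """Gene sets: one per planted direction plus seeded decoy sets."""
    rng = np.random.default_rng([spec.seed, _TAG_GMT])
    genes = gene_ids(spec)
    up, down = planted_truth(spec)
    sets = {"PLANTED_UP": list(up), "PLANTED_DOWN": list(down)}
    descriptions = {
        "PLANTED_UP": "planted up-regulated genes",
        "PLANTED_DOWN": "planted down-regulated genes",
    }
    for i in range(1, n_decoy_sets + 1):
        size = int(rng.integers(10, 51))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        sets[f"DECOY{i:02d}"] = members
        descriptions[f"DECOY{i:02d}"] = "random decoy set"
    return GeneSetCollection(sets, descriptions, universe=list(genes))
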