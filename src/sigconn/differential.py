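"""Per-gene fold changes, significance tests, DEG selection and the
cross-cell-line Venn partition.

Fold change is the ratio of group means on the raw intensity scale,
treated over control. The signed fold change keeps the ratio when it is
>= 1 and uses the negated reciprocal otherwise, so down-regulation carries
a negative sign with magnitude >= 1. Significance comes from a two-sided
Welch t-test on log2 intensities (Student's pooled t available behind a
flag); raw p-values are used by default, with Benjamini–Hochberg as an
option.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .io import CONTROL, TREATED, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ContrastTable:
    """Per-gene treated-vs-control contrast for one cell line.

    ``table`` is indexed by gene id with columns mean_control,
    mean_treated, fc, signed_fc, log2fc, p_value, adjusted_p, ok, flag.
    Genes with a non-positive intensity or a zero control mean are kept in
    the table but flagged ``ok=False`` and excluded from DEG selection.
    """

    table: pd.DataFrame
    cell_line: str

    @property
    def usable(self) -> pd.DataFrame:
        return self.table[self.table["ok"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", lineterminator="\n")


@dataclass
class DEGSet:
    """Up- and down-regulated gene lists for one cell line at stated cutoffs."""

    cell_line: str
    up: list[str]
    down: list[str]
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValidationError("a gene cannot be both up- and down-regulated")

    def genes(self, direction: str) -> list[str]:
        if direction not in ("up", "down"):
            raise ParameterError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up if direction == "up" else self.down


def _welch_or_student(
    log_t: np.ndarray, log_c: np.ndarray, equal_var: bool
) -> np.ndarray:
    """Two-sided t-test p-values per gene row, with the zero-variance
    degenerate case defined explicitly (p=1 when the group means agree,
    p=0 when they differ with zero spread)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(log_t, log_c, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(log_t.mean(axis=1), log_c.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def contrast(
    mat: ExpressionMatrix,
    cell_line: str | None = None,
    equal_var: bool = False,
    adjust: bool = False,
) -> ContrastTable:
    """Compute the per-gene contrast table for one expression matrix.

    Parameters
    ----------
    mat
        Validated expression matrix with >= 2 replicates per group.
    cell_line
        Label recorded on the output; defaults to ``mat.cell_line``.
    equal_var
        Use Student's pooled t instead of Welch's unequal-variance t.
    adjust
        Also fill ``adjusted_p`` with Benjamini–Hochberg adjusted p-values
        (computed over the usable genes).
    """
    label = cell_line if cell_line is not None else (mat.cell_line or "unknown")
    ctl = mat.samples_in_group(CONTROL)
    trt = mat.samples_in_group(TREATED)
    if len(ctl) < 2 or len(trt) < 2:
        raise ValidationError(
            f"need >= 2 replicates per group for a p-value "
            f"(control={len(ctl)}, treated={len(trt)})"
        )
    c = mat.values[ctl].to_numpy(dtype=float)
    t = mat.values[trt].to_numpy(dtype=float)

    positive = (c > 0).all(axis=1) & (t > 0).all(axis=1)
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.info("contrast(%s): %d genes with non-positive intensity excluded", label, n_dropped)

    mean_c = c.mean(axis=1)
    mean_t = t.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_c > 0, mean_t / mean_c, np.nan)
        signed = np.where(fc >= 1.0, fc, -1.0 / fc)
        log2fc = np.log2(fc)

    p = np.full(mat.values.shape[0], np.nan)
    if positive.any():
        p[positive] = _welch_or_student(np.log2(t[positive]), np.log2(c[positive]), equal_var)

    ok = positive & (mean_c > 0) & np.isfinite(fc) & (fc > 0)
    flag = np.where(positive, "", "nonpositive_intensity")
    flag = np.where((mean_c == 0) & positive, "zero_control_mean", flag)

    table = pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "fc": fc,
            "signed_fc": signed,
            "log2fc": log2fc,
            "p_value": p,
            "adjusted_p": np.nan,
            "ok": ok,
            "flag": flag,
        },
        index=mat.values.index,
    )
    if adjust:
        from statsmodels.stats.multitest import multipletests

        usable = table["ok"]
        if usable.any():
            table.loc[usable, "adjusted_p"] = multipletests(
                table.loc[usable, "p_value"], method="fdr_bh"
            )[1]
    return ContrastTable(table, label)


def select_degs(
    ct: ContrastTable,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    use_adjusted: bool = False,
) -> DEGSet:
    """Select DEGs: |signed FC| >= ``fc_cutoff`` (inclusive) and p < ``p_cutoff``."""
    if fc_cutoff < 1:
        raise ParameterError(
            f"fc_cutoff must be >= 1 (|signed fold change| is always >= 1), got {fc_cutoff}"
        )
    tab = ct.usable
    pcol = "adjusted_p" if use_adjusted else "p_value"
    sig = tab[pcol] < p_cutoff
    up = tab.index[sig & (tab["signed_fc"] >= fc_cutoff)].tolist()
    down = tab.index[sig & (tab["signed_fc"] <= -fc_cutoff)].tolist()
    return DEGSet(ct.cell_line, up, down, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)


def overlap_degs(sets: list[DEGSet], direction: str) -> dict[str, list[str]]:
    """Partition genes into Venn regions across cell lines.

    Returns a map from region key (sorted cell-line labels joined by
    ``"&"``) to the sorted genes belonging to exactly those cell lines.
    Every region of the partition appears as a key, including empty ones;
    region lists are disjoint and their union is the union of the inputs.
    """
    if len(sets) < 2:
        raise ParameterError("need >= 2 DEG sets for an overlap")
    labels = [s.cell_line for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate cell_line labels: {labels}")
    membership: dict[str, set[str]] = {}
    for s in sets:
        for g in s.genes(direction):
            membership.setdefault(g, set()).add(s.cell_line)
    regions: dict[str, list[str]] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(sorted(labels), r):
            regions["&".join(combo)] = []
    for gene, cells in membership.items():
        regions["&".join(sorted(cells))].append(gene)
    for key in regions:
        regions[key].sort()
    return regions
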