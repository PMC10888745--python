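"""Rank-based connectivity scoring between a query signature and a
reference signature library.

The reference profile assigns each landmark gene a signed rank: genes are
ranked by absolute amplitude ascending (rank n = largest |amplitude|) and
the rank carries the amplitude's sign; zero-amplitude genes get signed
rank 0. The query is the ordered, signed DEG list restricted to the
landmark space: in ordered mode gene i of m (ascending |log2 fold change|)
has signed rank sign * i, in unordered mode just the sign.

The connectivity score is the normalized signed-rank inner product

    c = C / C_max,   C = sum_i sr_ref(g_i) * sr_q(g_i),

with the closed-form theoretical maximum

    C_max = sum_{k=0}^{m-1} (m - k)(n - k)   (ordered)
    C_max = sum_{k=0}^{m-1} (n - k)          (unordered)

so that c is exactly 1 for a query that reproduces the reference's top-m
genes in order and sign, and exactly -1 for its sign-flipped mirror. C and
C_max are integer sums of integer rank products; the only floating-point
operation is the final division.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import ContrastTable, select_degs
from .errors import EmptyQueryError, ParameterError, UndefinedScoreError
from .io import SignatureLibrary

logger = logging.getLogger(__name__)

ORDERED = "ordered"
UNORDERED = "unordered"


@dataclass
class ReferenceRankProfile:
    """Signed ranks of one reference signature over n landmark genes."""

    signature_id: str
    signed_ranks: dict[str, int]
    n: int  # number of landmark genes in the reference space

    def __post_init__(self) -> None:
        nonzero = [abs(r) for r in self.signed_ranks.values() if r != 0]
        if len(set(nonzero)) != len(nonzero):
            raise ParameterError("nonzero |signed ranks| must be distinct")


@dataclass
class QuerySignature:
    """Ordered, signed query gene list (position m = strongest change)."""

    genes: list[str]
    signs: list[int]
    mode: str = ORDERED

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyQueryError("query signature has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("query genes must be unique")
        if len(self.signs) != len(self.genes):
            raise ParameterError("signs and genes must have equal length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ParameterError("query signs must be +1 or -1")
        if self.mode not in (ORDERED, UNORDERED):
            raise ParameterError(f"mode must be '{ORDERED}' or '{UNORDERED}'")

    @property
    def m(self) -> int:
        return len(self.genes)

    def signed_ranks(self) -> dict[str, int]:
        """Gene -> signed query rank (position in ordered mode, sign only
        in unordered mode)."""
        if self.mode == ORDERED:
            return {g: s * (i + 1) for i, (g, s) in enumerate(zip(self.genes, self.signs))}
        return {g: s for g, s in zip(self.genes, self.signs)}

    def flipped(self) -> "QuerySignature":
        return QuerySignature(list(self.genes), [-s for s in self.signs], self.mode)


@dataclass
class ConnectivityRecord:
    """Normalized connectivity score of one reference signature."""

    signature_id: str
    perturbagen_id: str
    cell_line: str
    c: float
    m_eff: int
    ok: bool = True
    note: str = ""


def _signed_rank_vector(amplitudes: np.ndarray, id_order: np.ndarray) -> np.ndarray:
    """Signed ranks for one amplitude vector.

    Ranks |amplitude| ascending; ties broken by ascending gene identifier
    (``id_order`` is each gene's position in the sorted id list). Zero
    amplitudes are assigned signed rank 0.
    """
    order = np.lexsort((id_order, np.abs(amplitudes)))
    ranks = np.empty(len(amplitudes), dtype=np.int64)
    ranks[order] = np.arange(1, len(amplitudes) + 1)
    signs = np.sign(amplitudes).astype(np.int64)
    return signs * ranks


def build_reference_ranks(
    lib: SignatureLibrary, signature_id: str
) -> ReferenceRankProfile:
    """Build the signed-rank profile of one library signature."""
    if signature_id not in lib.amplitudes.columns:
        raise KeyError(f"no signature {signature_id!r} in library")
    genes = lib.landmark_genes
    amps = lib.amplitudes[signature_id].to_numpy(dtype=float)
    id_order = np.argsort(np.argsort(np.asarray(genes, dtype=object)))
    sr = _signed_rank_vector(amps, id_order)
    if (sr == 0).all():
        logger.warning("signature %s has all-zero amplitudes", signature_id)
    return ReferenceRankProfile(signature_id, dict(zip(genes, sr.tolist())), n=len(genes))


def build_query(
    ct: ContrastTable,
    landmark_genes: list[str],
    m_max: int | None = None,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    mode: str = ORDERED,
) -> QuerySignature:
    """Build the query signature from a contrast table.

    DEGs (at the stated cutoffs) are intersected with the landmark space,
    ordered ascending by |log2 fold change| (ties broken by gene id), and
    optionally truncated to the ``m_max`` strongest.
    """
    degs = select_degs(ct, fc_cutoff=fc_cutoff, p_cutoff=p_cutoff)
    deg_genes = degs.up + degs.down
    landmarks = set(landmark_genes)
    in_space = [g for g in deg_genes if g in landmarks]
    n_dropped = len(deg_genes) - len(in_space)
    if n_dropped:
        logger.info(
            "build_query(%s): %d DEGs outside the landmark space dropped",
            ct.cell_line, n_dropped,
        )
    if not in_space:
        raise EmptyQueryError(
            f"no DEGs of {ct.cell_line} fall in the landmark space; "
            "scoring an empty query is undefined"
        )
    l2 = ct.table.loc[in_space, "log2fc"]
    ordered = sorted(in_space, key=lambda g: (abs(l2[g]), g))
    if m_max is not None:
        if m_max < 1:
            raise ParameterError("m_max must be >= 1")
        ordered = ordered[-m_max:]
    signs = [1 if l2[g] >= 0 else -1 for g in ordered]
    return QuerySignature(ordered, signs, mode)


def max_raw_score(n: int, m: int, mode: str = ORDERED) -> int:
    """Closed-form theoretical maximum of the raw strength C.

    Ordered: sum_{k=0}^{m-1} (m-k)(n-k); unordered: sum_{k=0}^{m-1} (n-k).
    """
    if mode == ORDERED:
        return sum((m - k) * (n - k) for k in range(m))
    if mode == UNORDERED:
        return sum(n - k for k in range(m))
    raise ParameterError(f"unknown mode {mode!r}")


def _score_from_ranks(
    ref_ranks: dict[str, int], n: int, q: QuerySignature
) -> tuple[float, int]:
    """Compute (c, m_eff) for one reference profile given as a dict."""
    effective = [
        (g, s) for g, s in zip(q.genes, q.signs) if ref_ranks.get(g, 0) != 0
    ]
    m_eff = len(effective)
    if m_eff == 0:
        raise UndefinedScoreError(
            "no query gene has a nonzero reference rank; the score is undefined"
        )
    if q.mode == ORDERED:
        # re-rank 1..m_eff preserving query order (genes absent from the
        # reference contribute to neither C nor C_max)
        sr_q = {g: s * (i + 1) for i, (g, s) in enumerate(effective)}
    else:
        sr_q = {g: s for g, s in effective}
    c_raw = sum(ref_ranks[g] * sr_q[g] for g, _ in effective)
    c_max = max_raw_score(n, m_eff, q.mode)
    return c_raw / c_max, m_eff


def zhang_score(
    ref: ReferenceRankProfile,
    q: QuerySignature,
    perturbagen_id: str = "",
    cell_line: str = "",
) -> ConnectivityRecord:
    """Score one query against one reference profile; c is in [-1, 1]."""
    c, m_eff = _score_from_ranks(ref.signed_ranks, ref.n, q)
    return ConnectivityRecord(ref.signature_id, perturbagen_id, cell_line, c, m_eff)


def score_library(lib: SignatureLibrary, q: QuerySignature) -> list[ConnectivityRecord]:
    """Score a query against every signature of a library.

    Returns one record per signature in signature-id order. Signatures for
    which the score is undefined (all-zero amplitudes over the query) come
    back flagged ``ok=False`` rather than raising.
    """
    if len(lib) == 0:
        return []
    genes = lib.landmark_genes
    n = len(genes)
    id_order = np.argsort(np.argsort(np.asarray(genes, dtype=object)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    A = lib.amplitudes.to_numpy(dtype=float)

    records: list[ConnectivityRecord] = []
    for sig_id in sorted(lib.signature_ids):
        j = lib.amplitudes.columns.get_loc(sig_id)
        sr = _signed_rank_vector(A[:, j], id_order)
        ref_ranks = {g: int(sr[gene_pos[g]]) for g in q.genes if g in gene_pos}
        meta = lib.meta.loc[sig_id]
        try:
            c, m_eff = _score_from_ranks(ref_ranks, n, q)
            rec = ConnectivityRecord(
                sig_id, meta["perturbagen_id"], meta["cell_line"], c, m_eff
            )
        except UndefinedScoreError as exc:
            rec = ConnectivityRecord(
                sig_id, meta["perturbagen_id"], meta["cell_line"],
                float("nan"), 0, ok=False, note=str(exc),
            )
        records.append(rec)
    return records


def records_to_frame(records: list[ConnectivityRecord]) -> pd.DataFrame:
    """Tabulate connectivity records for TSV serialization."""
    return pd.DataFrame(
        {
            "signature_id": [r.signature_id for r in records],
            "perturbagen_id": [r.perturbagen_id for r in records],
            "cell_line": [r.cell_line for r in records],
            "c": [r.c for r in records],
            "m_eff": [r.m_eff for r in records],
            "ok": [r.ok for r in records],
        }
    )
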