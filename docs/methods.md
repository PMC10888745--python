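# Methods

## Problem and model

The pipeline infers plausible targets for a compound from the similarity
of its transcriptome perturbation to those of approved drugs. The core
statistic is the rank-based connectivity score of Zhang-and-Gant type: a
reference differential-expression signature over *n* landmark genes is
reduced to signed ranks, the query is the compound's ordered, signed DEG
list, and the signed-rank inner product is normalized by its theoretical
maximum so the score lies in [−1, 1] with the endpoints attained exactly
by a self-derived query and its sign-flipped mirror. The score uses rank
information only, so it is invariant under any monotone transform of the
reference amplitudes — amplitudes can be z-scores, moderated statistics
or fold changes without affecting results.

## Differential expression

Fold change is the ratio of group means on the raw intensity scale
(treated / control); the literature for this assay family computes the
ratio before any log transform, and we follow that: `log2fc = log2(fc)`
and the signed fold change is `fc` when `fc ≥ 1`, else `−1/fc` (tie at
`fc = 1` takes the positive sign). Significance is a two-sided Welch
(unequal-variance) t-test on log2 intensities — the conventional choice
for triplicate array data, where variance heterogeneity between groups
is common; Student's pooled t is available via `equal_var=True`. Raw
p < 0.05 with |signed FC| ≥ 1.5 (inclusive) is the default DEG rule;
Benjamini–Hochberg adjustment is available but off by default, matching
the common practice of screening on raw p at this small replicate count.
Degenerate inputs are defined explicitly: genes with any non-positive
intensity are flagged and excluded from selection rather than shifted by
a pseudocount (the data model is positive array signal, and a silent
pseudocount distorts fold changes of low-expressed genes); groups with
zero variance get p = 1 when the means agree and p = 0 otherwise.

Duplicate gene rows in input matrices are rejected rather than averaged:
collapsing probes to genes is an upstream annotation decision this
package deliberately does not make, so input must already be gene-level.

## Connectivity score

Reference signed ranks: rank genes by |amplitude| ascending (rank n =
largest), attach the amplitude's sign; exact |amplitude| ties break by
ascending gene identifier so profiles are deterministic; zero amplitudes
get signed rank 0 and never contribute. Query signed ranks: DEGs
intersected with the landmark space, ordered ascending by |log2 FC|
(ties again by gene id), gene i of m getting `sign_i · i`; an unordered
mode (signs only) is provided for sensitivity analysis, since magnitude
weighting is a modelling choice rather than a mathematical necessity.
The default is ordered, which uses the DEG magnitude information.

The raw strength is `C = Σ sr_ref(g_i)·sr_q(g_i)`, normalized by the
closed-form maximum `C_max = Σ_{k=0}^{m−1}(m−k)(n−k)` (ordered) or
`Σ(n−k)` (unordered). The closed form is validated in the test suite
against exhaustive enumeration of every placement and sign assignment of
the query genes for all n ≤ 6, m ≤ 3, and every score is cross-checked
against an independent naive sum-of-products route. `C` and `C_max` are
integer arithmetic; the single final division is the only floating-point
operation, which is why the endpoint scores are exactly ±1.

When a query gene is absent from a reference profile (or has zero
amplitude there), the effective query re-ranks 1..m_eff over the
remaining genes in order: dropping such a gene then changes neither C
nor C_max, which keeps scores comparable across references with
different gene coverage. A query with m_eff = 0, or an all-zero
reference, has no defined score; library scoring flags such records
rather than silently reporting 0, because "no information" and "no
connectivity" are different findings. Query truncation to a fixed
signature size is exposed (`m_max`) but off by default.

## Drug ranking and target extraction

Multiple signatures of one drug in one cell line collapse to their
arithmetic mean first; the per-cell scores then average across cell
lines, so no cell line is over-weighted by replicate count. The default
missing-cell policy requires a drug to be profiled in every cell line
(`require_all_cells`); `mean_available` averages what exists. Ranking is
by descending mean score with ties broken by drug id, deterministically.
Target extraction unions the target proteins of the top-k drugs whose
pharmacological action is antagonist or inhibitor, deduplicated by gene
symbol (symbol-level identity: the same protein reached via two drugs
counts once), each entry tracing back to its source drugs.

Perturbagen-to-drug mapping accepts an explicit mapping table and also
recognizes the `_DBxxxxx` accession suffix convention of LINCS compound
ids as an implicit mapping. Dose and time metadata match numerically
under unit normalization ("uM" ≡ "µM", "h" ≡ "hr", relative tolerance
1e-9), not by string equality.

## Over-representation analysis

Per gene set, the p-value is the upper-tail hypergeometric sum
P(X ≥ k) for universe size N, set size s, query size q, overlap k,
identical to a one-sided Fisher exact test on the 2×2 table (asserted
per-row in the tests). The EASE variant replaces k with max(k−1, 0)
before the tail sum, a conservative correction that penalizes
single-gene overlaps. The background universe is explicit and mandatory
— in the pipeline it defaults to all genes present in the expression
matrices, never a genome-wide list the data cannot support. BH
adjustment is optional and off by default. GO/KEGG term databases are
out of scope: the analysis takes any GMT collection.

## Synthetic data

The generators emulate the study design the pipeline targets, and their
defaults are the study conditions: three cell lines (A549, PC3, MCF7),
triplicate control (DMSO-like) vs treated samples at 10 µM / 6 h
metadata, a 978-landmark-gene level-5-style reference schema, planted
DEGs (40 up, 30 down by default) at two-fold effect, and a library of
200 decoy drugs plus 5 mimics, one signature per drug per cell line.

Expression: per-gene lognormal baselines (median 200 intensity units,
log-scale σ 0.6 — a realistic array-intensity spread), multiplied by
the effect for planted genes, times multiplicative noise
`exp(N(0, noise_sd²))` with noise_sd = 0.1 by default. At noise_sd = 0 a
documented ε-jitter (1e-9 relative) keeps within-group variance nonzero
so the t-test is defined, and planted-DEG recovery is exact. Reference
library: decoys are i.i.d. standard normal; a mimic is the convex
mixture `ρ·template + (1−ρ)·noise` of a direction-aligned template
(planted query genes at top |amplitude| with matching sign) and fresh
noise; reversers negate the template. Convex mixing was chosen over
copula sampling for transparency: ρ = 0 makes mimics exactly decoys and
ρ = 1 makes them noiseless templates, both analyzable. Drug–target
tables give every drug 1–5 random targets with actions from the closed
vocabulary, and each mimic a designated true target with an inhibitory
action so end-to-end target recovery is checkable.

What the generator does **not** emulate: probe-level effects and
normalization artifacts of real arrays, the L1000 bead deconvolution and
z-scoring pipeline, correlated gene–gene structure, or dose–response.
Passing the recovery benchmarks therefore demonstrates the pipeline's
correctness and power under its own model assumptions, not performance
on real microarray/L1000 data.

## Benchmark scales and numerical choices

The planted-mimic recovery benchmark runs the full pipeline (expression
→ contrast → DEGs → query → library scores → cross-cell aggregation →
top 10) at 978 landmarks / 1200 genes, 200 decoys + 5 mimics, ρ = 0.9,
noise_sd = 0.05, over seeds 1–100; recovery = all 5 mimics in the
top 10. A ρ = 0 arm with identical sizes checks the negative control:
mimic ranks then distribute like any decoy's, with mean rank at the
library midpoint within Monte-Carlo error (4σ of the mean of uniform
ranks). These problem sizes keep a full 100-seed arm under a minute on
one core while leaving the per-arm Monte-Carlo error small.

All generators derive child RNG streams from `(seed, stream-tag)` tuples
via numpy's SeedSequence mechanism, so artifacts are independent of one
another and each is a pure function of the spec.

## Known limitations

- Input must be gene-level and aligned to the reference's landmark
  identifier space; no probe collapsing or identifier translation is
  provided.
- The score has no attached significance: no permutation p-values or
  Kolmogorov–Smirnov-style enrichment variant is implemented, because
  ranking (not testing) is the pipeline's decision rule.
- Whether to truncate queries to a fixed signature size, and whether to
  average or select among replicate signatures per drug and cell, are
  exposed as options (`m_max`, aggregation policy) with the defaults
  documented above; results can be sensitive to both on real data.
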