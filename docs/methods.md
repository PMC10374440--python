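# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `meltforms`.

## Data model and pre-processing

Peptide-level reporter-ion intensities live on a peptide × cell line ×
temperature grid (`PeptideQuantMatrix`); the temperature grid is sorted
ascending on load, so "first" and "lowest" temperature always coincide.
Missing values are NaN throughout; zero intensities are treated as missing
for fold-change purposes (a zero reference would otherwise create infinite
fold changes, and zero reporter signal in TMT data is indistinguishable
from non-detection). PSM-level input is summarized to peptides by
summation.

Per-temperature normalization equalizes the median intensity of each
sample within a temperature channel by a multiplicative factor (an affine
shift in log space). This is a deliberate simplification of full
variance-stabilizing normalization: the detector consumes *fold changes*
relative to the lowest temperature, which are invariant to per-sample scale
factors, so only the median-equalization component of VSN affects anything
downstream. The transform is monotone, rank-preserving and idempotent
(checked to 1e-9). Whether a full arsinh calibration should be fit per
channel jointly or per cell line is not determinable from the method's
description; the contract implemented here (per channel, across samples)
sidesteps the question at the scale that matters for clustering.

Fold changes x[i,n,k] = I[i,n,k] / I[i,n,0]; series lacking a reference are
masked entirely. Peptides must be quantified in ≥ 2 cell lines
(`min_cell_lines`, default 2) to enter the detector.

## Proteoform-group detection

Per gene, a complete graph over its peptides carries similarities
S = 1/(1+d) with the weighted Euclidean distance

    d_ij = sqrt( sum_{valid (n,k)} (x_i - x_j)^2 * v/(N*K) ),

v = number of positions quantified in both peptides. The factor v/(NK) is
implemented exactly as the method defines it, which *shrinks* distances
computed from sparse overlaps (two peptides sharing few observations look
more similar). The statistically unbiased completion would multiply by
NK/v instead; because the choice is consequential for sparse data, it is
exposed as `DetectionParams.distance_scaling = "as_published" | "unbiased"`
with the published variant as default.

Communities are found with Leiden (leidenalg, modularity objective,
resolution 1, iterated to convergence, seeded — deterministic for a fixed
seed). Modularity Q is igraph's weighted Newman–Girvan modularity of the
returned partition of the whole gene graph (computed before any
small-community drop; the alternative — recomputing Q after dropping
communities with < 3 peptides — is not what `modularity()` on the detected
partition yields).

Acceptance gates, all at their published defaults:

| gate | default | meaning |
| --- | --- | --- |
| `min_gene_peptides` | 10 | peptides per gene to attempt detection |
| `min_peptides_per_sample` | 2 | per cell line *in which the gene is quantified at all* |
| `max_ambiguity` | 0.5 | ambiguous / (specific + ambiguous) peptides |
| `q_threshold` | 1e-13 | partition modularity must exceed this |
| `min_group_peptides` | 3 | community support to become a group |

Genes failing any gate (or with Q ≤ threshold) keep one unresolved group
`<gene>_0`. Accepted communities are named `<gene>_1`, `<gene>_2`, … by
decreasing size, ties broken by the lexicographically smallest member
peptide — the upstream naming convention is unstated, and size order is
reproducible. Peptides of communities below 3 members stay unassigned and
are excluded from all downstream profiles, so outlier peptides cannot
contaminate accepted groups.

Group profiles are built by summing the *non-normalized raw* member
intensities per channel, then normalizing per temperature and forming fold
changes. Channels where every member is missing stay masked.

## Sigmoid melting model

f(T) = (1−p)/(1+exp(b − a/T)) + p with p ∈ [0,1). The objective is
non-convex, so fitting evaluates a start grid — candidate midpoints T0 ∈
{44, 46, …, 60} °C crossed with slope scales b0 ∈ {15, 50, 150}, a = b0·T0,
p0 = min(last observed fold change, 0.3) — and refines the best start by
RSS with a bounded trust-region least-squares solve (scipy, tolerances
1e-12). Fits need ≥ 4 points; S_res = sqrt(RSS/(n−3)). Fits with
S_res ≥ 0.1 are retained in outputs but flagged rejected, mirroring the
per-cell-line acceptance used by the differential test. The melting point
is the closed form Tm = a/(b − ln(0.5/(0.5−p))), undefined for p ≥ 0.5 or
a non-positive denominator (flagged, never raised). The melting AUC
integrates the fitted curve (adaptive quadrature, abs. tol. 1e-8) over the
experimental window [lowest, highest temperature] — a fixed window is
required for AUCs to be comparable across cell lines.

## Differential melting (NPARC-style)

Proteoforms quantified in ≥ 10 cell lines are tested. Alternative model:
one sigmoid per cell line, keeping lines with converged fits and
S_res < 0.1; the null sigmoid is refit on the pooled points of exactly
those kept lines. The statistic is implemented as printed:

    F = (RSS0 − RSS1)/RSS0 · d2/d1,  d1 = ν1 − ν0,  d2 = p_i − ν0,

ν0 = 3, ν1 = 3·(kept lines), p_i = total kept observations. Note this
differs from the classical partial-F (denominator RSS1/d2 with
d2 = p_i − ν1); the printed variant is bounded above by d2/d1 because the
variance-explained ratio saturates at 1. `f_variant="classical"` preserves
comparability with the textbook statistic. Because cell-line heterogeneity
inflates F relative to its theoretical null, hits are called by rank: F at
or above the 90th percentile of testable proteoforms (linear-interpolation
percentile; threshold ties count as hits). No p-values or FDR are attached
to this call by design.

## Differential co-aggregation

Protein pairs with STRING-style combined score ≥ 950 are expanded to all
proteoform-group pairs (3 groups × 2 groups → 6 pairs). Per cell line the
co-aggregation test compares the Euclidean distance of the two curves
against an empirical null of 10,000 uniformly sampled non-annotated
proteoform pairs from the same cell line, with the pseudo-count p-value
p = (1 + #{null ≤ observed})/(n_null + 1) (so p ∈ [1/(n+1), 1] and the
procedure can never report zero), BH-adjusted across pairs within each
line. The underlying reference procedure is not fully specified upstream;
this construction is the minimal faithful version and is fully seeded.
Pairs co-aggregating (p_adj < 0.1) in ≥ 1 line are scored for differential
co-aggregation with

    F = (RSS_(n−1) − RSS_(2)) / RSS_(2)

over the per-line curve RSS values (measured fold changes at shared
temperatures, not fitted curves), requiring RSS in ≥ 4 lines, where n
counts the lines in which both proteoforms are quantified. Using second-
order statistics on both ends makes F provably insensitive to one extreme
line on either side; RSS_(2) = 0 yields an infinite sentinel with a flag.
The top decile of F among eligible pairs is flagged. The PPI-prediction
harness ranks protein pairs by cell-line-averaged curve distance and
reports a ROC/AUC against any supplied positive set.

## Drug-sensitivity association

Drugs are filtered to a minimal effect: max sDSS over cell lines ≥ 6 (the
method's two phrasings of this cutoff conflict; the reading "at least one
cell line responds" is implemented). Per (proteoform, drug), sDSS is
regressed on melting AUC by OLS with the exact two-sided t-test for the
slope; all tests are jointly BH-adjusted and called at p_adj < 0.1. The
upstream analysis used limma-moderated linear models; with a single
predictor and equal n per test, empirical-Bayes variance moderation changes
ranking only marginally, and OLS keeps the module dependency-light. The
interface accepts an exclusion list for outlier cell lines (e.g. a line
that is unspecifically sensitive to most drugs).

## Simulation benchmark

The generator reproduces the stated benchmark conditions as defaults:
1,000 negative proteins, 200 positive proteins (50 per ΔTm level ∈
{1,2,3,4} °C), base Tm ~ Uniform(50, 60) °C, melting-point variability
SD 2 °C, fold-change noise SD 0.1 with non-positive draws forced to 1e-3,
8 temperatures (41–63 °C) × 20 cell lines, 15 or 50 peptides per protein.
Curves follow the melting sigmoid with plateau 0 and a = b·Tm (b = 50), so
f(Tm) = 0.5 exactly and curves span ≈1 → ≈0 over the window; each series is
referenced to its first temperature before noise. Positives split their
peptides 50/50 between the two proteoforms (split unstated upstream; both
Tm jitters are drawn independently).

**Melting-point jitter is drawn per peptide *and* cell line by default**
(`tm_noise_mode="per_measurement"`). This is a deliberate design choice:
a single per-peptide draw shared across all 20 cell lines is not noise but
a reproducible peptide-level offset — under that model the negative
proteins carry genuine cross-line cluster structure and any modularity-
based detector splits the majority of them (measured FDR 0.7–0.85),
contradicting the benchmark's purpose of measuring false discoveries on
proteins *without* proteoform evidence. Under per-measurement jitter the
benchmark reproduces the method's published behavior: negatives rarely
split (FDR ≈ 0–12% depending on coverage, ≤ 10% at the calibrated
threshold), sensitivity rises with ΔTm, and ROC AUC rises with peptide
coverage. Both modes remain available.

Evaluation: a protein is *detected* when ≥ 2 accepted groups are reported,
regardless of peptide-level assignment accuracy; FDR = FP/(TP+FP) (0 when
nothing is detected); sensitivity is stratified by ΔTm; ROC ranks proteins
by partition modularity. `calibrate_q_threshold` sweeps a modularity grid
and returns the least stringent threshold whose empirical FDR meets the
target (most stringent grid point, with a warning, when none does),
together with the full FDR-vs-threshold table.

## Problem sizes used by the test suite

The acceptance checks run the full 1,200-protein benchmark for the FDR
criterion at both coverage settings. The monotonicity suite (5 seeds × 2
coverage settings) runs with 200 negatives and the full 200 positives per
run: sensitivity is a function of the positives only, and 200 negatives
are enough to rank the ROC stably across seeds. The drug-association null
calibration uses 1,000 pure-noise tests per seed. Sigmoid parameter
recovery uses 200 replicates at noise SD 0.01.

## Known limitations

- The simulator models complete data (no missingness), a common plateau of
  0 and one shared curve-shape parameter; real TPP data have missing
  channels, nonzero plateaus, peptide-specific slopes and intensity-
  dependent noise. Passing benchmarks therefore demonstrates correctness
  of the detector and its calibration under the stated noise model, not
  performance on any particular real dataset.
- The v/(NK) distance scaling shrinks distances for sparsely overlapping
  peptide pairs; with heavy missingness this biases such pairs toward
  similarity (see `distance_scaling`).
- Percentile-based hit calling (differential melting, co-aggregation)
  provides a fixed hit fraction, not an error rate.
- The co-aggregation null draws pairs uniformly from non-annotated
  proteoforms; if the annotation is very dense, the null pool shrinks and
  p-values coarsen.
- Raw spectrum processing, PSM-level FDR, peptide-to-isoform sequence
  mapping and visualization are out of scope.
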