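# Methods

This note records the models, defaults, and numerical choices behind
follimap, and what the synthetic validation does and does not establish.

## Quality control

Cell filters apply the printed thresholds of the underlying protocol with
strict inequalities, so boundary values survive: mitochondrial count
fraction > 0.10, total UMIs < 200, total UMIs > 10,000, hemoglobin fraction
> `hb_max`. The hemoglobin rule is qualitative in the protocol ("high
levels of hemoglobin-encoding genes"); the default `hb_max = 0.01` is this
package's documented choice, exposed as a parameter, and it is likewise
unspecified whether the original rule was a fraction or an absolute count —
we implement a fraction. Gene and spot cutoffs for "extremely low" spot
quality are similarly unquantified upstream; the defaults (250 UMIs, 100
genes per spot) are package choices.

Each removed barcode is attributed to the *first* rule that catches it, in
the fixed order mito → umi_min → umi_max → hb (spots: label exclusion →
UMI → gene count), so per-rule counters always sum to `n_in − n_out`. Spot
label-exclusion — the stand-in for morphology-based removal of non-tissue
spots — runs before the count filters; the upstream ordering is unstated and
this one is pinned here.

Doublet removal is deliberately *not* a re-implementation of a doublet
simulator: it is rank-threshold plumbing over a supplied score column. Per
sample (time point), the top `round(0.06 · n)` cells by score are removed,
ties broken by barcode so the cut is deterministic. The stage order is
cell filters → gene filter → doublet exclusion, following the protocol's
narrative order.

## Normalization

`value(g,o) = ln(1 + count(g,o)/total(o) · S)`. For spots, S is the median
spot total (the stated spot rule). For cells the upstream scale factor is
not stated; we use the ecosystem-standard S = 10,000 with natural log, and
record S and the log base in the `ExpressionMatrix` metadata so tests can
pin it. Zero counts map to zero; observations with zero totals must be
removed beforehand (the QC UMI floor guarantees this in the pipeline).

## Differential expression and marker sets

"Statistically higher expression" is implemented as a two-sided test plus a
positive average-logFC filter, rather than a one-sided test — this matches
how the quoted thresholds (P < 10⁻²⁰, P < 0.001) are conventionally used
with two-tailed tests. The *t* test defaults to Welch; cluster-vs-rest
designs have grossly unequal group sizes and variances, making pooled
variance a poor default (a pooled option exists, and the choice is recorded
in the result's provenance note). Average log fold change is the difference
of mean log-normalized expression on the natural-log scale; downstream use
is only thresholding at 0 or 0.5, and the definition is pinned by tests.

The Wilcoxon path uses the normal approximation with tie correction and
continuity correction (scipy's Mann-Whitney machinery). When both groups
have ≤ 8 observations it switches to exact enumeration of all rank
assignments with midranks, doubling the smaller tail. The approximation
tracks exact enumeration to within 0.02 for continuous data once both
groups have ≥ 5 observations (measured on a randomized suite); below that,
or for heavily tied data, deviations reach ~0.1–0.4 — which is precisely why
the exact path exists at small sizes.

For MIA gene sets the p threshold is applied to *raw* p-values by default:
the intersection-analysis protocol quotes P < 10⁻²⁰ without adjustment,
while the separate DEG workflow quotes adjusted values — both are available
via the `adjust` flag. P-values are floored at 10⁻³⁰⁰ so the 10⁻²⁰
threshold stays decidable even when the test statistic saturates.

Benjamini–Hochberg adjustment delegates to statsmodels and is verified in
tests against the brute-force step-up definition
`adj_(i) = min_{j≥i} m·p_(j)/j`.

## MIA

Enrichment is the inclusive upper tail P(X ≥ k) of
Hypergeometric(N, m, n), computed in log space; depletion is
−log10(P(X ≤ k−1)) with the lower tail summed directly — computing
1 − P(X ≥ k) by subtraction underflows exactly where depletion is
strongest. Both tails are evaluated with (m, n) in canonical order so the
pair statistic is bitwise symmetric in its two sets. Scores are capped at
300 (a plotting convenience; the cap is configurable). At k = 0 the lower
tail is exactly zero and the depletion score reports the cap.

"All genes as the background" is ambiguous across two modalities with
different post-QC universes. The default background is the *intersection*
of the two universes, because the hypergeometric draw is only well-defined
when both sets are subsets of the background; union and custom-list modes
are selectable. Genes in a set but outside the background are dropped from
the set (and counted), never added to the background.

The null calibration experiment draws random set pairs with m, n ∈
[1000, 1500] from a background of 5000. At these sizes the discrete null is
near-calibrated (fraction of p < 0.05 ≈ 0.04–0.05); with small sets
(m, n ≲ 100) the hypergeometric test is strongly conservative — a property
of the test, not a defect — and the nominal-rate check would not be
informative there.

## Ligand–receptor interactions

The score for pair (L, R) from sender A to receiver B at time t is the mean
of two group averages of log-normalized expression (zeros included). The
null shuffles the joint (type, time) label vector across all cells —
matching a procedure that "shuffles the cell-type and time-point labels" —
and recomputes the score; group sizes are preserved by construction. A
`within_time` scope is provided for a null that does not mix time points.

The empirical p is one-sided in the enrichment direction with ties counted
toward the null (conservative); the upstream description of this rule is
truncated mid-sentence, so direction and tie handling are pinned here. The
default p-rule is add-one smoothing, (1 + #null ≥ obs)/(1 + B), so no
reported p is exactly zero; the plain proportion is available. All pairs in
one (sender, receiver, time) stratum share the same permutations — one
permutation scores all combinations — and each stratum's stream is derived
from the global seed and the stratum's position in sorted type/time order,
so results are independent of iteration order. Significance counts use
BH-adjusted p < 0.05 by default; the counting threshold is not specified
upstream and is configurable.

## Synthetic data

Counts are negative binomial via a gamma–Poisson mixture with a shared
dispersion (default 2.0; variance μ + μ²/2) — the standard minimal model for
UMI overdispersion. Per-gene baseline means are gamma-distributed around
`baseline_mean = 1.0` (≈1000 UMIs per cell over 1000 genes), with a
log-normal per-cell library factor (σ = 0.25). Defaults emulate the study
design: 4 time points × 500 cells, 11 cell types at fixed frequencies
(largest-remainder apportionment, so group sizes are exact), 20 markers per
type with log effect 2.0, mitochondrial and hemoglobin gene classes pinned
to expected count fractions of 5% and 0.3%, and a planted doublet rate of
0.06 — doublets are constructed (a cell plus a random partner's counts,
score 1.0 vs. < 0.5 for singlets), not sampled, so the realized rate is
exact.

Spatial spots lie on a square grid, assigned to regions concentrically
(first region innermost = central). Each region's 20-gene program shares
60% of its genes with the linked cell type's markers — large enough for
top-1 hypergeometric recovery at desk scale, configurable down to 0 as a
negative control — with a region log effect of 1.5 and spot depth 5× the
cell depth.

The default ligand–receptor channels plant eight myeloid→TFC-1 pairs with
staggered decaying effect schedules (the flagship Tnf → Tnfrsf1a decays
2.0 → 1.5 → 1.0 → 0.5 across the four ages; others switch off at successive
time points) plus six decoy pairs with no effect. No quantitative decay
rates exist upstream; the schedule is a free parameter chosen to produce a
monotone decline in active channels, and it is recorded per time point in
the generated truth tables. All randomness flows from one seed through
fixed child streams, so identical configurations give byte-identical files.

What the generator does *not* emulate: real library-size and gene-frequency
distributions, ambient RNA, batch effects, spatial smoothness beyond region
blocks, multi-subunit ligand/receptor complexes, or cluster-frequency
drift over time. Passing tests therefore demonstrate correctness of the
*procedures* (filters, statistics, set logic, permutation machinery) and
recoverability of planted structure under a clean generative model — not
performance on real tissue data.

## Problem sizes and determinism

The bundled demo and most tests run at reduced scale (150–250 cells per
time point, 200–600 genes, 200–300 spots, 100–1000 permutations); the
power and recovery experiments use the defaults stated above (e.g. 200
cells/type and B = 1000 for channel power across 20 seeds). These sizes are
the package's validation choices and are recorded in each experiment's
signature. Every pipeline output is plain text with no embedded
timestamps, and the run manifest stores SHA-256 checksums per output file,
so end-to-end determinism is directly checkable by re-running a
configuration.

## Known limitations

- Single-ligand/single-receptor pairs only; complexes are out of scope.
- The MIA background choice materially affects p-values when the two
  universes differ; the intersection default is principled but not unique.
- Empirical p-values are bounded below by 1/(B+1); B = 1000 cannot
  distinguish signals beyond p ≈ 10⁻³.
- The doublet stage trusts the supplied scores; no expression-based doublet
  inference is performed.
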