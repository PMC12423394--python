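# Methods

## Scope and data plane

`isenics` operates downstream of deconvolution: its inputs are
cell-type-specific expression matrices on the TPM scale (genes × samples),
or single-cell matrices (genes × cells), plus a senescence signature and
optional auxiliary gene lists (SASP, immune-related, immune-checkpoint).
Deconvolution itself (e.g. TAPE-style deep-learning deconvolution of bulk
cohorts) is an external step; the package only validates its outputs
(`matrix_concordance`, `nnls_fractions`). Gene identifiers are
case-sensitive symbols with no alias resolution — the data plane is
symbol-keyed TSV/CSV/MTX and GMT throughout. Duplicate gene rows are
collapsed by summation before any scoring, a deterministic,
order-independent rule.

## Scoring engines

**GSVA-style engine.** For gene *i* with expression *x<sub>i·</sub>* across
*n* units, the cross-unit statistic is the Gaussian-kernel CDF estimate
*z<sub>ij</sub>* = Σ<sub>k</sub> Φ((x<sub>ij</sub> − x<sub>ik</sub>)/h<sub>i</sub>) with
bandwidth *h<sub>i</sub>* = sd<sub>i</sub>/4, floored at 1e-8 so
zero-variance genes degrade to a step function instead of erroring.
TPM/counts input is log2(x+1)-transformed first; `kcdf="none"` uses values
directly. Within each unit, genes are ranked by decreasing *z* (ties broken
by stable input order), giving the symmetric rank statistic
*r* = |rank − (G+1)/2|, and a weighted KS-like random walk visits genes in
rank order: an in-set gene steps up by *r*<sup>τ</sup> normalised by the
total in-set weight, an out-set gene steps down by 1/(G−|S|). The
enrichment score is the maximum positive plus the maximum negative walk
deviation (`max_diff`; the signed single largest deviation is available as
`two_sided_max`). Defaults (Gaussian kcdf, τ = 1, `max_diff`) follow the
published GSVA convention; all constants are surfaced in `GsvaParams`.
Degenerate cases are defined, not errors: with no out-set genes the walk
never steps down and the score is 1; a zero total in-set weight yields
zero up-steps.

Because the walk depends only on within-unit rankings of the statistic,
scores are invariant to any strictly increasing transform applied to the
statistic of every gene, and unit-permutation equivariant (the kernel CDF
is itself permutation-invariant). At least 3 units are required for a
meaningful cross-unit CDF.

**AUCell-style engine.** Genes are ranked within each unit by decreasing
expression (stable input order on ties; a seeded random tie rule exists for
parity checks). Over the top *k* = ⌈`top_fraction`·G⌉ ranks, the score is
the step-function area under the cumulative in-set count, divided by the
maximal area (all in-set genes at the very top), so scores live in [0, 1]
and 1 means the in-set genes occupy the top ranks. `top_fraction` defaults
to 0.05, the reference convention; on small gene panels (~100 genes) this
gives a 5-rank window and coarse, heavily tied scores — widen the window
(e.g. 0.25) so it covers the signature size when scoring small simulated
panels. The score is monotone: promoting an in-set gene to a better rank
never decreases it.

**ICSS.** For a signed signature, ICSS = score(positive) − score(negative),
both components computed with the same engine and parameters and retained
on the result for audit; swapping the sets negates the score exactly. For
unsigned signatures ICSS is the single-set score, oriented higher = more
senescent. Signature alignment requires at least `min_overlap` (default 2)
surviving genes per non-empty set; a difference score over singleton sets
is rank-degenerate, hence the floor of 2.

## Grouping and STIME classification

Quartile grouping uses linear-interpolation ("type 7") quantiles — the
default of mainstream statistical environments — with the boundary rule
score ≤ q1 → low, score ≥ q3 → high, which guarantees non-empty extreme
groups for distinct scores; for i.i.d. continuous scores the extreme groups
hold exactly ⌈n/4⌉ units. When q1 = q3 the distribution is degenerate: a
warning is emitted and boundary units are labeled medium. The single-cell
convention takes the top and bottom ⌈fraction·n⌉ units (default 25%) with
stable-order tie-breaks, filling the high quota first.

STIME classification is a strict-majority vote: HSTIME iff more than half
of the evaluated cell subtypes are high, LSTIME iff more than half are low,
MSTIME otherwise (an exact half is MSTIME). The denominator is the number
of cell types in which the sample has a score — deconvolution may omit cell
types per cohort. Quartile thresholds are computed per cell type (pooled
thresholds are available via a flag); within a multi-cancer analysis the
intended unit of analysis is one cohort at a time.

## Association statistics

Spearman correlation uses average-tie ranks; p-values use the
t-approximation for n > 9 and the exact permutation distribution of the
rank statistic for n ≤ 9. Zero variance in a ranked vector is an explicit
`UndefinedCorrelationError`.

SASP concordance reports, per cell type, each expressed SASP gene's
correlation with ICSS and the fraction correlating positively. "Expressed"
means nonzero in ≥ 20% of units (parameterised; the notion is not standard
and this is a deliberate, documented choice). Positivity is ρ > 0
regardless of significance by default, with a significance-filtered variant
by flag. Genes whose correlation is undefined among the expressed set are
excluded from the denominator with a warning.

Co-senescence networks place one candidate edge per cell-type pair with
≥ 3 shared samples, retained at Spearman p ≤ 0.05 (BH-adjusted q when
requested); edge weight is |ρ| and node size is recomputed as the
cumulative incident weight after filtering, so the bookkeeping identity
holds for any edge subset. Matrix concordance between two deconvolved
profiles correlates their per-gene mean expression vectors over shared
symbols — a summary chosen because the per-sample pairing between
independently deconvolved matrices is not otherwise defined.

## Differential expression

The DE engine is deliberately simple and fully specified: linear-scale
fold change (mean_high + 1)/(mean_low + 1) with a pseudocount of 1 TPM to
stabilise low-expression genes, Welch's t on log2(x+1) per gene, BH FDR,
and context presets for the significance cuts (bulk P < .01 ∧ FC > 2;
immune cells P < .01 ∧ FC > 1.2; immunotherapy-screen preset P ≤ .05 ∧
FC > 2). A moderated-variance (limma-style empirical Bayes) engine was
considered and not adopted: the cuts, not the test engine, carry the
definition of the gene lists, and the Welch stand-in is exactly
reproducible. Medium-group units are excluded before testing. Genes with
no variance in both groups are defined (FC from means, p = 1), not errors.
Fold-change cuts are linear-scale (FC > 2 ⇔ |log2FC| > 1).

Fisher's exact overlap test builds the 2×2 in-both / A-only / B-only /
neither table over an explicit gene universe, with the two-sided p summing
hypergeometric probabilities no larger than the observed table's, and the
sample odds ratio (+∞ on a zero cross cell).

## Synthetic cohorts

The generator emulates the statistical structure the scorer assumes:
per-gene baseline log-mean ~ N(2, 1) (natural-log TPM, median ~7 TPM,
spanning roughly 0.5–50 TPM), unit-level log-normal noise with sd 0.5, a
planted binary senescence status per cell type covering 30% of units
(exact count, for stable group sizes), and multiplicative effects on
senescent units: positive-set genes × 2, negative-set genes ÷ 2, SASP
genes × 2. Defaults: 100 genes, 200 units, 3 cell types, a 15-positive /
10-negative signature and 20 SASP genes, all cell types sharing one status
vector (the co-senescence ground truth); `shared_status` accepts pair maps
for partial sharing or `None` for independence. Pseudo-bulk mixes
cell-type profiles at Dirichlet(1) fractions, and an NNLS re-estimator
recovers fractions from noiseless mixtures exactly — a validation tool,
not a deconvolution method.

What the generator does **not** emulate: single-cell dropout, batch
effects, negative-binomial counts (inputs are TPM by construction),
correlated background genes, or deconvolution error structure. Passing
tests therefore demonstrate correctness of the scoring/classification
machinery and its calibration under the stated model, not performance on
real cohorts.

## Numerical and problem-size choices

All randomness flows through explicit integer seeds; simulations are
bit-reproducible. Exact agreement with the brute-force scoring oracles is
asserted to 1e-12. Oracle batteries use matrices up to 6 genes × 5 units
(GSVA) and 20 genes (AUCell); planted-recovery checks use the default
cohort (3 × 100 × 200); null network calibration uses 20 seeds of 5 cell
types × 500 units; DE recovery uses 1000 genes at 50 units per group; the
Fisher-null uniformity check uses a 10,000-gene universe with 3000-gene
sets, because the exact test's p-value is discrete and only approaches
uniformity for large tables. The pipeline writes a SHA-256 manifest and is
hash-reproducible under a fixed config.

## Known limitations

* GSVA constants (kcdf, τ, enrichment statistic) are fixed to the
  published convention since upstream option choices are rarely reported;
  parity with other implementations is rank-level, not bitwise (tie-break
  and kernel details differ across ports).
* The single-cell ICSS defaults to the positive-minus-negative AUCell
  difference; the positive-set-only variant is available by passing an
  unsigned signature.
* No survival modelling, infiltration scoring, communication inference or
  enrichment annotation — those consume ICSS/STIME outputs downstream.
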