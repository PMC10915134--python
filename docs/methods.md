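# Methods

## The scoring model

The package quantifies, per sample, how far a bulk CD138+ expression
profile has drifted from the normal plasma-cell marker programme.  The
statistic operates on within-sample ranks only:

1. **Ranking.** Genes are ordered by expression, descending.  Ties break by
   ascending lexicographic gene identifier, making the ranking a pure
   function of the input.
2. **Running sum.** With F(i) the fraction of signature genes and B(i) the
   fraction of background genes encountered by rank position i, the raw
   enrichment score is ES = F(i\*) − B(i\*) at the position i\* of maximum
   |F − B|, the earliest such position on ties.  ES ∈ [−1, 1].
3. **Permutation normalisation.** ES depends on universe size N and
   signature size m, so it is z-scored against the null of the signature
   placed uniformly at random in the ranking: z = (ES − μ₀)/σ₀ with the
   population σ of the null.  When C(N, m) ≤ 10,000 all placements are
   enumerated; otherwise 1,000 Monte-Carlo placements are drawn (seeded).
   For the default unweighted statistic the null depends only on (N, m)
   and is computed once and shared across samples, which also makes scores
   of identical samples identical by construction.
4. **Orientation.** The PBM score is −z of the plasma signature, so that a
   depressed marker programme (bottom-ranked markers, negative enrichment)
   maps to a *high* malignancy score.  A flag flips the convention.

A weight exponent α ≥ 0 on |expression − sample median| can up-weight the
foreground walk by expression magnitude (α = 0, unweighted, is the
default).  With α > 0 the null is no longer placement-exchangeable across
samples, so gene-label permutations are drawn per sample; this variant is
exposed for sensitivity analysis, not used by the pipeline defaults.
Signature genes absent from the matrix are dropped with a logged count; a
signature retaining fewer than 5 genes (configurable) is an error.

Key consequences of the rank-based construction, verified by the test
suite: invariance under strictly monotone transforms of a sample's values;
z ~ (0, 1) calibration when a signature is placed at random; and strict
monotone growth of the PBM score as marker expression is shifted down,
until the ranking saturates.

## Statistical kernel

Group comparisons use the Wilcoxon rank-sum test (exact by enumeration for
n ≤ 20 without ties, otherwise the tie-corrected normal approximation with
continuity correction).  The ordered-stage trend uses a Cuzick-type rank
statistic T = Σ wᵢRᵢ with equally spaced group scores; its permutation null
has E(T) = (N+1)/2·Σw and Var(T) = N²/(N−1)·var(w)·var(R) (mid-ranks make
the variance tie-corrected), with exact enumeration available for N ≤ 8.
The trend test was chosen to match the nonparametric style of the rest of
the kernel; when labels arrive as an ordered pandas Categorical the
category order defines the trend direction, otherwise first appearance
does.  Fisher's exact test is two-sided by the minimum-likelihood rule.
Multiple testing uses Benjamini–Hochberg step-up.  Gene–score correlation
(Spearman default, Pearson optional) is vectorised across genes with
t-distribution p values; constant genes are reported as r = 0, p = 1.
Set over-representation is a one-sided hypergeometric tail on a
user-supplied universe/target pair.

## Survival machinery

Kaplan–Meier curves and the G-group log-rank test come from lifelines, as
do Cox fits with Efron tie handling (the default).  A compact in-house
Newton maximiser of the Breslow partial likelihood provides the second tie
convention and serves as an independently checkable route; both agree with
a brute-force one-parameter likelihood search to 1e-4 on tie-free data.
Monotone likelihood (complete separation) is reported as a flagged
non-converged result with signed-infinite coefficients (sign from the
score at β = 0), never an exception — a fit with |β̂| > 10 is treated as
separated.  Harrell's C counts a pair as usable when the smaller time is
an event and scores risk ties ½.

Model comparison follows a repeated cross-validation design: 100 repeats
of event-stratified 5-fold splits (stratification avoids event-free test
folds; a failed repeat refolds once with an offset seed before erroring).
Every candidate model sees identical folds, so the 500 held-out
concordance values per model are paired; the reported p value is the
Wilcoxon signed-rank test on the per-fold differences.  Pairing per fold
was chosen over pooling the two distributions because the fold-to-fold
variation is shared across models and would otherwise swamp the
between-model signal.

Staging systems are encoded from their standard definitions with fixed
unit conventions — β2-microglobulin in mg/L, albumin in g/dL, LDH against
its upper limit of normal: ISS (III if B2M ≥ 5.5; I if B2M < 3.5 and
albumin ≥ 3.5; else II), R-ISS (I = ISS I, no high-risk cytogenetics, LDH
normal; III = ISS III with high-risk cytogenetics or high LDH; else II)
and the additive R2-ISS points (ISS II: 1, ISS III: 1.5, del17p: 1, high
LDH: 1, t(4;14): 1, gain1q: 0.5; groups Low / Low-Int / Int-High / High at
0, 0.5–1, 1.5–2.5, 3–5).  Median splits send values equal to the median to
"low", deterministically.  Event-free survival reuses the identical
machinery on (efs_time, efs_event); there is no separate code path.

## Classification

AUC is the tie-corrected Mann–Whitney probability (ties ½), identical to
the trapezoidal area under the empirical ROC.  Operating cutoffs maximise
Youden's J over midpoints between adjacent distinct scores — a cutoff can
therefore never coincide with an observed score, making strict-versus-weak
comparison conventions immaterial; J ties resolve to the smallest cutoff.
Stage discrimination reports the AUC of every ordered (earlier, later)
stage pair with the later stage as positive class.  Progression evaluation
chains ROC → Youden cutoff → 2×2 high/low-by-outcome table → Fisher's
exact p and the progression rate ratio.

## Immune-microenvironment profiling

Whole-bone-marrow profiles are scored with the same signature engine, one
marker set per immune cell type, keeping the pipeline self-contained
rather than depending on a reference-profile deconvolution.  Stromal cell
types (osteoblast, osteoclast, adipocyte) are excluded by name.  A
minimum-mean-abundance filter (default 1%) applies only to fraction-scale
inputs (non-negative rows summing to ≤ 1) that users import from external
deconvolution tools; applying it to score-scale data is a guarded error
because scores carry no percentage scale.  Retained cell types are
standardised to mean 0, sd 1 (sample sd) and patients are clustered by
Ward/Euclidean agglomeration cut at k = 5.  Ward linkage is deterministic,
so the clustering needs no seed; labels are renumbered C1…Ck by descending
size, deliberately outcome-blind — the association report, not the label,
says which cluster survives best or worst.

## The synthetic-data generator

Every generator is a pure function of (parameters, seed).  A latent
malignancy level λ ∈ [0, 1] per sample drives all coupled outputs:

- **Expression** (defaults: 2,000 genes, 50 markers, Δ = 2 log2-units,
  noise sd 0.5): background means μ_g ~ N(6, 1.5) on the log2 scale,
  markers at baseline +2, shifted by −λΔ (80% of markers) or +λΔ (20%,
  modelling two-sided perturbation of the marker programme).
- **Survival**: T ~ Exponential(rate·exp(η)) with η = βλ (or a group
  contrast, or any supplied per-sample log-hazard); independent uniform
  censoring whose upper bound is calibrated by root-finding so the
  expected censoring fraction matches the target (default 30%).
- **Stages**: thresholds (0.1, 0.3, 0.5, 0.7) on λ map to the ordered
  Healthy → MGUS → SMM → NDMM → RRMM vocabulary.
- **Mutations**: driver carriage ~ Bernoulli(logistic(a + bλ)) per gene;
  extra nonsynonymous burden ~ Poisson(exp(c + dλ)) spread over passenger
  gene names.
- **Whole bone marrow**: per-sample cell-type fractions from a Dirichlet
  whose concentration combines k = 5 planted cluster boosts with an
  exp(coupling·(λ − ½)) tilt (CD8 T up; neutrophils, mast cells,
  eosinophils and resting NK down); expression is the fraction-weighted
  mixture of archetype profiles, each over-expressing its own markers.
- **Progression cohort** (358 samples, 39 progressors): non-progressor
  scores ~ N(0, 1), progressors ~ N(δ, 1) with δ = 1.07, giving the
  closed-form AUC Φ(δ/√2) ≈ 0.776 against which the empirical ROC is
  checked.

Cohort sizes mirror the targeted study designs loosely (a 762-patient
newly-diagnosed cohort, the 358/39 MGUS cohort) so tests exercise
realistic shapes at desk scale.  What the generator does **not** emulate:
microarray probe effects and probe-level summarisation, batch structure,
heavy-tailed or count noise, real marker-gene identities, correlated
cytogenetic architecture, or informative censoring.  Passing tests
therefore demonstrate internal statistical correctness and end-to-end
recoverability of planted signal — not performance on any real cohort.

### The hazard-recovery harness

Parameter recovery for the survival arm is defined on the groups actually
compared: a cohort is generated, scored, median-split on the PBM score,
and the known group log-hazard (log 1.72) is applied to that high/low
contrast before Cox estimation.  With the contrast instead applied to the
*latent* median group, the ~6% of samples near the median that score to
the other side attenuate the estimated HR — a mismatch between estimand
and target, not an estimation error; the chosen design keeps the estimand
well-defined while still exercising generation, scoring, splitting and
fitting end to end.  Measured behaviour: ~95/100 CIs cover the true HR,
and the null (no effect) mean log-HR is within ±0.01 of zero.

## Numerical conventions and degenerate inputs

- Permutation z uses the population sd of the null; a zero-spread null is
  an error, as are: constant score vectors in a median split, all-censored
  log-rank inputs, constant Cox covariates, one-class ROC labels,
  zero-margin Fisher tables, constant columns in z-normalisation.
- Duplicate expression rows collapse by per-sample maximum (a common
  microarray convention; the rule is logged and idempotent — how the
  source cohorts summarised probes to genes is not documented, so this is
  a declared convention of the package).
- Gene identifiers match as case-sensitive trimmed symbols; no alias
  resolution, keeping I/O deterministic.
- The nonsynonymous vocabulary is the standard MAF set (missense,
  nonsense, nonstop, frame-shift ins/del, in-frame ins/del, splice site,
  translation start site); unknown classification strings are excluded
  with a log message, or raise in strict mode.
- Reports flag significance at a single two-sided α = 0.05; flags never
  drive filtering.  All report numbers are pure functions of config and
  seeds; wall-clock metadata lives in a separate block so reruns compare
  byte-identically on the results.

## Problem sizes used by the checks

The acceptance-style checks run at: 100 scoring-oracle instances (≤ 50
genes); 200 samples for null calibration and malignancy tracking; 100
replicate cohorts of n = 800 for HR coverage; n = 600 with 100×5-fold CV
for the model comparison; n = 500 for the stage trend; n = 2,000 per shift
for binormal AUC recovery; n = 250 with k = 5 for immune-cluster recovery.
These sizes give the statistics enough resolution for the stated bands
while keeping a full run in the single-digit minutes on one CPU.

## Known limitations

- The permutation null is placement-based (gene-label exchangeable); a
  cohort-wide empirical null is not implemented.
- No proportional-hazards diagnostics beyond the separation guard; no
  time-dependent covariates or competing risks.
- The immune-composition estimate is a score, not a fraction; cross-sample
  comparability rests on the z-normalisation step, and the 1% abundance
  filter cannot apply to it.
- The R2-ISS point groups assume complete cytogenetic flags; any missing
  flag propagates to a missing group rather than being imputed.
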