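# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, the numerical conventions that had
to be pinned for reproducibility, and what the synthetic cohort does and
does not emulate.

## Synthetic cohort

The generator produces the study design the analysis assumes: 70
participants split 7 SGA / 58 AGA / 5 LGA, three samples each, at
gestational ages drawn from truncated normals inside the visit windows
12–19, 21–27 and 28–34 weeks (per-visit means/SDs follow the cohort's
demographic table: 15.7 ± 1.2, 23.4 ± 1.0, 31.3 ± 0.97). Birth-weight
z-scores are drawn per group from normals with the group's reported mean
and SD (−1.9 ± 0.35, −0.12 ± 0.58, 1.7 ± 0.30), truncated to the group's
defining interval so the label invariant (z > 1.3 ⇒ LGA, z < −1.3 ⇒ SGA)
holds by construction — untruncated draws at these means/SDs would
occasionally cross the cutoffs. BMI is N(24.1, 2.8²) kg/m², nulliparity
Bernoulli(0.5), fetal sex Bernoulli(0.44 female); covariates are not
confounded with group by default.

The log₂ abundance of protein g in sample (i, v) is

    b_g + f_g(GA) + u_i + δ_g(group, v) + ε,

with baseline b_g ~ N(10, 1.5²) log₂ RFU, a smooth trend
f_g(GA) = a₁(GA−23) + a₂(GA−23)² + A·sin(2πGA/P + φ) with a₁ ~ N(0, 0.03),
a₂ ~ N(0, 0.003), amplitude A = 0.1 and period P = 20 weeks (a random
quadratic plus a sinusoid: smooth, nonlinear, and recoverable by a
spline of basis dimension ≤ 6), a participant intercept u_i ~ N(0, 0.3²)
and noise ε ~ N(0, 0.25²). The within-participant correlation implied by
the 0.3 log₂-unit intercept SD is a free choice — no published estimate
exists for this design — and is set where repeat plasma proteomics
typically lands (intra-class correlation ≈ 0.6 against the 0.25 noise).
Group effects δ are added only to flagged proteins: by default 16 proteins
carry an LGA effect and 4 an SGA effect of +1 log₂ unit, constant across
visits (a per-visit effect vector is available to emulate visit-specific
significance patterns). The default protein count is 500 — the full assay
scale (~4565 post-QC proteins) is available by configuration but desk-scale
testing does not need it; 16/500 and 4/500 keep the differential fractions
of the motivating analyses roughly proportional.

What the generator does **not** emulate: aptamer cross-reactivity,
plate/batch effects, limit-of-detection censoring, per-protein variance
heterogeneity (noise SD is shared, so the empirical-Bayes prior
degenerates to d₀ = ∞ on generator output; the moderation path is
exercised by direct variance simulations in the tests), and
covariate–group confounding (available behind a switch via configuration
of per-group parameters). Passing tests on this cohort therefore
demonstrate correctness of the machinery, not robustness to assay
artefacts.

Outliers are injected multiplicatively: ⌊rate·entries⌋ uniformly chosen
cells times a factor (> 1, default 50) — a heavy-tailed spike model that
winsorization is designed to absorb.

## Preprocessing

Order is fixed: winsorize → log₂ → reference fit → MoM. Winsorization
clips each protein at 2 × its 98th percentile, computed per protein across
all samples and visits pooled (a single preprocessing pass; the per-visit
alternative is not offered). The quantile uses linear interpolation
between order statistics (NumPy's default, "type 7"); the convention must
be pinned because the clip threshold sits on an order-statistic knife
edge. Clipping to exactly the threshold makes the operation idempotent:
re-computed thresholds can only rise, so no new exceedances appear.

The gestational reference curve is a B-spline smooth fitted to the AGA
samples only: basis dimension k ∈ {3, 4, 5, 6} (cubic for k ≥ 4, quadratic
for k = 3, interior knots at age quantiles), second-difference penalty on
the coefficients, smoothing parameter chosen by GCV over a log-spaced grid
that includes λ = 0 (the unpenalized regression spline, also available
directly for exact small-sample reproducibility). k is selected by highest
plain r² = 1 − RSS/TSS on the AGA training points, ties toward smaller k;
a constant response is assigned r² = 0 by convention. Whether the original
GAM machinery used plain or adjusted r² is not documented; plain r² is the
simpler contract and the k choice is insensitive on smooth signals. With
fewer than k_max + 2 distinct AGA ages the fit falls back to a
least-squares line with a warning.

MoM subtracts the fitted curve from every sample's log₂ value — SGA and
LGA included, which is the point: their deviations are measured against
the AGA norm. Ages outside the AGA fit range use linear continuation with
the boundary slope, keeping extrapolation bounded for extreme gestational
ages. Because the penalty null space contains constants, residuals are
exactly orthogonal to the intercept at any λ, so AGA MoM values average
to ~0 per protein by construction.

Per-visit PCA centers columns but does not scale them: MoM values already
share a log₂-deviation scale, and unit-variance scaling would up-weight
the flattest proteins.

## Clinical comparisons

Welch's t (unequal variances, Welch–Satterthwaite df) from raw vectors or
summary statistics; the degenerate both-variances-zero case returns p = 1
for equal means. Fisher's exact test on 2×2 and 2×3 tables enumerates all
tables with the observed margins; the two-sided p sums the multivariate
hypergeometric probabilities of tables no more likely than the observed
one, with relative tolerance 1 + 1e−7 on the comparison — the convention
of the standard R implementation, needed to reproduce published values on
knife-edge tables (the enumeration's probabilities are asserted to sum to
1 within 1e−9 on every call). Spearman's ρ uses mid-ranks and the
t-approximation p-value at all n, matching the helper the motivating
analysis used at these sample sizes; an exact permutation p is available
for n ≤ 9. Boundary z-scores of exactly ±1.3 classify as AGA (strict
inequalities define the extreme groups).

## Moderated differential inference

Per protein, OLS of MoM on intercept + effect column + BMI + nulliparity.
Group contrasts are fitted on the corresponding two-group subset (cases +
AGA) rather than inside a three-group design: this reproduces pairwise
moderated t-tests without forcing a variance shared across all three
groups beyond the empirical-Bayes prior. Models are per visit; no pooled
longitudinal model is fitted (the scientific target is the per-visit
contrast, and the cohort design gives no basis for a shared
cross-visit effect).

Moderation follows the published moment-matching formulation: with
s²|σ² ~ σ²χ²_d/d, the statistic e = log s² − ψ(d/2) + log(d/2) has mean
log σ²; matching mean and variance of e across proteins to the
digamma/trigamma expressions of a scaled inverse-χ²(d₀, s₀²) prior gives
s₀² and d₀ (trigamma inverted by monotone Newton iteration). If the
observed variance of e does not exceed the χ² sampling contribution the
prior is degenerate: d₀ = ∞ and s₀² is the geometric mean of the observed
s², so identical variances pass through unchanged. Posterior variances
are the convex combination (d₀s₀² + ds²)/(d₀ + d); moderated t uses
d₀ + d degrees of freedom (normal when d₀ = ∞). The robust/winsorized
variant of the prior fit is deliberately omitted — the motivating analysis
used defaults. The implementation agrees with the reference R
implementation to ~1e−10 on heterogeneous-variance data (tested via
Rscript when available).

Proteins with numerically zero residual variance are excluded from the
prior fit and from the BH multiplicity count and reported with NA
statistics. BH is the plain step-up with enforced monotonicity;
significance is declared at q < 0.05.

## Prediction

LOO-CV is the outer loop; everything else nests inside it. Screening
ranks proteins by moderated-t p-value computed on the training fold only
(ties: |t| descending, then id — which also makes the 5-protein list a
prefix of the 50-protein list). Elastic-net models standardise features
with training-fold means/SDs and tune (α, λ) on a 10 × 10 grid
(α ∈ {0, 1/9, …, 1}; λ log-spaced over [1e−3, 1e1]; logistic elastic net
with C = 1/(nλ)) by inner stratified 5-fold CV maximising ROC-AUC — the
only reading of "tuning + LOO" that is leakage-free. Random forests use
500 trees, √p features per split, no class weighting. Fold-level RNG
seeds derive deterministically from (master seed, fold index), so a spec +
seed pair fixes the entire CvResult bit-for-bit.

A deliberate-leakage switch (screening once on all samples before CV)
exists purely as a negative control: on pure-noise data it inflates the
apparent AUC to ~0.9 while the nested design stays at chance. The nested
design's null AUC is itself slightly below 0.5 for prevalence-sensitive
learners (the held-out sample's class shifts the training prevalence — a
known LOO artefact, strongest for the penalised-regression models);
bootstrap-averaged forests are nearly unbiased, which is why the
null-behavior test suite uses them.

Metrics: ROC-AUC by the Mann–Whitney rank formulation with tie
correction; its CI from the DeLong placement-variance estimator (default
level 0.95, configurable, e.g. 0.98); PR-AUC by interpolation-free step
summation (equal to average precision); F1 and balanced accuracy at
probability threshold 0.5 with the minority class positive. Threshold
0.5 is a convention, not an optimum — with 5 cases against 58 controls a
prevalence-aware threshold would change F1 substantially, which is
exactly why the threshold-free AUCs lead the report. Note that a
"balanced accuracy of 0" is impossible under this (standard) definition —
its floor is 0.5·specificity; the package reports the standard quantity.

## Over-representation analysis

Upper-tail hypergeometric p per gene set after intersecting set members
with the supplied background; BH across all tested sets (not the
collection size); retention at overlap ≥ 3 and q < 0.2. The "simplify"
step is a greedy set-similarity filter — scan by ascending p, keep a term
iff its Jaccard similarity with every kept term is below 0.7 — a
deliberate replacement for ontology-topology-aware semantic simplify:
it needs no GO graph, is deterministic under the stated sort, never drops
the global minimum-p term, and the cutoff is configurable. Term clustering
is average linkage on 1 − Jaccard with a flat cut at 0.8; the merge tree
exports as Newick.

## Trajectories

Per-group curves are fitted on winsorized log₂ RFU (not MoM — the display
target is the abundance level itself, and consistency with preprocessing
argues for the winsorized scale), one spline per group with the same
engine and k-selection as the reference curves, sampled on a 100-point
grid over the group's observed age range. Groups with fewer than
k_max + 2 distinct ages are skipped with a warning (15 points from 5
participants × 3 visits suffice). No uncertainty bands are drawn.

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation between order statistics throughout.
- Spline systems solved with a 1e−10 ridge jitter only if singular; GCV
  effective df via direct trace.
- Fisher enumeration caps at 10⁷ candidate tables and supports 2×C,
  C ≤ 3, only.
- bh_adjust rejects p outside [0, 1]; empirical-Bayes moderation requires
  ≥ 10 positive finite variances and common residual df ≥ 1.
- evaluate_predictions refuses single-class truth; inner CV re-stratifies
  with fewer folds when a class has fewer members than folds.
- All generator, CV and simulation randomness flows from explicit seeds
  (NumPy Generator / SeedSequence); no global RNG state is touched.

## Problem sizes in the test and acceptance runs

Test fixtures use 40–100 proteins and the study's 70-participant design;
the distributional suites use 500 proteins with n = 60 (CV null
behavior), 200 replicate datasets (FDR control), 2000 proteins × 50
replicates (prior recovery) and 100 replicates (ORA null). These sizes
were chosen so each suite gives stable Monte-Carlo verdicts at desk
scale; the full assay scale is exercised only through configuration,
not in routine runs.

## Known limitations

- The spline engine is a single smoother, not a full GAM framework: one
  covariate, no tensor products, no automatic basis-dimension diagnostics
  beyond the r² selection rule.
- The elastic-net inner tuning maximises ROC-AUC; with 5-vs-58 imbalance
  the inner folds contain very few cases and the chosen (α, λ) are noisy.
- ORA treats gene sets as flat sets; parent/child relations between
  ontology terms are invisible to both the test and the simplify step.
- The quality-filtration step of real assay data is modelled only as a
  user-supplied pass-list, since its criteria are not public.
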