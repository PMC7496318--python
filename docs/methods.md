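# Methods

## The trait and its measurement

The trait throughout is relative segment position: the distance from the
larva's anterior tip to the anterior border of each abdominal denticle
belt (A1..A8), divided by total body length.  It is scale-free — a larva
twice as long with proportionally placed borders has identical relative
positions — and the pipeline preserves that invariance end to end
(pixel size and image rotation cancel; all comparisons run on
fractions).

Image measurement standardises each dark-field image before reading
positions.  Segmentation uses a three-class multi-Otsu threshold
(background / body / belt) and keeps the largest connected region;
orientation rotates the region's principal axis horizontal and decides
anterior by body thickness (the head end is tapered).  Belt borders are
found on the column-wise mean intensity over body rows, Gaussian-smoothed
(σ = 2 px): the eight most prominent peaks are belts and each border is
the sub-pixel half-maximum crossing of its peak.  The half level uses
the body-plateau intensity (median of the inter-belt valley minima) as
the baseline rather than a local minimum: local minima near the body
ends sit in the dark taper and would bias the outermost borders by
1–2 px.  A half-pixel shift converts crossings between pixel centres to
the continuous border coordinate.  The procedure is parameter-free apart
from the smoothing width and has no contrast calibration, so it is
stable under global intensity changes.  Manual image clean-up is
replaced by an optional radius-1 median despeckle.  On real images the
anterior cue would preferably be the posterior spiracles; thickness
tapering is a synthetic-data-validated stand-in and a known limitation.

## The synthetic cohort model

A larva is nine inter-boundary spans (anterior tip→A1, A1→A2, …,
A8→posterior tip).  Per individual each mean span is multiplied by
`exp(ε_j + g_j)` where ε_j are independent Gaussian log-perturbations
and g is a smooth axial field (Gaussian process, squared-exponential
kernel, length-scale 0.25 body lengths) sampled at the span midpoints;
spans are renormalised to the drawn body length, so body size and
position are decoupled.  The smooth field is what produces
within-individual correlations that decay with inter-segment distance —
the structure the correlation analyses probe.  Defaults (per-span
σ = 0.02, field amplitude 0.025) were chosen so the within-species CV of
relative position is ≈ 0.03 and roughly flat along the body, which is
the regime reported for real larvae.

Two span-specific noise factors shape the terminal regions:

* the tail span (A8→tip, 6× noise) enters every relative position
  through the shared denominator, so it acts as a common factor — this
  flattens the CV profile (posterior positions are otherwise pinned by
  the renormalisation);
* the A7→A8 span (8× noise) moves only the A8 border, making A8's
  position shift more independently of the other segments, again a
  reported feature of real cohorts.  With these factors the generator
  reproduces (i) flat CV ≈ 0.028, (ii) positive correlations decaying
  with separation, and (iii) lower correlations for A8-involving pairs
  at matched separations.

Between-species structure: each species' mean boundaries are the grand
mean plus two components — a posterior-growing gradient (the dominant
axis, giving PC1 ≈ 89% of individual-level variance and deviations that
grow toward A8) and a sign-changing "shape" component so neighbouring
segments can shift in opposite directions in some species.  One species
sits near the grand mean, one has a strongly anterior-shifted A8 border
(long tail region, the cactophilic phenotype), one a posterior-shifted
A8 border.  Mean body lengths (870–1150 µm) are assigned independently
of the boundary offsets, so length–difference regressions are null by
construction.  Cohort sizes are drawn uniformly from 105–145.

Belt posterior borders sit at a fixed 0.35 of the local inter-boundary
span — arbitrary but fixed, so width metrics have a known ground truth.

The generator does **not** emulate: measurement failure modes of real
microscopy (debris, touching larvae, uneven illumination), biological
covariates (temperature, staging, egg size), or non-Gaussian trait
variation.  Tests passing on synthetic data therefore validate the
pipeline's correctness and calibration, not the biology of any real
dataset.

## Frequentist battery

The interaction ANOVA uses type-I (sequential) sums of squares on
`p ~ species + segment + species:segment`, matching the classical
`lm`/`aov` treatment of a balanced-ish layout.  Its calibration test
uses a dedicated i.i.d.-noise null generator: the cohort generator
deliberately violates the model's independent-errors assumption (shared
within-larva factors), so it cannot be used to check the F-test's
nominal size.

Tukey HSD per segment pools the within-group mean square across species
and applies a single studentized-range criterion; unbalanced groups use
the harmonic mean of all group sizes (the convention of the classical
HSD routine).  The cross-check path is Welch t-tests with a global
Bonferroni factor of (species pairs × segments) — 66 × 8 = 528 at full
size.  Welch was chosen over the pooled t because cohort sizes differ
(105–145) and variance homogeneity is not guaranteed.  On balanced
instances the Tukey indicators are verified against an independent
studentized-range implementation and against published critical values.

The "corrected total" divides the overall count of significant
(segment, pair) differences by the number of segments, making counts
comparable before and after removing a terminal region.  End removal
recomputes positions as: without A8+tail, `p' = X_i / X_A8` (i = 1..7);
without head+thorax, `p' = (X_i − X_A1) / (Y − X_A1)` (i = 2..8).  These
formulas are fixed by the requirement that positions rescale to the
truncated body.

Within-species correlations are Pearson correlations of raw
per-individual relative positions between segment pairs (centering
cancels in r, so this equals correlating deviations from the species
mean).  Anatomical distance between two segments is the absolute
difference of their species-mean positions.

## The evolutionary model

Species-mean positions evolve on a fixed rooted ultrametric tree (depth
scaled to 1) under multivariate Brownian motion: the increment on branch
*b* has covariance `t_b · r_b · Σ`.  Implemented clocks: strict
(r ≡ 1), UCLN (log-rates i.i.d. normal — episodic rate change), ACLN
(log-rates diffuse along the tree with variance ν per unit time), and a
per-segment UCLN (independent branch rates per trait).  Identifiability:
σ² and the rates enter only as a product, so UCLN/strict log-rates are
constrained to mean zero (enforced exactly by exchange-type proposals
that perturb two branches in opposite directions); σ² then carries the
scale.  ACLN is left unconstrained, anchored by its root value.

Priors (configurable): per-segment σ² lognormal with median 0.01 and
s.d. 1 on the log10 scale — position changes of a few percent of body
length over the tree's depth; s_r ~ Exponential(mean 0.587) (a standard
weakly-informative relaxed-clock choice: the prior median rate ratio
between branches is modest but the tail allows strong heterogeneity);
ν ~ Exponential(1); root state uniform on (0,1) per segment.

Likelihood: the marginal (pruning) likelihood is computed by
Felsenstein's contrast algorithm in O(tips) — each cherry contributes a
Gaussian contrast, the node collapses to a precision-weighted value with
extra effective length v₁v₂/(v₁+v₂).  With `root="integrated"` the root
is marginalised under an improper flat prior (the REML/contrasts
likelihood, equal to analytically integrating the root out of the dense
multivariate normal); with a root vector the final term is the root
node's Gaussian.  Both paths are property-tested against dense-MVN
oracles to 1e-8.

Sampling: Metropolis-within-Gibbs on the augmented state.  Internal node
states have exact Gaussian full conditionals (precision-weighted over
the three adjacent branches) and are Gibbs-updated; the root adds the
box prior by rejection.  σ² and the hyperparameters get log-scale
random-walk moves; rates get the centred exchange moves.  Defaults for
paper-scale runs are 100k iterations, thin 50, 10% burn-in; the test
suite uses 1.5k–3k iterations on 12-tip problems, where the sampler's
integrated autocorrelation is short (the 2-tip posterior matches a
closed-form oracle by KS, and strict-clock σ² credible intervals achieve
nominal coverage at these lengths).  Effective sample sizes are computed
for every scalar parameter and a warning is attached below 200.

Ancestral states, per-branch normalised change `c_b = |x_child −
x_parent| / t_b` (pooled over posterior samples for the
distribution-of-changes view; posterior means per branch for tree
colouring), and cross-segment rate correlations (Pearson r of
posterior-mean log branch rates between per-segment fits, paired with
anatomical distance) are all summaries of the same posterior.  Note that
under Brownian motion `c_b` scales like √(r_b/t_b), so rankings of
posterior-mean change are only comparable between branches of similar
length.

Marginal likelihoods use stepping-stone sampling with β_k = (k/K)^(1/0.3)
and warm-started stones; the β = 0 stone samples the (proper) prior
exactly.  MC error comes from a per-stone delta-method estimate with
ESS-corrected sample sizes.  `n_stones=1` degenerates to the
harmonic-mean family and is flagged unreliable.  Tip measurement error
is ignored by default (species means are the data); a known per-tip SE
can be supplied and inflates terminal-branch variances (diagonal Σ
only).

## Rate-correlation generator

For the decay-of-rate-correlations check, segments are simulated under
multivariate BM whose trait correlation matrix decays with index
separation (squared-exponential, length-scale 2 segments) plus shared
UCLN branch rates.  Per-segment scalar fits then see correlated branch
increments and recover correlated rates.  A generator that correlates
only the rate *magnitudes* (not the increments) was tried first and
rejected: with one scalar increment per branch the χ²₁ realisation noise
attenuates estimate correlations below detectability on a 12-tip tree.

## Problem sizes and numerical choices

Validation experiments run at: 200 random ≤6-tip instances for the
likelihood oracle; 50 replicates for σ² coverage; 20 for UCLN rate
recovery; 100 larvae for the image round-trip; 1000 fits for ANOVA
calibration (replicate seeds are spawned from a `SeedSequence` —
consecutive integer seeds were measurably correlated across replicates);
100 instances for the Tukey oracle; 10 cohorts and 5 tree replicates for
the two decay trends.  These sizes give Monte-Carlo error comfortably
inside each check's tolerance.  Trees with a branch shorter than 1e-3
are excluded from oracle comparisons (the dense covariance becomes
ill-conditioned; the pruning side is unaffected).  All randomness flows
from explicit per-operation seeds; no global random state is used.

## Known limitations

* Anterior-end disambiguation on real images relies on body taper only.
* The within-species generative model is a stand-in: the real
  developmental covariance structure is unknown beyond its qualitative
  features, and no conclusion should rest on its specific parameters.
* Full (non-diagonal) Σ estimation (``correlations=True``) uses the
  separation strategy — per-segment rates plus a sampled correlation
  matrix under a uniform prior over positive-definite correlation
  matrices, with pairwise random-walk moves.  With 12 tips the
  correlation posterior is strongly attenuated toward zero for weakly
  informed pairs; the per-segment-fit route is the default for the
  rate-coordination analysis.
* The tree is consumed as fixed input; uncertainty in the phylogeny is
  not propagated.
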