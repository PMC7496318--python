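# segmorph

Morphometrics and phylogenetic comparative analysis of larval segment
position in *Drosophila*.

First-instar *Drosophila* larvae carry eight abdominal denticle belts —
transverse rows of cuticular bristles whose anterior borders proxy the
segment borders.  Scaling each border's distance from the larva's
anterior tip (*X*) by total body length (*Y*) gives the **relative
segment position** *p = X / Y*, a robust developmental trait that
nevertheless varies measurably between species.  `segmorph` provides the
full analysis chain for asking how that trait varies and evolves:

1. **`segmorph.imaging`** — measure *X* and *Y* from dark-field images:
   segment the larva, rotate it horizontal (anterior left), and detect
   belt borders as sub-pixel half-maximum crossings of the axial
   intensity profile.
2. **`segmorph.morpho`** — relative positions, terminal-region removal
   (A8+tail, head+thorax), per-species means and 95% CIs, deviations
   from the across-species mean, coefficients of variation, belt widths,
   and PCA of mean-centred positions.
3. **`segmorph.stats`** — the species × segment interaction ANOVA,
   all-pairs Tukey HSD per segment (harmonic-mean Tukey–Kramer), Welch
   t-tests with a global Bonferroni correction, difference counting with
   the ÷(number of segments) correction, within-species
   correlation-versus-distance profiles, and body-length analyses.
4. **`segmorph.phylo`** — Bayesian inference of trait evolution on a
   fixed ultrametric phylogeny under (multivariate) Brownian motion with
   relaxed morphological clocks.  The increment along branch *b* is
   Gaussian with covariance *t_b · r_b · Σ*; branch-rate multipliers
   *r_b* follow a strict, uncorrelated-lognormal (UCLN), or
   autocorrelated-lognormal clock.  A Metropolis-within-Gibbs sampler
   returns posteriors for rates, branch multipliers and ancestral node
   states; stepping-stone sampling estimates marginal likelihoods for
   clock-model comparison.
5. **`segmorph.simulate`** — synthetic everything: random ultrametric
   trees, Brownian trait histories with known branch rates, larval
   cohorts whose within-species noise reproduces the distance-decaying
   segment correlations, and rendered dark-field images with pixel-level
   ground truth.  Every downstream stage is testable without any data
   download.

## Worked example

```python
import segmorph as sm

# a 12-species synthetic study (105-145 larvae per species)
df  = sm.simulate_study(seed=1)
rel = sm.relative_positions(df)

counts = sm.count_and_correct(sm.tukey_pairwise(rel, alpha=0.05))
print(counts["total"], round(counts["corrected_total"], 2),
      counts["n_pairs_all_segments"])
# 274 34.25 11

pca = sm.pca_segments(rel)
_, mean_cv = sm.coefficient_of_variation(rel)
print(round(100 * pca.variance_explained[0], 1), round(mean_cv.mean(), 3))
# 89.3 0.028
```

274 of the 528 per-segment species-pair comparisons differ at α = 0.05
(34.25 after dividing by the 8 segments); 11 of the 66 species pairs
differ at *every* segment.  PC1 of the mean-centred positions carries
89.3% of the variance and loads on the posterior segments, while the
within-species coefficient of variation stays low (≈ 0.028) along the
whole larva — position is precise everywhere even though the posterior
shifts the most between species.

Fitting the evolutionary model on species means:

```python
tree = sm.simulate_tree(12, seed=1, labels=sorted(df.species.unique()))
tips = rel.pivot_table(index="species", columns="segment", values="p")
model = sm.SegmentEvolutionModel(tree, tips,
                                 rate_model=sm.BranchRateModel("ucln"))
res = model.fit(n_iter=20_000, thin=10, seed=7)
print(res.summary().head(3))           # sigma2 per segment, s_r, branch rates
anc = res.ancestral_states()           # per-node posterior mean + 95% CI
changes = res.branch_changes()         # |Δp| / t per branch and segment
```

A command-line interface mirrors the stages
(`segmorph simulate | measure | morpho | stats | phylo | run`); a full
configured run is `segmorph run --config run.yaml`.

Deposited measurement tables (one row per larva with per-segment
anterior/posterior columns) load through `segmorph.io.load_measurements`,
which converts them to the tidy layout the pipeline uses; place such a
table at `data/deposited/segment_measurements.csv` to run the
reproduction checks in `tests/test_acceptance.py`.

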