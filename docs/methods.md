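# Methods

`oneirolex` implements a two-track quantitative analysis of verbal reports
of dreams and waking experiences: a data-driven *lexical domain* track that
discovers semantic clusters in a word-embedding space and scores every
report against them, and a hypothesis-driven *semantic dimension* track
that aggregates multi-rater 1–9 Likert scores.  Both tracks feed a common
mixed-effects inference layer with permutation-based significance for the
dream-versus-wake contrast.

## Lexical domain discovery

**Similarity matrix.** All lemma embeddings (content words only; the
package consumes pre-lemmatized input) are compared by cosine similarity;
negative cosines are clipped to zero and the diagonal fixed at 1, giving a
symmetric non-negative matrix `S`.

**NNMF and rank selection.** `S` is factorized as `S ≈ W·H` with
non-negative factors by alternating least squares: each sweep solves the
unconstrained least-squares problem for one factor and projects negative
entries to zero, starting from a non-negative double-SVD (NNDSVD-ar)
initialization whose zero fills are seeded per repetition.  The rank is
chosen by masked cross-validation: 10% of the off-diagonal cells (sampled
in the upper triangle and mirrored, so `S` stays symmetric; the constant
diagonal is never masked) are hidden, the factorization is fitted with the
hidden cells treated as missing — they are imputed with the current
reconstruction before every sweep, an EM scheme that minimizes squared
error over observed cells only (a zero-fill variant is available) — and
scored by RMSE on the hidden cells against the original values.  All
candidate ranks see the same masks within a repetition (a paired design
that removes mask-to-mask variance from rank comparisons); the selected
rank minimizes the mean RMSE over repetitions (the median curve is also
reported).  Defaults: 500 max iterations, relative objective tolerance
1e-6, 50 repetitions at full scale (8 at desk scale, which testing showed
is already stable for well-separated structure).

**Domain embeddings and macro-categories.** Each component is summarized
by the mean embedding of its 20 highest-`H` lemmas (boundary ties broken
lexicographically, for determinism).  Components with an all-zero `H` row
are dropped with a warning.  Macro-categories come from classical
(Torgerson) MDS of the domain-embedding cosine dissimilarities to two
dimensions, followed by k-means (1000 restarts) for each candidate cluster
count in `2..min(10, n_domains − 1)`; the count maximizing the mean
silhouette wins.  Two degeneracy guards: if all domain embeddings are
nearly identical (max chordal distance < 0.05) or no candidate reaches a
mean silhouette of 0.05, the result is flagged `no_macro_structure` — note
that k-means on pure noise still produces a *positive* silhouette, so the
scale guard, not the silhouette, catches the identical-embeddings case.

## Report scoring and binarization

**Lemma-by-domain matrix.** Cosine similarities between every lemma and
every domain embedding are clipped at zero and sparsified per domain at a
knee-point cutoff: on the descending sorted curve of positive similarities,
the knee is the point of maximum perpendicular distance from the chord
joining the first and last points (first index wins ties).  Surviving
entries are normalized twice — within domain (columns sum to 1), then
within lemma (rows sum to 1) — so a lemma loading on exactly one domain
carries weight exactly 1 there, and every loaded lemma distributes unit
mass over its domains.

**Report scores.** A report's continuous score for a domain is the sum of
its tokens' weights divided by its total token count; out-of-vocabulary
tokens add nothing to the numerator but count in the denominator, and
repeated lemmas count once per occurrence.

**Dual-null calibration.** Binarization thresholds are calibrated per
domain on two synthetic corpora sized exactly like the real one (same
report count and per-report lengths): *domain-specific* nulls plant one
single-domain lemma per report (rest padded with non-loading fillers) and
estimate sensitivity; *shared* nulls contain only lemmas loading on two or
more domains, sampled to match corpus occurrence frequencies, and estimate
specificity.  The threshold grid covers midpoints between all distinct
pooled null scores; the chosen threshold minimizes |sensitivity −
specificity| (ties resolved toward higher balanced accuracy, then lower
threshold), and a domain is retained only when its balanced accuracy
exceeds 0.80.  Retention generalizes: tests verify balanced accuracy ≥
0.80 on freshly regenerated held-out null sets.

A structural point the synthetic design must respect: a domain-specific
null report scores `1/L` on its target domain (`L` = tokens per report),
while an all-shared null report scores about `1/K` per domain (`K` =
domain count), because each shared lemma splits unit row mass across its
domains.  Calibration can therefore only separate the two null
distributions when `K > L` — the regime of real corpora, where the domain
count is of the order of the (content-word) report length.  The default
synthetic scenario respects this with 16 domains and 8 tokens per report.

## Semantic dimensions

Per-report dimension values are the median across raters (midpoint for an
even rater count; a missing single rater leaves the median of the rest).
Rater agreement is pairwise Spearman correlation (average ranks for ties)
over shared reports; a constant rater yields a missing correlation.

## Mixed-effects inference

**Models.** Every outcome is modelled with a per-participant random
intercept.  Dimension outcomes (1–9 scale) use a gaussian linear mixed
model fitted by maximum likelihood (statsmodels `MixedLM`).  Binary domain
outcomes use a random-intercept logistic model whose marginal likelihood
integrates the intercept by Gauss–Hermite quadrature (25 nodes), maximized
by BFGS with the analytic score; this engine reproduces `lme4::glmer`
(nAGQ = 25) estimates to ~1e-4 on test fixtures.  The vigilance state is
coded 0 = wake, 1 = dream.  Reported per-model statistics: coefficient
estimates with Wald 95% CIs and normal-theory p-values; a full-model
likelihood-ratio p against the intercept-only model (same random
structure); and an adjusted R² defined as the squared correlation between
conditional fitted values (including predicted random intercepts) and
observations, adjusted for the number of fixed effects — mixed-model R²
has no unique definition, so this choice is stated prominently.

**Permutation test.** The state coefficient's null distribution comes from
shuffling dream/wake labels *within* each participant (each participant
keeps their exact state counts; participants with one report are kept and
contribute no variability).  Gaussian refits in the permutation loop run
through a dedicated profiled-likelihood engine — the deviance is profiled
down to a one-dimensional search over the variance ratio, with GLS fixed
effects in closed form — which matches `MixedLM` ML estimates to ~1e-6 but
is fast enough for 5000 refits per outcome.  Binomial refits reuse the
quadrature engine (15 nodes, warm-started at the observed fit).

**GPD tail p-values.** The two-sided permutation p-value is
`(1 + #{|null| ≥ |obs|}) / (n + 1)`.  When fewer than 10 null values reach
the observed statistic, a generalized Pareto distribution is fitted to the
top 250 absolute null values (threshold midway between tail and bulk) and
the tail probability extrapolated, giving resolution below `1/n_perm`; a
failed or degenerate fit falls back to the empirical value with a warning.
Under a global null the combined procedure is calibrated: p-values pass a
KS uniformity check over 200 simulated datasets (12 participants × 8
reports, 500 permutations each — desk-scale sizes chosen to keep the whole
check to a few minutes while leaving the permutation resolution of 1/501
well below the 0.05 operating point).

**Multiplicity.** Benjamini–Hochberg FDR at q < 0.05, with families
following the study design: across outcomes for the state (or experiment)
coefficient; within each model for the trait-interaction and
sleep-pattern suites; separately for the time-by-state interaction and the
time main effect.

**Effect sizes and displays.** Cohen's d is the pooled-sd standardized
dream-minus-wake difference of covariate-adjusted values (dream minus
wake).  Adjusted values subtract the mean-centered contribution of the
nuisance covariates (centering makes them invariant to constant covariate
shifts); for binomial outcomes the response-scale residual is added back
to the reduced-model fitted probability.  A coefficient-based d is easy to
derive from the reported β and residual sd if preferred; the
adjusted-values variant is the default.  Actigraphic indices are reduced
by correlation-matrix PCA (z-scored columns — the indices have
heterogeneous units; constant columns dropped), keeping 4 components by
default.  Time trends for display use the lowest polynomial degree (≤ 3)
within 2 AIC units of the best fit; these never feed inference.

## Synthetic data generator

The generator emulates the study's structure, not its surface: reports are
bags of lemma tokens, not sentences, and no Italian morphology or
word-frequency profile is modelled.  What it plants, and what passing
tests therefore demonstrate recovery of:

* **Embedding geometry** — unit lemma vectors around domain centroids with
  exact expected within-domain cosine (`within_sim`), between-macro cosine
  (`between_sim`) and within-macro cosine (`macro_sim`), built from an
  orthonormal frame (requires `dim ≥ 1 + n_macro + n_domains`); shared
  lemmas sit midway between two random centroids.
* **Corpus** — per-participant random domain-mixture intercepts
  (log-odds sd `participant_sd` = 0.5), a dream-state log-odds boost
  (`state_domain_shift` = 1.0) on three designated dream-enriched domains,
  an optional monotone time drift, and a shared-lemma token rate of 0.15.
* **Rater scores** — latent per-report dimension values (base 5, planted
  state effects: bizarreness +2, visual +1.2, space +1, thought −1.5,
  agentivity −1.2 Likert points, participant sd 0.7) observed by three
  raters with independent N(0, 1) noise, rounded and clipped to 1..9.
* **Traits and actigraphy** — multivariate-normal traits with a requested
  correlation; 24 actigraphic indices from a 4-factor block-loading model
  plus N(0, 0.3) noise.

The default scenario (40 participants × 8 dream + 8 wake reports of 8
tokens; 16 domains × 24 lemmas + 24 shared lemmas in 3 macro-clusters,
dim 64) runs the full pipeline in about a minute on one core.  Every
generator call consumes a single seeded `numpy` generator and serializes
its parameters and seed as a `GroundTruth` record, so any dataset is
exactly reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: lexical frequency skew (real lemma
distributions are Zipfian; generated mixtures are near-uniform within
domains), report-length variability, polysemy beyond two-way shared
lemmas, rater biases that correlate across reports, missing trait values,
and any dependence between report content and the trait table.

## Numerical choices and degenerate inputs

* Knee point requires ≥ 3 values, not all equal; per-domain curves failing
  this are kept un-sparsified with a warning.
* Jaccard overlap of two all-zero binary columns is defined as 0 (with a
  warning) to avoid 0/0.
* Date ties in time ranks receive the average rank before normalization to
  [0, 1]; at least two distinct dates are required.
* Verbosity is the natural logarithm of the mean of the two
  picture-description word counts.
* Wakefulness downsampling processes each participant's dreams
  chronologically, matching each to the nearest earlier day holding an
  unassigned wake report (any gap allowed); unmatched dreams draw
  substitutes uniformly from the remaining unassigned wake reports.  Each
  wake report is assignable at most once.
* The gaussian engine checks the σ²ᵤ = 0 boundary explicitly and returns
  the pure fixed-effects solution when it fits better.
* Logistic fits with any |β| > 15 are flagged as possible separation and
  marked non-converged.

## Known limitations

* The logistic permutation loop is ~50× slower than the gaussian one;
  at the paper-scale 5000 permutations × 30+ domain outcomes a full
  binomial permutation suite is an overnight job, not a desk job.
* Adjusted R² for mixed models is a convention, not a canonical quantity;
  comparisons across software should use the definition stated above.
* The GPD tail fit uses a fixed 250-value tail without a goodness-of-fit
  gate; extremely heavy-tailed nulls could in principle bias the
  extrapolation, though the empirical fallback bounds the damage.
* Macro-category recovery degrades when within-macro and between-macro
  centroid similarities are close; the silhouette criterion then selects
  unstable cluster counts (flagged, not silently accepted).
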