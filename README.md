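# oneirolex

Quantitative semantic analysis of verbal reports of dreams and waking
experiences, for sleep and consciousness researchers who collect
dream-diary corpora and want reproducible, scalable content measures
instead of manual coding.

The package implements two complementary tracks over a corpus of
pre-lemmatized reports:

* **Data-driven lexical domains.** The lemma–lemma cosine similarity
  matrix `S` (negatives clipped to 0) is decomposed by non-negative matrix
  factorization, `S ≈ W·H`, with the rank chosen by masked
  cross-validation: 10% of cells are hidden, the fit treats them as
  missing, and held-out reconstruction RMSE selects the component count.
  Each component — a lexical domain — is summarized by the mean embedding
  of its top-20 lemmas; domains cluster into macro-categories via
  classical MDS + k-means with silhouette selection.  Lemma-to-domain
  cosines are sparsified at a per-domain knee point and normalized twice
  (within domain, then within lemma), so a lemma belonging to exactly one
  domain gets weight 1.  Reports are scored by length-normalized weight
  sums and binarized at per-domain thresholds calibrated on two null
  corpora (domain-specific vs shared lemmas) at the sensitivity =
  specificity crossing, retaining a domain only if its balanced accuracy
  exceeds 80%.
* **Hypothesis-driven semantic dimensions.** Sixteen report-level
  properties (bizarreness, valence, arousal, agentivity, ...) rated 1–9 by
  multiple raters are aggregated by the per-report median.

Both feed a mixed-effects inference layer: for outcome *y* (a dimension
score, gaussian; or a binary domain indicator, logistic),

    y ~ 1 + vigilance_state + sex + age + education + BADA + (1 | participant)

with the state coefficient tested by within-participant permutation
(dream/wake labels shuffled inside each participant, preserving the
repeated-measures structure), generalized-Pareto tail refinement of
extreme p-values, Benjamini–Hochberg FDR, and Cohen's d on
covariate-adjusted values.  The full suite covers pairwise
dimension/domain association models, trait-by-state interaction models,
actigraphy-PCA sleep models, a lockdown-cohort contrast and
normalized-time trend models.

A first-class synthetic-data module generates every input with planted
ground truth (domain structure in the embedding space, participant random
effects, state/trait/time effects, rater noise), so the entire pipeline is
testable end to end without any external download.

## Worked example

Generate the default synthetic study (40 participants, 8 dream + 8 wake
reports each, with planted dream effects on bizarreness and thought), then
fit the dream-versus-wake dimension models with 1000 permutations:

```python
import pandas as pd
from oneirolex import synthetic_data as sd, dimensions as dm, inference as inf

data = sd.default_scenario(seed=7)
table = (data["reports"]
         .merge(data["traits"], on="participant_id")
         .merge(dm.aggregate_rater_scores(data["rater_scores"]).reset_index(),
                on="report_id"))
table["state"] = (table["vigilance_state"] == "dream").astype(int)

res = inf.run_model_suite(4, table,
                          dimension_cols=["bizarreness", "thought", "incorporation"],
                          n_perm=1000, seed=1)
cols = ["outcome", "estimate", "ci_low", "ci_high", "cohens_d", "p_perm", "q_value"]
print(res[cols].round(3).to_string(index=False))
```

```
      outcome  estimate  ci_low  ci_high  cohens_d  p_perm  q_value
  bizarreness     1.997   1.885    2.108     2.085   0.001    0.001
      thought    -1.431  -1.544   -1.318    -1.503   0.001    0.001
incorporation    -0.072  -0.184    0.041    -0.077   0.222    0.222
```

The generator planted a +2 Likert-point dream effect on bizarreness and
−1.5 on thought, and no effect on incorporation: the state coefficients
recover both planted effects (estimates 2.00 and −1.43, permutation
q < 0.05), while the null dimension is correctly non-significant.
`cohens_d` is the standardized dream-minus-wake difference of
covariate-adjusted scores; `p_perm` is the within-participant permutation
p-value with GPD tail refinement.

The same pipeline is available from the shell:

```sh
oneirolex simulate --seed 7 --out study/
oneirolex discover --embeddings study/embeddings.txt --out model/ --rank-max 24 --reps 8 --seed 1
oneirolex score --model model/ --embeddings study/embeddings.txt \
    --reports study/reports.jsonl --out scores/ --seed 3
oneirolex dimensions --raters study/rater_scores.csv --out dimensions.csv
```

`discover` prints the cross-validated component count and macro-category
count (`selected rank 17; 17 domains, 3 macro-categories` on the default
scenario); `score` prints the calibration outcome (`retained 14/17
domains (balanced-accuracy floor 80%)`).

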