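# foodlex

Food-environment studies that mine location-based social media (restaurant
reviews, geotagged posts) need a dictionary of food words, each tagged by how
calorie-dense the food is. Hand-curated dictionaries are small and miss dish
names, ingredients and multicultural food terms. `foodlex` implements a
pipeline that grows such a dictionary automatically and labels every new term:

1. **Seed lexicon** — food terms with energy density ED (kcal/g) are read from
   food-composition tables, normalized, merged, and classified by the British
   Nutrition Foundation scheme (very low < 0.6; low 0.6–1.5; medium 1.5–4;
   high > 4 kcal/g), collapsed to a binary label at 1.5 kcal/g:
   L-ED (ED < 1.5) vs H-ED (ED ≥ 1.5).
2. **Clustering** — the seeds' word-embedding vectors x ∈ ℝᵈ are modelled as a
   Gaussian mixture p(x) = Σₖ πₖ N(x; μₖ, Σₖ). The component count K and the
   covariance family (full / tied / diag / spherical) are selected by minimum
   AIC = 2·(#params) − 2·log L over a grid.
3. **Expansion** — for each centroid μₖ, vocabulary words with cosine
   similarity ≥ s are tested for membership in the component's hyperellipse at
   probability level p, either as posterior responsibility γₖ(x) ≥ p or as
   Mahalanobis²(x, μₖ, Σₖ) ≤ χ²ᵈ(p). Words inside at least one component, and
   not already seeds, are the newly discovered food words. Raising s or p
   yields fewer but cleaner words.
4. **Energy-density prediction** — ten classifier families (ANN, SVM, GP,
   AdaBoost, Naïve Bayes, QDA, Gradient Boosting, KNN, Random Forest,
   Decision Tree) are benchmarked with stratified fivefold cross-validation on
   the seeds' vectors; the top five are grid-search tuned and the winner
   labels the harvest (serialized 1 = L-ED, 2 = H-ED).
5. **Corpus analysis** — both dictionaries are matched against review text
   (greedy longest-first matching of 1–4-word terms) and compared per district
   by the percent-increase statistic 100·(E − O)/(O + E) and Welch's
   unequal-variance t-test on per-outlet counts.

A synthetic-data module generates embedding spaces with planted food clusters
and background vocabulary, class-consistent seed lexicons, and review corpora
with known planted counts, so the full pipeline is testable offline with exact
ground truth.

## Worked example

```python
import numpy as np
import foodlex as fl

# a planted world standing in for a pretrained embedding + seed databases
spec = fl.SyntheticSpec(seed=42)
space, cluster_truth, ed_truth = fl.generate_embedding_space(spec)
seeds, held_out = fl.generate_seed_lexicon(cluster_truth, ed_truth,
                                           fraction=0.5, seed=42)

# mixture calibration by AIC on the seed vectors
words, X = space.subset(sorted(seeds.surfaces))
best, table = fl.calibrate(X, range(8, 13), ("full", "diag"), seed=42)

# harvest new words at similarity 0.65, probability 0.75
res = fl.expand(seeds, space, best, fl.ExpansionConfig(0.65, 0.75, "posterior"))

# label the harvest with an SVM trained on the seeds
svm = fl.fit_final_model(X, [seeds[w].ed_class for w in words], "SVM", seed=42)
labels = fl.predict_ed(svm, res.words, space)
```

Output of the full script:

```
embedding space: 800 words, d=25
seed lexicon: 200 terms; held-out food words: 200
selected K=12 (full), AIC=1725.1
discovered 201 new words; precision=0.995, recall=1.000
H-ED share of harvest: 50.2%
```

The space holds 10 planted food clusters (400 words) plus 400 background
words; half of each cluster becomes seeds. The AIC winner slightly over-splits
(K=12 on 200 points in 25 dimensions), yet the harvest at (s=0.65, p=0.75)
recovers essentially all 200 held-out food words while admitting a single
background word — the precision/recall trade-off the similarity and
probability levels control. The H-ED share reflects the generator's
alternating per-cluster class assignment.

The same pipeline is available from the shell: `foodlex simulate`,
`build-seeds`, `fit-gmm`, `expand`, `sweep`, `train-ed`, `predict-ed`,
`analyze-reviews` (see `foodlex --help`).

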