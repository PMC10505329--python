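# Methods

## Model and pipeline

`foodlex` treats food vocabulary discovery as density-level-set harvesting in
a word-embedding space. Food words used in similar contexts lie close
together; the seed words (food terms with known energy density) are assumed to
follow a finite Gaussian mixture

p(x) = Σₖ πₖ N(x; μₖ, Σₖ),  x ∈ ℝᵈ,

one component per latent food group. New food words are vocabulary items that
fall inside a component's high-probability region while also being
cosine-similar to its centroid. The energy-density label of a word is then
predicted from its vector alone, on the premise that L-ED words (produce,
plain staples) and H-ED words (fried dishes, sweets, processed foods) occupy
different regions of the space.

### Energy density classification

Energy density ED is kilocalories per gram of the food. The four-level scheme
(very low < 0.6, low 0.6–1.5, medium 1.5–4, high > 4 kcal/g, with 4.0
inclusive in "medium") is collapsed at 1.5 kcal/g into the binary L-ED/H-ED
target. The boundary conventions matter at the edges and are pinned by tests:
0.6 → low, 1.5 → medium/H-ED, 4.0 → medium, anything above → high.

Composition-table energies are accepted as kcal/100 g (divided by 100),
kcal/g, or kJ/100 g (1 kcal = 4.184 kJ). Synonymous rows that normalize to
the same surface are merged by the arithmetic mean ED, and the class labels
are derived from the mean, not from any single row.

### Membership at a probability level

"Inside the hyperellipse at probability level p" has two defensible readings,
and they select different word sets, so both are first-class and the caller
must choose:

* **posterior** — component k accepts x iff the responsibility
  γₖ(x) = πₖN(x; μₖ, Σₖ)/p(x) is ≥ p. This is how mixture libraries expose
  per-sample probabilities. Because responsibilities are relative, a point far
  from every component can still be accepted by its nearest one; the cosine
  similarity pre-filter is what keeps such points out of the harvest.
* **quantile** — component k accepts x iff
  (x − μₖ)ᵀ Σₖ⁻¹ (x − μₖ) ≤ χ²ᵈ(p), the ellipsoid containing p of the
  component's own mass. This is absolute but, in high d, strict: a component's
  own draws are accepted at rate exactly p.

The default in the expansion configuration is `posterior`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| similarity level s | 0.65 | cosine threshold around each centroid; higher → fewer, cleaner candidates |
| probability level p | 0.75 | membership threshold (either mode), in (0,1) |
| membership mode | posterior | see above |
| candidate cap | 100 000 | per-centroid retrieval cap before membership testing; a cost guard, configurable, full scan available |
| K grid / covariance families | 1–101 step 5 → refine | AIC model-selection grid; two-stage coarse→fine search is two `calibrate` calls |
| reg_covar | 1e−6 | diagonal jitter on covariances; indispensable for full-covariance fits in high d on few points |
| EM | k-means init, ≤ 100 iters, tol 1e−3 | standard mixture defaults; non-convergence is flagged, not fatal |
| CV | stratified 5-fold, shuffled, fixed seed | identical fold splits for all ten model families |
| scaling | off | the benchmark compares library defaults; a `scale` flag inserts standardization for the scale-sensitive families |

The (s, p) defaults correspond to the harvest setting that balances yield
against purity in the reference workflow; the sweep utility tabulates the
trade-off for any grid.

Tuning grids (the benchmark defines none canonically): SVM C ∈ {0.1,1,10,100}
× RBF width ∈ {auto, 1e−3, 1e−2}; KNN k ∈ {3,5,11,21}; RF trees ∈
{100,300,600} × depth ∈ {∞,10,20}; ANN hidden ∈ {(50),(100),(100,50)} × L2 ∈
{1e−4,1e−3}; GP RBF length-scale ∈ {0.5,1,2} with the internal kernel
optimizer disabled so the grid is what is compared. Tuned scores are the best
cross-validated mean over the grid on the same folds as the untuned run; the
final model is the tuned-accuracy winner, ties broken by lower fold standard
deviation.

Class imbalance is left unweighted by default (harvests are typically
H-ED-heavy); a class-weight flag is available on the final fit via
`set_params`.

## Percent increase and t-tests

The district comparison uses 100·(E − O)/(O + E) — the difference over the
combined total — as the primary percent-increase statistic, because that is
the form under which the reference per-district and per-term-length figures
reproduce from their printed count pairs. The conventional 100·(E − O)/O is
reported alongside under a separate name. Significance uses Welch's
unequal-variance two-sample t-test on per-outlet counts with
Welch–Satterthwaite fractional degrees of freedom (the fractional df values
in the reference tables identify the unequal-variance form). Occurrences
(tokens), not distinct types, are counted.

Matching is greedy longest-first, left-to-right and non-overlapping, so
sub-terms of a matched dish name ("fries" inside "sweet potato fries") are
not double-counted; an overlapping mode exists for sensitivity analysis.

## Synthetic data: what it emulates, what it does not

The generator plants K isotropic Gaussian clusters (σ = 1) with centers on a
shell of radius 10σ, rejection-sampled to pairwise separation ≥ 8σ, and
background words at radii 30σ–45σ in random directions; d = 25 by default so
full-covariance mixtures stay cheap. Cluster membership and per-cluster ED
class (alternating H/L by default, keeping the binary benchmark balanced) are
returned as ground truth. Seed ED values are drawn from class-consistent
ranges (L-ED 0.05–1.45, H-ED 1.55–6.0 kcal/g), so derived labels always equal
planted labels. Word strings are opaque lowercase-letter identifiers, so no
string feature can leak labels, and every identifier passes the expansion
module's clean-word filter.

Review corpora plant Poisson-distributed term occurrences separated by filler
words; filler sharing any token with a lexicon surface is discarded, which
makes greedy matching recover the planted counts *exactly* — the corpus tests
are bookkeeping identities, not statistical checks.

This geometry preserves what the pipeline exploits (cluster structure,
cosine separability of background, class-by-region structure) but not the
features of real embeddings: anisotropic and overlapping clusters, polysemy,
Zipfian frequencies, or genuine lexical semantics. Passing tests therefore
demonstrate correctness of the machinery and its behavior in the separable
regime, not performance on a real pretrained space.

## Numerical choices

* Raw vectors feed the mixture and classifiers; a unit-normalized copy is
  used for cosine search (cosine is norm-free; no normalization step is
  assumed elsewhere).
* Neighbor search is a full matrix scan, never approximate, so brute-force
  oracle equivalence is exact; ties in similarity order lexicographically.
* Mahalanobis distances use the fitted precision Cholesky factors.
* AIC uses the analytic parameter count (K−1) + K·d + covariance terms
  (full K·d(d+1)/2, tied d(d+1)/2, diag K·d, spherical K), cross-checked
  against the fitting library's internal count.
* Lexicon TSVs write floats at 17 significant digits so rebuild-from-output
  is bit-idempotent.
* Identical constant samples in the Welch test return t = 0, p = 1 rather
  than erroring; zero variance with differing means is an error.

## Problem sizes in the test and acceptance runs

Component-count recovery runs at n = 1000, d = 25 over K ∈ 1..10 × four
covariance families; the expansion world is 800 words (10 clusters × 40 + 400
background), d = 25; the classifier benchmark is n = 2000, d = 25, ten
clusters in two class super-groups. These sizes exercise every code path at
desk scale — full-covariance fits at the embedding dimension of pretrained
news models (d = 300) are supported but much slower, which is why the default
synthetic dimension is 25.

## Known limitations

* The expansion cannot reproduce any specific published word list: that
  requires the original pretrained embedding and seed databases, which are
  not redistributable.
* Posterior-mode membership depends on the cosine pre-filter to reject
  far-away points (responsibilities always sum to 1 somewhere).
* In quantile mode the per-component acceptance rate of genuine members is
  ≈ p by construction, so recall at p = 0.75 is bounded near 0.75 unless
  components overlap; posterior mode does not have this ceiling.
* The AIC winner on small high-dimensional samples tends to over-split
  (select K above the planted count) when the per-cluster sample is thin
  relative to d; harvesting is robust to this because extra components still
  cover the food region.
* Greedy longest-first matching is deliberate vocabulary-side bias: a
  dictionary containing a longer phrase suppresses counts of its sub-terms.
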