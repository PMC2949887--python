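# Methods

## Model and estimation

The classifier is a two-class nearest-centroid rule. On a training sample
with n_k specimens in class k, each gene j gets a per-class mean c_jk and
sample variance v_jk (denominator n_k − 1), plus the pooled variance
v_jP = {(n0−1)v_j0 + (n1−1)v_j1}/(n0+n1−2). The distance from a specimen to
centroid k over gene set G is the square root of the sum of squared
deviations, each standardized by v_jP (distance measure D = 1) or v_jk
(D = 2). Standardization makes the rule invariant to per-gene rescaling, so
highly expressed genes carry no extra weight.

Two score formulas, both oriented class-1-high:

* **Ripples (S = 1)** — the difference of squared distances. With D = 1 it
  is algebraically identical to the diagonal linear discriminant (the unit
  tests verify this to 1e−10 against an independently expanded linear
  form); with D = 2 it matches the diagonal quadratic discriminant up to
  the omitted log-variance terms, and its boundaries are lines and conics.
* **Swirls (S = 2)** — the fraction d0/(d0 + d1) in [0, 1]. Its level sets
  are closed curves around a centroid. When the two classes have unequal
  variances but a pooled variance is specified, Swirls can separate the
  classes where Ripples cannot: a tight class sitting inside a diffuse one
  is enclosed by a Swirls contour.

The square root in the distance matters only for Swirls; Ripples depends on
squared distances alone. A specimen equidistant from both centroids scores
0 (Ripples) or 0.5 (Swirls); those values are also the default cutpoints
for a hard classification (score ≥ cutpoint → class 1). A specimen lying on
both centroids simultaneously is class-indifferent and scores 0.5 under
Swirls by convention. Genes with non-positive required variance cannot be
standardized: they are silently excluded from *selection* candidacy, but a
user-supplied gene set containing one raises an error rather than patching
the variance with an epsilon.

## Binormal AUC

Selection ranks candidates by the area under the ROC curve of the score,
computed under a normality assumption from per-class score means m_k and
variances w_k: AUC = Φ((m1 − m0)/√(w0 + w1)). This closed form is evaluated
thousands of times inside the search loops, which is why the rank-based
(Wilcoxon) AUC is not used there; the two agree within 0.02 for normal-ish
scores at n ≥ 200 per class (tested). When w0 + w1 = 0 the limit value is
used: 0.5 for equal means, else 0 or 1 by the sign of m1 − m0.

## Selection procedure

Per (S, D) combination:

1. **Prefilter** — rank all eligible genes by single-gene binormal AUC,
   keep the top `n_prefilter` (default 50); ties break toward the lower
   gene index. The prefilter is recomputed per (S, D) because a gene's
   single-gene AUC depends on both.
2. **Greedy** (default) — start from the best single gene (accepted
   unconditionally), then repeatedly add the candidate maximizing the
   multi-gene score AUC, accepting only gains ≥ `greedy_delta` (0.02).
   Centroids and AUC both use the full training sample.
3. **Wrapper** — five stratified 50/50 splits of the training sample; per
   split, the greedy search runs with centroids from the train-train half
   and AUC measured on train-test scores, threshold `wrapper_delta` (0.01
   — the honest held-out evaluation tolerates a smaller gain). The gene
   set of the split with the highest inner-test AUC wins (ties → earliest
   split). The final rule recomputes centroids and its reported AUC on the
   full training sample, maximizing data use; the prefilter list from the
   full training sample is reused inside the splits.

Then D = 1 is kept per score formula unless D = 2 improves the AUC by
`d_delta` (0.02), and the score formula with the highest AUC wins, ties
toward Ripples (the simpler boundary). The thresholds are deliberately not
tuned — optimizing them would consume the test sample for selection.

All tie-breaks are deterministic (lower gene index, earlier split), and all
randomness flows through a single generator, so a seed fixes the entire
selection trace bit-for-bit. The five wrapper splits are drawn
independently for each (S, D) combination from that stream.

## Evaluation

The empirical ROC places cutpoints at the deciles (10%–90%) of the pooled
test-score distribution plus ±∞ sentinels. Class 0 is the "positive" class:
TPR_u is the fraction of class-0 specimens with score < u, FPR_u the same
fraction in class 1. This orientation is unusual and is carried through
consistently: the prevalence π in the relative-utility formulas refers to
class 0.

The bootstrap band resamples scores with replacement *within* each class
(class sizes preserved; a resample can therefore never lose a class),
recomputes the decile ROC, and linearly interpolates TPR at
FPR = 0.1, …, 0.9, anchored at (0,0) and (1,1); flat segments keep the
maximal TPR at a duplicated FPR. The band is the per-grid mean ± one SD
(population SD, so a single iteration yields a zero-width band), clipped to
[0, 1]. The default of 20 iterations matches the intended routine use;
tests verify that at large B the mean band converges to the original
sample's curve.

The relative-utility curve starts from the upper concave hull of the mean
ROC (monotone-chain construction; collinear points dropped, so hull slopes
strictly decrease; idempotent; verified against a brute-force chord oracle
on small configurations). Each hull segment of finite positive slope s maps
to the risk threshold R = sπ/(sπ + 1 − π), and the relative utility there
is evaluated at the segment's vertex:

* RU = TPR − ((1−π)/π)·(R/(1−R))·FPR for R ≥ π (comparison vs treat-none);
* RU = (1−FPR) − (π/(1−π))·((1−R)/R)·(1−TPR) for R < π (vs treat-all).

The two branches agree at R = π (both reduce to TPR − FPR). A hull with
fewer than two vertices strictly between (0,0) and (1,1) carries too little
information; the curve is then refused, and the workflows degrade to a
warning and omit the RU output. π defaults to the test-sample class-0
proportion and can be overridden with a target-population value.

## Synthetic design

The default generator draws 2002 genes with independent normal
distributions: 2000 noise genes ~ N(0, 5²) in both classes and two
informative genes ~ N(0, 5²) in class 0 and N(2, 1) in class 1, occupying
the last two row indices. The informative genes therefore carry two signals
at once — a mean shift of 2 and a 5:1 SD ratio — which is exactly the
regime where Swirls with a pooled variance beats Ripples, and where the
class-specific distance sees a much stronger single-gene signal than the
pooled one. Real expression data differ in ways the generator deliberately
ignores: genes are correlated, distributions are heavy-tailed and often
log-scaled, and informative genes are rarely this cleanly separated, so
passing simulation tests demonstrate correctness of the machinery and
qualitative behavior, not field performance.

Workflows: Goal 1 makes one stratified 70/30 training/test split, selects
the rule on the training sample, and reports the bootstrap ROC band and RU
curve on the test sample. Goal 2 repeats the stratified split (default 100
times, each from an independent substream of the master seed), reselects
the rule per split, and tabulates each gene's selection frequency; the
per-split test ROC curves are retained. Splits are stratified by class so
small classes cannot vanish from either side.

Note on interpreting Goal-2 frequencies: they are conditional on the single
dataset realization. A noise gene whose realized class difference happens
to be large in that dataset will legitimately recur across resplits; a null
calibration (no gene dominates) therefore requires fresh realizations per
replicate, which is how the test suite phrases it.

## Problem sizes and numerical choices

The repeated-split study in `scripts/acceptance.py` runs at the design's
full scale (2002 genes, 100 splits per cell, both algorithms, both sample
sizes); the vectorized incremental search (per-gene score terms are
precomputed once per candidate set, so each greedy step is a rank-1 update)
completes all four cells in well under a minute on one CPU. Unit tests use
smaller instances where the property under test permits it. Float
comparisons in the greedy tie-break use exact equality, which is
well-defined because both paths compute identical expressions.

## Known limitations

* Two classes only; no shrunken-centroid variant (it blurs the class
  centroids) and no network-based gene selection.
* The binormal AUC can misrank heavily non-normal score distributions;
  Swirls scores are bounded and can be skewed, though in practice the
  ranking agrees closely with the rank-based AUC.
* The wrapper requires at least 4 specimens per class in the training
  sample (each inner half needs 2 for a variance).
* No confidence band for the RU curve; it is a point estimate from the
  mean ROC.
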