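# Methods

## Problem setting

Supervised interactive network inference: given a reference set of node
pairs known to interact (+1) or not (−1), train a classifier that predicts
the label of new candidate pairs. Evidence about individual nodes
(genes/proteins) arrives as *node kernels* — symmetric PSD similarity
matrices from heterogeneous sources such as sequence kernels or diffusion
kernels over assay networks. The package combines five ingredients:
pairwise kernels, multiple kernel learning (MKL), sigmoid calibration,
cautious classification, and sequential data cleaning.

## Pairwise kernels

A node kernel K is lifted to a kernel on unordered node pairs in five
ways (a, b and c, d denote the nodes of the two pairs):

| kind | definition | implicit feature map |
|------|------------|----------------------|
| P1 (TPPK) | K(a,c)K(b,d) + K(a,d)K(b,c) | symmetrized tensor product |
| P2 (direct sum) | K(a,c) + K(a,d) + K(b,c) + K(b,d) | Φ(a) + Φ(b) |
| P3 (MLPK) | (K(a,c) − K(a,d) − K(b,c) + K(b,d))² | tensor of difference vectors |
| P4 (cosine) | P3 bracket normalized by the difference-vector norms | unit difference vector |
| P5 (CSPK) | indicator-gated sum on node identities | Cartesian graph product |

All five are PSD for PSD K **given a fixed orientation of each pair**: P4
is antisymmetric under swapping the two nodes inside one pair, so pairs
are canonicalized to (smaller index, larger index) at ingest. Self-pairs
are rejected (P4 is undefined on them and link semantics concern distinct
nodes). P4 raises an error when a pair's two nodes are kernel-identical
(zero difference norm) rather than adopting a silent convention. P5's
indicator compares node identities, not kernel rows.

Node kernels are cosine-normalized (K_ij / sqrt(K_ii K_jj)) before pair
construction by default, giving heterogeneous sources a common scale;
normalization happens before pairing, and the flag is recorded in saved
models so prediction is consistent. Gram assembly is blocked (default
1024 rows per block) and results are independent of the block size.

## MKL with an SVM dual

The composite pair kernel is a convex combination of base Grams,
K̄ = Σ_ℓ λ_ℓ K̂_ℓ, with λ on the probability simplex. Weights and SVM dual
coefficients solve

    min_λ max_α  1'α − ½ (αy)' K̄(λ) (αy)
    s.t. Σλ = 1, λ ≥ 0, 0 ≤ α ≤ C, α'y = 0.

The outer minimization is reduced-gradient descent on the simplex with an
exact SVM solve per iterate (SimpleMKL style); inner solves use libsvm
with a precomputed kernel (tolerance 1e−8). The objective J(λ) is convex
(a pointwise max of affine functions of λ), the line search only accepts
decreases, so the outer objective is non-increasing and never exceeds the
uniform-weight objective (uniform weighting is the feasible point
λ = 1/p). Convergence: relative duality gap ≤ 1e−4 (the gap is
½[max_ℓ (αy)'K_ℓ(αy) − Σλ_ℓ (αy)'K_ℓ(αy)]) or λ-step ≤ 1e−6, with at most
200 outer iterations. Weights below 1e−4 are zeroed, λ renormalized, and
the SVM re-solved on the sparsified composite. Indefinite inputs beyond
the tolerance (smallest eigenvalue < −1e−8 × largest) are convexified by
eigenvalue clipping with a warning.

**Bias.** The midpoint rule over bias-free decision values f0:

    b = −½ [ max_{y=−1} f0 + min_{y=+1} f0 ],

with the max/min restricted to points whose α is strictly below the box
bound C. For such points the KKT conditions pin y(f0 + b) ≥ 1 with
equality at support vectors, so the midpoint recovers the exact bias; on
separable data no α reaches the bound and the rule reduces to the plain
midpoint over each class. The restriction matters: margin violators at
α = C satisfy only the reverse inequality, and a single mislabeled
learned point would otherwise drag the bias arbitrarily (observed as
confidently-wrong models during cleaning). A class whose every member is
at the bound falls back to all its members. Free/bound classification
uses α < C(1 − 1e−6).

**Choosing C.** The default box bound is C = 1. Kernel *weights* are
interpreted at a C selected by cross-validated accuracy: with soft-margin
MKL, a high-capacity uninformative kernel (a near-identity Gram) can
attract weight at large C because it lets the dual memorize the training
pairs, and at intermediate C because it mimics extra slack. On the
synthetic benchmark CV selects C ≈ 0.1–0.3; `synthetic.BENCHMARK_C = 0.3`
is used wherever the benchmark generator is used. The CLI accepts a list
of C values and reports the weight table per C.

## Calibration

Margins φ are mapped to link probabilities through
p(y=+1|φ) = 1/(1 + exp(Aφ + B)), fitting (A, B) by minimizing the
cross-entropy with raw targets t = (y+1)/2 ∈ {0, 1}. The optimizer is a
damped (Levenberg-style) Newton iteration on the two-parameter surface:
damping starts at 1e−3, ×10 on a rejected step, ÷10 on an accepted one;
accepted steps never increase the loss; convergence at gradient ∞-norm
≤ 1e−8 or 200 iterations; starting point A=0, B=log(N−/N+). On separated
margins the unpenalized optimum diverges; the fit stops at |A| = 1e3
(configurable) and sets a `capped` flag. Platt's regularized targets
((N++1)/(N++2) and 1/(N−+2)) are available behind a flag, default off.
The CLI calibrates on out-of-fold margins from cross-validation, not
training margins, which are optimistically large.

## Cautious classification

A prediction is retained when its confidence max(p, 1−p) reaches a cutoff
in [0.5, 1]; cutoff 0.5 retains everything and coverage is non-increasing
in the cutoff. Accuracy is reported among retained points only (missing
when nothing is retained). The default curve grid is 0.50–0.99 in steps
of 0.01 plus 0.995 and 0.999. The cutoff is a posterior-confidence
threshold (sometimes loosely called a "p-value cutoff" in applied work);
it is not a significance level. AUC is the rank-based Mann–Whitney
statistic with ties counted ½.

## Sequential cleaning

Both strategies start from centroid seeds: per class, the 10 points
closest to the class centroid in the composite feature space, computed by
the kernel identity d²(x) = K(x,x) − (2/n)Σ_j K(x,x_j) + (1/n²)Σ_{jk}
K(x_j,x_k). Seeding distances use the **cosine-normalized** Gram by
default: under P1 a link pair's self-similarity is 1 + K(a,b)² versus ≈ 1
for a mislabeled nonlink, so raw distances systematically rank mislabeled
pairs as "most central" (on the benchmark, all ten positive seeds were
flips before normalization). Unit-sphere embedding removes that artifact;
the raw identity remains available (`cosine=False`).

*Lowest-confidence ordering*: repeatedly train on the learned set,
compute |φ| for all unlearnt points, learn the argmin (ties toward the
lowest index). The stopping criterion fires the first time every unlearnt
point has |φ| > 1 (margin band empty): beyond it each candidate is either
a would-be non-support vector or a point confidently placed among the
opposite class — a likely mislabel. The run records the stop position and
continues to the end so stop-vs-full comparisons need one pass. Training
is a full exact re-solve per step; results equal a cold re-solve by
construction.

*Random screening*: visit points in seeded random order; predict each
point's label with the current model and calibration; skip (and log) any
point whose confident prediction (≥ 0.95 by default) contradicts its
recorded label. The internal calibration is refit every 25 learned points
on 3-fold cross-validated margins within the learned set, with
regularized targets — training margins made the screen overconfident
(saturated slope), and confidence capped at ~(N+1)/(N+2) prevents the
small early model from confidently discarding correct points.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes while
staying fully self-contained:

* **Network**: planted partition, nodes round-robin over modules, link
  probability p_in within and p_out between modules. Defaults 60 nodes, 6
  modules, p_in = 0.9, p_out = 0.05 — a regime with held-out error around
  0.11–0.14, comparable to real link-prediction data sets of this size.
* **Node kernels**: cosine-normalized linear kernels of features
  s·one_hot(module) + (1−s)·z, z ~ N(0, I/dim), with informativeness s per
  kernel (defaults (0.9, 0.6, 0.0)) and dim = 8. The dimension is kept
  small so the pure-noise kernel is low-rank: real uninformative kernels
  carry structure unrelated to the labels, they are not high-capacity
  memorizers (a dim ≫ 8 noise kernel can linearly separate any labeling of
  a few hundred pairs, which soft-margin MKL rewards).
* **Pairs**: a balanced sample of links and nonlinks (counts within 1),
  without replacement.
* **Label noise**: exactly round(fraction·n) labels inverted uniformly at
  random, indices recorded.
* All randomness derives from one seed through fixed per-subgenerator
  spawn keys, so adding a generator never perturbs the others.

The cleaning benchmark uses a separable variant (p_in = 1, p_out = 0,
informativeness (0.9, 0.6), 400 pairs, 10% flips, C = 1): the method is
positioned as the alternative to a soft margin for data that are clean
apart from mislabels, and that is the regime where its screening claims
are testable.

What the generator does **not** model: real sequence/diffusion kernel
spectra, degree heterogeneity, assay-specific noise, non-uniform
mislabeling. Passing tests demonstrate the machinery behaves as designed
under the planted model, not performance on any real organism's data.

## Known limitations

* **Uniform mislabeling is invisible to label-blind selection.** The
  empty-margin-band stop selects the unlearnt set by |φ(x)|, which does
  not involve the point's own label. When flips are planted uniformly at
  random, the unlearnt-at-stop set therefore contains flips at
  approximately the base rate (measured 0.8–1.4× across wide parameter
  ranges) — not enriched. Enrichment of the unlearnt set requires a
  mislabeling process concentrated on high-margin pairs (e.g., spurious
  links between unrelated proteins), which is plausibly true of real
  curation errors but is not what a uniform flip model produces. The
  label-*aware* selection — unlearnt points whose confident margin
  contradicts their recorded label — is strongly enriched for flips; that
  is precisely what the random screen measures, and its skip precision on
  the benchmark is 0.67–1.0.
* With an intrinsically ambiguous network (p_out > 0), held-out error at
  the stop can exceed the error of the fully trained soft-margin model;
  the stopping rule is designed for the separable-plus-mislabels regime.
* The reduced-gradient MKL solver finds the global optimum of a convex
  problem, but the weight *interpretation* is only meaningful at a
  well-chosen C (see above).
* Calibration quality depends on the margin distribution; on separated
  data the slope is capped and flagged rather than meaningful.

## Problem sizes

Tests and the acceptance script use 200–400 pairs over 60 nodes, 2000–5000
simulated margins for calibration/cautious checks, and 20-point problems
for QP cross-checks; the full suite and the acceptance script each run in
well under a minute of CPU except the cleaning benchmark (a few seconds
per sequential run).
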