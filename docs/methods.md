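# Methods

This note documents the model, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Preprocessing

Features are standardized to zero mean and unit **population** standard
deviation (1/n denominator); the pooled covariance used for Mahalanobis
distances uses the n−1 denominator. The two conventions are deliberately
kept distinct rather than unified. Standardization statistics may be
fitted on the union of training and simulation data (the chronological
convention of normalizing the full record before splitting it) or on the
training block only; the pooled fit is what `split`-based workflows and
the benchmark harness use, and a caller who needs strictly leakage-free
preprocessing passes train-only statistics to `fit`.

## PLS feature reduction

NIPALS extracts score/weight/loading sets one component at a time:
`w ∝ Eᵀu`, `t = Ew`, `q = Fᵀt/tᵀt`, `u = Fq/qᵀq`, iterated to a 1e−10
relative change in `t` (closed-form single pass for univariate Y, where
the alternation is exact), then both blocks are deflated — `E` by `tpᵀ`
and `F` by the regression of `F` on `t`. Extraction stops early when the
X residual reaches 1e−12 of its initial Frobenius norm (rank exhausted),
recording the achieved count. The regression matrix is
`B = W(PᵀW)⁻¹Qᵀ`; transforming new data uses the same rotation
`R = W(PᵀW)⁻¹`, so training scores are reproduced exactly. Y is
standardized like X before fitting and predictions are de-standardized.

The retained count `l` minimizes K-fold PRESS (default K = 10;
contiguous block folds, deterministic and suited to chronologically
ordered data; shuffled folds available behind a seed). Ties break to the
smallest `l`; a first-local-minimum rule is available. With every
component retained on full-rank data, predictions coincide with ordinary
least squares — the test suite asserts this against a normal-equations
oracle and against scikit-learn's PLSRegression.

The PCA baseline keeps the smallest number of correlation-matrix
eigencomponents whose cumulative explained-variance ratio reaches a
threshold (default 0.80).

## Hierarchical subclass partitioning

Distances are Mahalanobis with the pooled covariance of the working
matrix, pseudo-inverted (Moore–Penrose) when singular; a ridge inverse
(V + εI, ε = 1e−8·tr(V)/p) is available and agrees with the
pseudo-inverse on rank-deficient test cases. UPGMA linkage merges the
pair of clusters with the smallest class-average distance — the square
root of the mean squared cross-pair distance — maintained by the
size-weighted Lance–Williams update on squared distances, which is
algebraically identical to recomputing every cross-pair average from
scratch (the suite checks this against a brute-force oracle). Merge ties
break to the smallest cluster-id pair, making trees deterministic.
Heights are non-decreasing (UPGMA is reducible).

The tree is cut either at a height threshold λ or to exactly K clusters
(default K = 3; 3–6 is the recommended range). A minimum-subclass-size
guard (default floor 3) folds any smaller splinter into its nearest
subclass, because a 1–2 sample subclass cannot train a network. Under
the K rule, folding a splinter would leave fewer than K groups, so the
guard re-cuts the tree one level deeper until K adequately-sized
subclasses remain (merging closest centers back down if a deeper cut
overshoots). Under the λ rule the cut height is authoritative and
splinters are simply folded in.

A property worth knowing: because the pooled covariance contains the
between-cluster scatter, Mahalanobis whitening *saturates* the distance
between cluster centers — pushing generating clusters further apart does
not increase their whitened separation, while every pure-noise dimension
in the working space adds to within-cluster distances. Partitioning is
therefore markedly more reliable on the supervised low-dimensional PLS
scores than on the raw standardized features; this is precisely the
argument for combining the two reductions, and the benchmark reproduces
it (raw-feature clustering essentially never recovers the generating
3-blob partition, PLS-score clustering recovers it in ~90% of draws).

## Elman network experts

Architecture: `x(k) = σ(w1 u + w2 x_c + b_h)`, `y = w3 x + b_o`, with the
context ("undertake") layer the same width as the hidden layer and
`x_c(k) = x(k−1)`. Biases are included — the textbook equations omit
them, but a bias-free sigmoid layer cannot shift its activation, so this
is a deliberate, documented deviation. Hidden width comes from the
empirical formula `s = round(√(0.43nm + 0.12m² + 2.54n + 0.77m + 0.35)
+ 0.51)` with `n` equal to the expert's input count (the PLS score count
`l` after reduction — the architecture is re-derived after compression).

Because the classifier applies a recurrent net to *non-sequential*
samples, the default context handling is reset-per-sample with two
forward passes: pass 1 (zero context) seeds `x_c` from the sample
itself, pass 2 produces the output. This exercises the `w2` recurrence
while keeping predictions independent of sample order; carry-over mode
exists for genuinely sequential data. The feedforward baseline is the
same object with `w2` frozen at zero (identical seed → identical
`w1`/`w3`/bias initialization, so the two architectures are directly
comparable).

**Training.** Batch Levenberg–Marquardt on the truncated gradient: the
per-sample context activations are treated as constants while
differentiating (the classical simplification for this architecture,
and what makes batch LM well defined). Each epoch builds the analytic
Jacobian of all residuals w.r.t. all weights and biases (verified
against central finite differences of the same frozen-context model to
< 1e−4 relative error), solves `(JᵀJ + μI)Δ = Jᵀe`, and accepts the step
only if the full-network SSE decreases — so the accepted-step SSE trace
is non-increasing by construction. Damping defaults: μ₀ = 1e−3, ×10 on
reject, ×0.1 on accept, stop at μ > 1e10, goal SSE 1e−3, max 2000
epochs. These are conventional values; none is prescribed by the
method. Weights initialize uniformly in [−0.5, 0.5] from a seed;
training is bit-reproducible given (data, config, seed). Gradient
descent with momentum (`train_gdm`) is provided as the weight-update
fidelity option and baseline trainer. "Training steps" are counted as
accepted epochs, summed over experts for cluster-wise variants.

Class labels are encoded as their integer values on a single linear
output and decoded to the nearest class value, ties to the lower class.
One-hot multi-output training is supported by the network layer but the
pipeline uses the single-output ordinal coding, matching the degree-type
targets of the motivating application.

## Routing

Each simulation sample goes to the subclass with the nearest mean center
in Mahalanobis distance under the pooled training covariance (per-subclass
covariances would be singular for small subclasses); ties to the lowest
subclass id. Routing inherits affine invariance from the metric.

## Alternative stage orderings

Four orderings of reduce/cluster/train are implemented. The shipped
default reduces once globally, clusters only the training samples, and
routes test samples afterwards. The alternatives are retained with their
failure modes surfaced rather than patched: orderings that cluster
training and simulation samples jointly raise an error when a subclass
contains no training members (its expert cannot be trained), and
per-subclass PLS warns when subclasses select different latent
dimensions (their feature spaces are out of step).

## Synthetic data

The generator draws a Gaussian mixture in a low-dimensional latent space
(unit within-cluster SD; centers rejected-sampled to pairwise distance ≥
`separation`), lifts it through a random full-rank loading, and appends
`redundancy` noisy copies of existing columns (N(0, noise_sd²),
default 0.1). Labels come from the generating cluster, a cluster→class
mapping, or a latent linear regression. Presets fix all parameters and
seeds:

| preset | n × p | latent | clusters | sep. | redundant | split |
|---|---|---|---|---|---|---|
| `midge_like` | 60 × 14 | 3 | 3 | 8 | 4 | 45/15 |
| `ionosphere_like` | 351 × 34 | 5 | 3 | 8 | 8 | 300/51 |
| `separable_benchmark` | 150 × 14 | 3 | 3 | 8 | 0 | 100/50 |

`midge_like`/`ionosphere_like` copy the study shapes (sample counts,
feature counts, class structure, chronological splits). Separation 8
makes subclass structure unambiguous at the generating scale — the
benchmark probes algorithmic correctness, not boundary-case power.
`separable_benchmark` is larger (one held-out error costs 2% rather than
6.7%) and omits redundant columns so that *every* variant, including
raw-feature-space cluster routing, can reach its ceiling; the redundancy
pathology is exercised by the other presets and the PLS-specific tests.

What passing these benchmarks does **not** show: real weather or radar
covariates are not Gaussian mixtures with linear liftings; class overlap,
label noise, non-stationarity and non-linear feature interactions are all
absent. On this clean data the single-network baselines also reach
ceiling accuracy, so the benchmark demonstrates the cluster-wise
pipeline's correctness and its training-effort advantage (several small
quickly-converging experts vs one larger fit), not an accuracy gap —
published accuracy gaps on the real datasets reflect difficulty this
generator deliberately does not emulate.

## Degenerate inputs and tie-breaks

Constant feature columns are rejected by name at standardization.
Rank-deficient covariances take the pseudo-inverse path. NIPALS stops at
rank exhaustion and records the achieved component count; a Y block with
no covariance on X yields near-zero coefficients and mean predictions.
UPGMA merge ties take the smallest id pair; equidistant routing and
equidistant class decoding take the lower id/class. Expert seeds derive
deterministically from the pipeline seed and subclass id, so a K = 1
cluster-wise model is bit-identical to the corresponding single-network
variant.

## Problem sizes

Default test and acceptance runs use the preset sizes above, 10 generator
draws per statistic, 100 random instances for the linkage oracle, and
50 instances for the PLS/OLS agreement check — sizes at which every
statistic is stable yet the full suite runs in seconds.
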