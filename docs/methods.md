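# Methods

## Model

The classifier is a broad learning system (BLS): a single hidden layer of
random *feature nodes* (n groups × k nodes, each group its own random
linear map plus activation) and random *enhancement nodes* (m nodes applied
to the concatenated feature block), with only the output weights trained.
Targets are one-hot class indicators; with λ ≥ 0 the ridge solution is
W = (AᵀA + λI)⁻¹AᵀY for the state matrix A = [Zⁿ | Hᵐ]. We solve the
normal equations by Cholesky factorization rather than an explicit
inverse; an exactly singular system (λ = 0 with rank-deficient A) raises an
error advising λ > 0.

Graph regularization adds geometric structure. Both graphs are binary
symmetric kNN graphs built **once per training set in the raw
(standardized) input-feature space** with Euclidean distance — not on the
mapped features — so they are independent of the evolving node parameters
and can be reused across thousands of fitness evaluations. V_ij = 1 iff
the label condition holds (intrinsic: same label; penalty: different
label) and either sample is among the k nearest neighbours of the other.
Self-neighbours are excluded; distance ties break toward the lower sample
index so graphs are deterministic. Laplacians are unnormalized, L = D − V.
The composed regularizer is Bᵀ L_w B with B = (L_p + ζI)^(−1/2) computed by
symmetric eigendecomposition; eigenvalues are clipped below at ζ/10 before
the −1/2 power to guard round-off negativity, and the product is
symmetrized.

A note on the quadratic form: the standard Laplacian identity is
Σ_ij V_ij‖ŷ_i − ŷ_j‖² = **2**·Tr(ŶᵀLŶ). Some presentations of this
regularizer omit the factor 2; since it only rescales λ₁, we use L = D − V
directly and the property tests assert the identity with the factor 2.

### The λ₁ scale

Every penalty Laplacian is singular (constant vector, plus one null
direction per connected component), so B amplifies those directions by
ζ^(−1/2). When the penalty graph is sparse — exactly the well-separated
regime — the composed regularizer approaches L_w/ζ: the graph term is
effectively multiplied by 1/ζ = 10⁵. The default λ₁ = 1e−4 therefore
weights the *raw* intrinsic Laplacian by roughly 10, which is heavy
relative to the ridge term (λ₂ = 0.1) yet leaves the least-squares term in
charge of score calibration. With λ₁ = O(1) the graph term dominates and
drags all raw scores toward class-wise constants below the fixed 0.5
decision threshold, collapsing predictions to the majority class. ζ
defaults to 1e−5; both are configurable.

## Self-adaptive differential evolution

All node parameters are flattened into one vector
(length n·k·(M+1) + m·(n·k+1); flatten/unflatten round-trips bit-exactly)
and evolved. Per individual and generation:

* a mutation strategy is roulette-sampled from the pool
  {DE/rand/1, DE/rand-to-best/2, DE/rand/2, DE/current-to-rand/1};
* CR ~ N(0.5, 0.3) truncated to [0, 1), F ~ N(0.5, 0.1) clipped to (0, 2],
  K ~ U[0, 1] — resampled per individual per generation;
* parent indices r1…r5 are mutually distinct and ≠ i (hence the NP ≥ 6
  floor); mutants are clipped to the search bounds (default [−1, 1], the
  usual random-weight range);
* binomial crossover guarantees at least one mutant component via j_rand;
* the trial replaces the parent if it improves the RMSE by more than the
  relative tolerance ε_sel, or if it is within ε_sel of the parent *and*
  has a smaller ‖W‖_F (a mild generalization bias). Each trial is counted
  exactly once as a success or failure of its strategy.

Strategy probabilities are uniform (1/4) for the first LP generations,
then proportional to s_l = Σns/(Σns + Σnf) + ε over a sliding window of
the last LP generations; ε = 0.01 keeps every probability strictly
positive. Population updates are synchronous: trials are generated against
the current generation, survivors committed at its end, and the best
individual used by DE/rand-to-best/2 is refreshed per generation.

Fitness is the *training* RMSE ‖AW − Y‖_F/√(N·C) of the closed-form
graph-regularized solve — a true root mean square, i.e. a strictly
monotone transform of a plain normalized residual, so selection decisions
are unaffected by the normalization choice. The run stops at G_max
generations or when the best RMSE falls below an optional threshold
(disabled by default). Defaults: NP = 20, LP = 5, G_max = 50,
ε_sel = 1e−3. With ε_sel = 0 the per-individual and best fitness are
provably non-increasing; with ε_sel > 0 a survivor's fitness can rise by
at most the factor (1 + ε_sel) in one generation. The whole run is
bit-reproducible under a fixed seed.

## EEG pipeline

Epochs are 2 s with consecutive windows sharing 0.5 s — i.e. a 1.5-s
stride, the plain reading of "overlap"; partial windows at the recording
end are dropped. An epoch is labelled seizure when at least 50 % of its
span intersects an annotated interval (threshold configurable; an exact
50 % overlap counts as seizure). The 13 per-channel time-domain features
use population (divide-by-n) variance, biased skewness, and biased *excess*
kurtosis; zero-variance channels define skew = kurt = 0; argmin/argmax are
0-based first-occurrence indices; the sum of absolute differences is the
first-difference L1 norm. Features are z-scored with statistics computed
from the training folds only (zero-variance features map to zero), which
is handled inside the classifier's `fit` so cross-validation cannot leak
test-fold statistics.

No filtering or artifact rejection is performed; preprocessing is limited
to channel-count consistency checks and epoching.

I/O: CSV (channel-named header plus a sampling-rate sidecar or flag) and
EDF. EDF reading uses MNE; writing uses a minimal single-record 16-bit EDF
writer, so round trips are exact to each channel's physical-range/65535
resolution.

## Evaluation

Confusion counts treat seizure = 1 as positive. Metrics with a zero
denominator are defined as 0. Cross-validation is stratified by default
(plain k-fold optional): an unstratified split into five equal folds can
produce degenerate training folds on imbalanced seizure data.
Summaries are per fold, mean ± sd, or best single fold (by accuracy, F1
tie-break). Scores are compared to the fixed threshold 0.5 on the
positive-class column; a score exactly at the threshold is called seizure,
favouring sensitivity.

## Synthetic data

`synth_recording` emulates what the pipeline needs from ictal EEG, not its
physiology: background is 1/f-shaped noise (σ_b = 10 µV default) plus a
10-Hz rhythm at 5 µV; seizures superimpose a high-amplitude (σ_s = 60 µV)
~3-Hz sawtooth slow wave with a sharp transient per cycle. This produces
the amplitude/variance/line-length contrast that time-domain features key
on. It does **not** model electrode artifacts, inter-channel coherence,
evolving seizure morphology, or realistic spectra — so passing tests
demonstrate the machinery end to end, not clinical performance.
`synth_feature_clusters` draws two unit-variance Gaussian classes with
per-dimension means ±separation/2 (default separation 6 over 10
dimensions: essentially perfectly separable, the regime where a correct
implementation must score ≈ 1.0).

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
exercise every code path in seconds: solver-vs-minimizer checks on ≥ 20
random instances with N ≤ 50, D ≤ 20; DE dynamics over 50 generations of a
10-individual population on a small cluster instance; end-to-end
cross-validation with NP = 10 and G_max = 15 on 400 samples — enough
evolution to measurably reduce the training RMSE while keeping the whole
pipeline fast. The independent oracle for the closed-form solvers is a
Newton-CG minimizer of the same objective with exact gradient and
Hessian-vector products (quasi-Newton methods stall short of the ≤ 1e−7
agreement bound on graph instances, whose conditioning is dominated by the
1/ζ amplification).

## Known limitations

* Raw linear scores are not probabilities; the fixed 0.5 threshold assumes
  reasonable calibration, which strong graph regularization can break (see
  the λ₁ discussion).
* Graphs are dense N×N constructions — fine for epoch counts in the
  thousands, not for very long recordings without subsampling.
* Node counts (n, k, m) are configuration, not optimized quantities; the
  evolution tunes the parameters *within* a fixed architecture.
* Subject-grouped splitting is exposed (`stratified=False` plus external
  grouping) but not a first-class option; the default stratified split can
  be optimistic when epochs from one recording appear in both training and
  test folds.
* Incremental node addition (the classic BLS update) is out of scope.
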