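# Methods

## Task representation

All models operate on paired comparisons: a row x ∈ {−1, 0, +1}^m codes
which of two alternatives each cue favors, and y ∈ {−1, +1} codes which
alternative has the higher criterion. `make_pairs` enumerates all unordered
object pairs in table order ("left" = earlier row); pairs with tied
criterion values are dropped because the outcome space has no code for
them. Orientation is immaterial: every model and heuristic is antisymmetric
(negating x negates the choice), which the suite checks exhaustively.
Median-split dichotomization of continuous cues is available but off by
default — the models accept signed differences of raw cues directly —
and leaves already-binary {0,1} cues untouched, making it idempotent.
Missing cue values are an error, not imputed.

## Heuristics

Cue validity is the proportion of correct inferences a cue makes among the
comparisons where it discriminates, v_j = #{x_ij·y_i = +1} / #{x_ij ≠ 0}.
A never-discriminating cue gets v_j = 0.5 ("uninformative") and is excluded
from the undirected heuristics. Learned directions are sign(v_j − 0.5),
with the +1 convention at exactly 0.5. TTB searches cues in descending
*oriented* validity max(v_j, 1 − v_j) — the validity of the cue once its
direction has been learned — with ties broken by ascending cue index. The
oriented validity is computed as the single integer ratio
max(a, d−a)/d rather than max(v, 1−v) in floats, so a reversed cue and a
direct cue of equal informativeness tie exactly and the index tie-break is
deterministic; the COR decision rules use the same lowest-index convention,
which is what makes exact limit-equivalence checks meaningful. Guessing is
represented as choice 0 and scored 0.5 by the evaluator rather than
resolved by a coin flip (same expectation, no Monte-Carlo noise).

## Half-ridge model

Likelihood y = Xw + ε with ε ~ N(0, σ²I); prior w ~ N(0, η²I) truncated to
the orthant O fixed by the a-priori cue directions. σ defaults to 1 and is
held there throughout: with y ∈ {−1, +1} the error scale is not separately
identified, and the continuum is indexed by η alone. The untruncated
posterior is N(μ, S) with S = (XᵀX/σ² + I/η²)⁻¹, μ = S·Xᵀy/σ²; truncation
is handled by component-wise Gibbs sampling whose full conditionals are
exact univariate truncated normals. The truncated draws use naive
resampling when the truncation point is below 0.3 standard units and a
translated-exponential rejection step in the tail, so conditionals remain
exact arbitrarily deep into the orthant boundary. Defaults: 5,000 retained
draws after 1,000 burn-in, no thinning, seeded; a split-chain
scale-reduction statistic above 1.05 emits a warning. The chain starts at
the orthant-folded untruncated mean. These defaults were validated against
an independent rejection sampler (draw from N(μ, S), keep draws in O) at
m ≤ 3, where the two estimators agree within combined Monte-Carlo error;
Monte-Carlo standard errors are estimated by batch means. Degenerate
all-zero cue columns are retained — the prior keeps the posterior proper
and the sampled mean reproduces the half-normal prior mean ±η√(2/π).

Decisions are the sign of x·E[w], the mean being sufficient because the
decision statistic is linear. A choice is declared a guess when
|x·mean| ≤ max(10⁻¹², 0.05·‖x‖₂‖mean‖₂). The band is *relative* by design:
it keeps decisions invariant under positive rescaling of the weights, and
it is what lets the strong-prior model reproduce tallying's guesses — at
η = 10⁻³ the sampled mean magnitudes are equal only to ~1% relative error,
so tally-tied inputs produce small but nonzero dot products (relative size
~10⁻², versus ≥ 0.25 for decided inputs at m ≤ 6). The 0.05 threshold sits
between those two scales with a factor ≥ 4 margin on either side. At
intermediate η the band converts near-ties (evidence below 5% of the
weight scale) into guesses, costing at most a sliver of expected accuracy.

`sign_constrained_ls` (nonnegative least squares after flipping columns to
their assumed direction, via scipy's NNLS) serves as the executable η → ∞
oracle; `rescaled_limit_mean` (direction-signed mean of |N(0,1)| draws) as
the η → 0 oracle, converging to ±√(2/π) ≈ ±0.798.

## COR model

Column j of the weight matrix is the mean posterior of a regression with a
flat prior on the direct weight and N(0, η²) priors on the cross-weights
(σ = 1, λ = 1/η²): w⁽ʲ⁾ = (XᵀX + λM_j)⁻¹Xᵀy, where M_j zeroes the (j,j)
entry of the identity. The flat direct prior is the minimal closed form
with all four stated limits: every column equals OLS at λ = 0, and as
λ → ∞ the cross-weights vanish while the diagonal tends to the
simple-regression slopes Σx_ij·y_i / Σx_ij² = 2v_j − 1. Systems are solved
with lstsq for λ > 0, so never-discriminating cues (exactly singular
blocks) get minimum-norm solutions with zero weight; at λ = 0 an
ill-conditioned XᵀX raises, advising a positive penalty. Log-spaced grids
with endpoints 10⁻⁶ and 10⁸ stand in for the 0 and ∞ limits.

Decision rules on the outputs ŷ = xW use two numeric tolerances. Output
components (and argmax ties) within relative 10⁻⁴ of the largest |ŷ_j| are
treated as zero (tied): at λ = 10⁸ the residual cross-weights leak O(n/λ)
into outputs that are exactly zero in the limit, and break exact argmax
ties against the lowest-index convention, while genuine validity gaps on
training sets of n ≤ ~100 comparisons are ≥ 1/n² ≈ 10⁻⁴·scale·(factor 5).
An absolute floor of 10⁻⁵ (between the ~10⁻⁶ leakage and the smallest
validity signal |2v−1| ≥ 1/n) makes a test item that discriminates only on
uninformative cues yield a guess, exactly as the heuristics do.

## Synthetic environments

The generator realizes the assumption that cues differ in predictiveness
but not arbitrarily so, using the half-ridge model's own prior family so
that parameter-recovery and peak-location experiments are well-specified:

* true weights w*_j = d_j·|N(0, τ²)|, τ = `weight_scale` (default 1);
* binary cues by thresholding equicorrelated Gaussians at zero
  (one-factor structure), giving pairwise latent correlation ρ; the
  induced binary correlation is 2·arcsin(ρ)/π (≈ 0.71 at ρ = 0.9);
* criterion = cues·w* + N(0, σ_e²) — Gaussian noise on the latent
  criterion before pairing, matching the linear-model error, not on y.

Everything is drawn from one seeded generator, so identical specs are
bit-identical. What this emulates: controllable weight dispersion, cue
redundancy, and outcome noise. What it does not: the heavy-tailed cue
distributions, varying cue counts, and non-binary cues of real datasets —
so passing tests show the limit algebra and the qualitative
sweep/crossover phenomena, not performance on any particular real-world
collection.

## Evaluation harness

Splits sample comparisons (pair-level), not objects, matching how training
cases are counted in this literature; test pairs may share objects with
training pairs, an acknowledged alternative to object-level splitting.
Accuracy scores 1/0.5/0 for correct/guess/wrong. SEM is sd/√n_reps across
replications. Replication streams are derived from (master seed, rep) with
SeedSequence, and all models inside a sweep or comparison see identical
environments, splits, and sampler seeds — a paired design, so model
contrasts use the SEM of the paired difference. Training draws in which no
cue ever discriminates are resampled with fresh derived seeds and counted.
Default sweep grids have 25 log-spaced points. The OLS comparator is
ridge at θ = 0 (falling back to θ = 10⁻⁸ on singular designs) with
sign-of-prediction decisions and no known directions.

Two frozen study designs are used by the acceptance checks:

* matched sweep environment: m = 6, τ = 1, ρ = 0.3, σ_e = 1, 20 objects
  (190 pairs), train 40, 100 replications;
* crossover environment: m = 6, τ = 1, ρ = 0.5, σ_e = 2, train 20 vs 100,
  200 replications; 25 objects (300 pairs) — the smallest round object
  count leaving ~200 test pairs beyond the larger training size.

On the matched environment the interior-peak margin is resolvable for the
COR sweep but not for the half-ridge sweep: with directions known a priori
and 40 training pairs for 6 weights, sign-constrained regression barely
overfits, so the half-ridge curve rises to a weak-prior plateau and the
matched-prior advantage over that endpoint is on the order of 10⁻⁴
accuracy — real but below the 2·SEM resolution of 100 replications. The
strong-prior (tallying) endpoint is beaten by ~25 SEM. The corresponding
acceptance test states the margin condition and is expected to fail for
the half-ridge sweep on this environment; the COR margins are ~5 and
~13 SEM at 500 replications, though the weaker one hovers near 2 SEM at
100.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full
suite under a minute of compute after JIT warm-up: 10–25-object
environments, 81-input exhaustive grids at m = 4, 20 training sets for
limit equivalences, 10⁶ draws for the limit constant, 100–200
replications for the stochastic designs, and 20,000-draw chains where a
sampler is compared against an oracle.

## Known limitations

* The half-ridge sampler is a single chain; the split-chain diagnostic
  catches gross non-convergence but not multimodality (the truncated
  Gaussian posterior is log-concave, so none is expected).
* COR's intermediate-λ weights depend on the flat-direct-prior choice; a
  weak proper prior on direct weights would reproduce the same limits but
  shift the middle of the continuum.
* No L1 (lasso-type) variants of either model, and no empirical-Bayes
  estimation of η; prior strength is always swept externally.
* Only binary outcomes and two-alternative comparisons are supported.
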