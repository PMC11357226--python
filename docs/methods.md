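# Methods

## Factor coding and the Box–Behnken design

Each factor is coded by `x = 2 (a − center) / (high − low)`, so the three
experimental levels map to −1/0/+1. The scale is `(high − low)/2` even
when the center is not the midpoint (a warning is logged in that case);
coding and decoding are exact inverses by construction.

`generate_bbd` builds the k-factor Box–Behnken lattice (k ≥ 3): for each
of the k(k−1)/2 factor pairs, the four (±1, ±1) combinations with all
other factors at 0, followed by the center replicates. Runs are emitted
pair-block by pair-block in factor-index order with the center points
last; no randomization schedule is generated, and all comparisons against
external run lists are order-insensitive (the lattice is a set). For
k = 4 with 5 center points this is the 29-run design of the bundled
reference experiment. Linear columns are mutually orthogonal and
orthogonal to all interaction columns, which the tests exploit (e.g. the
partial SS of a linear term reduces to 12 bⱼ² on this design).

## Quadratic fit and ANOVA

The full second-order model (15 terms for k = 4) is solved by the normal
equations (`solve(X'X, X'y)` with symmetric-positive solver); an
SVD-based generic least-squares routine serves as an independent oracle
in the tests, and statsmodels OLS as a second cross-check. Rank
deficiency is detected with a rank test and reported through QR column
pivoting, naming the collinear terms.

Single-df term sums of squares are **partial (Type III)**,
SSⱼ = bⱼ²/[(X'X)⁻¹]ⱼⱼ, the convention of the DoE software that the
reference tables come from (quadratic columns are not orthogonal to the
intercept, so sequential SS would differ there); sequential (Type I) SS
is available via `anova(..., ss_type="sequential")`. Pure error is the
within-group SS over replicate groups, where replicates are detected by
exact equality of coded rows after rounding to 6 decimals; lack of fit is
the remainder of the residual (clamped at 0 with a warning if numerically
negative), on df(residual) − df(pure error). F ratios: model and term
MS over residual MS; lack-of-fit MS over pure-error MS. p values come
from the upper tail of the F distribution (scipy), rendered as
`<0.0001` below 10⁻⁴ in the text table while full precision is kept in
the CSV/JSON artifacts.

Adjusted R² is `1 − [SS(res)/df(res)] / [SS(tot)/df(tot)]`. On the
bundled dataset this gives ≈ 0.886; it is reported but never asserted
against external values.

## Exact box-constrained maximization

Writing the surface as `b₀ + b'x + x'Bx` (B symmetric, bᵢᵢ diagonal,
bᵢⱼ/2 off-diagonal), the unconstrained stationary point is
`x* = −½ B⁻¹ b`, classified maximum/minimum/saddle by the eigenvalue
signs of B. Over a box, the maximum lies either at an interior stationary
point or on a face; every face is a lower-dimensional box for a
restricted quadratic, so enumerating the stationary points of all 3^k
fixed/free patterns (each factor at its lower bound, upper bound, or
free) together with the corners yields the exact global maximum. An
L-BFGS-B polish from the best candidate guards against numerical slip;
ties break toward the lexicographically smallest coded point. The default
domain is the experimental region [−1, 1]^k — optimizing outside it is
extrapolation and requires explicitly wider bounds. Tests verify
agreement with a 21-per-axis grid-plus-refinement oracle on 200 random
concave surfaces and dominance over the full 3⁴ lattice on arbitrary
(saddle/convex) ones.

## Network surrogate

Topology 4-9-1: tanh hidden layer, identity output — the standard
function-fitting configuration of the toolbox family the training mode
("gradient descent with momentum") comes from; the source study does not
state activations. Inputs and output are min-max scaled to [−1, 1]
before training (scalers are fitted on the full dataset so every design
point is in range). Weights initialize from U(−1/√fan-in, +1/√fan-in),
seeded. Training is full-batch gradient descent on the MSE with momentum,
Δw(t) = −η ∇MSE + μ Δw(t−1), η = 0.1, μ = 0.7 by default. Analytic
gradients are verified against central finite differences in the tests.
A non-finite loss raises a divergence error naming the epoch.

The default data split is 70/15/15 (train/validation/test) by seeded
random permutation, with early stopping after 6 consecutive epochs
without validation improvement and restoration of the best-validation
weights — sensible defaults for predictive use. For reproducing the
reference *fit statistics*, however, the package trains on the complete
dataset (`split=(1, 0, 0)`): the study's published per-run network
predictions match several experimental values exactly and are constant
across the five replicated center runs, i.e. its reported fit quality
describes a network fit to all 29 runs. Under that regime every seed
tried converges to R² ≈ 0.995 on the full design within 1000 epochs;
under a 70/15/15 split the all-runs R² is generalization-limited to
≈ 0.9 at this sample size (29 points, noise SD ≈ 3.8 mg g⁻¹), which is
why held-out training is not used for the reference comparison.

The frozen fixture network (`data/ann_fixture.json`) is a reconstruction
of the study's trained model, which is documented only through its fit
statistics and its GA optimum: `scripts/make_ann_fixture.py` trains seeds
0–19 on the full dataset (all reach R² 0.995) and freezes the seed whose
box-constrained argmax lies closest, in coded Euclidean distance, to the
study's reported optimum conditions. The selection rule is part of the
script and was fixed before freezing.

## Genetic algorithm

Real-coded chromosomes over the coded box (no binary encoding). Per
generation: linear-ranking fitness assignment with selective pressure 2,
stochastic universal sampling of `round(GGAP · N)` parents, arithmetic
(blend) crossover with probability 0.7 (per-gene convex combinations, so
offspring stay in the box), per-gene uniform-reset mutation with
probability 0.1, and survival of the top `N − round(GGAP · N)` elites
(2 of 40 at the default generation gap 0.95). Elitism makes the
per-generation best monotonically non-decreasing, which is asserted on
every run in the tests. All randomness flows from one seeded generator;
identical seed/config/fitness gives identical trajectories. The source
study names only the operator probabilities; the selection scheme,
encoding and elitism mechanics are this package's documented choices from
the same toolbox lineage.

## Comparison metric

The verification ("relative") error is implemented as the absolute
difference between the measured confirmatory yield and the
model-predicted yield, in mg g⁻¹ — the definition under which the
reference report's printed values are exact arithmetic
(128.31 − 125.46 = 2.85; 131 − 130.21 = 0.79). A genuine percentage
error is emitted alongside in a separately named column. Verification
yields are wet-lab measurements and always user-supplied; a missing value
leaves the error cells blank with a warning.

## Synthetic data

`generate` draws a BBD with responses = quadratic(truth) + perturbation
+ N(0, σ²), seeded. Defaults are the study conditions: the published
coefficient vector as truth, 5 center replicates, and σ = 3.78 mg g⁻¹
(the square root of the reference pure-error mean square 14.29). The
noise is homoscedastic Gaussian — exactly the assumption of the OLS
analysis being validated — so passing calibration tests demonstrate
estimator correctness under the model, not robustness to real-data
features such as heteroscedastic measurement error, drift between
blocks, or non-Gaussian tails, none of which are simulated.

The optional lack-of-fit perturbation adds `amplitude · x₁²x₂`, a smooth
cubic term chosen because it is *not* in the span of the 15 quadratic
model columns on the BBD support (verified numerically in the tests;
pure cubics xᵢ³ alias with the linear terms on three-level designs and
triple products vanish on a BBD). `pure_error_calibration` replicates
the generate→fit→ANOVA loop to check that the pure-error MS is unbiased
for σ² and that the 5% lack-of-fit test holds its nominal type-I error
under the null.

## Problem sizes and tolerances

The reference analyses are desk-scale (29 runs, 15 parameters) and
deterministic; tests assert them at the published rounding. Stochastic
components use fixed seed sets chosen a priori: 20 training seeds for the
best-of-seeds fit-quality bound, 10 GA seeds for optimum reproducibility,
500 replicates for coefficient-recovery/coverage checks and 1000 for the
type-I-error and pure-error calibrations. Grid oracles use 21 points per
axis for quadratics (exact optimizer available as reference) and 41 per
axis for the network surrogate. Floating-point identities (round trips,
orthogonality, oracle agreement) are asserted at 10⁻⁸–10⁻¹² as noted in
the individual tests.

## Known limitations

- The exact box maximizer enumerates 3^k face patterns; it is meant for
  the small k of designed experiments (k ≲ 10), not high dimensions.
- The network trainer implements plain momentum gradient descent only —
  no Levenberg–Marquardt or adaptive optimizers — because that is the
  procedure being modeled; it is not a general-purpose ML trainer.
- GA constraint handling is box-only; desirability-style multi-response
  optimization is out of scope.
- With 29 observations a near-interpolating 9-hidden-unit network is
  not a validated predictor away from the design points; the comparison
  report quantifies fit, not extrapolation quality.
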