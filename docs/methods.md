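# Methods

`pathwayopt` implements batch Bayesian optimization over a discrete grid of
combinatorial pathway designs, together with the synthetic benchmarks used
to characterize it and the plate-level plumbing needed to run it against a
biofoundry. This note records the model, the pinned numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Problem setting

A pathway of `d` genes is tuned by choosing, for each gene, one of `L`
ordered promoter/RBS combinations (an expression ladder). A design is a
point `x = (x_1, …, x_d)` with `x_j ∈ {1, …, L_j}`; the canonical instance
is the 3-gene lycopene pathway (crtE, crtB, crtI) with 24 levels per gene,
a grid of 24³ = 13,824 constructs. The objective `f(x)` is product titer,
observable only by building and assaying the construct — expensive, noisy,
and without a useful mechanistic model. The goal is to locate the grid
maximum with as few evaluations as possible.

Levels enter the model through the affine map `(x_j − 1)/(L_j − 1)` onto
`[0,1]` per factor. Treating levels as a *strength-ranked* ladder is a
modeling commitment: it is what makes a smooth prior over the grid
meaningful. Library files are therefore required to be pre-sorted by
strength, and the loader verifies monotonicity when `relative_strength` is
present.

## Surrogate model

The surrogate is a Gaussian process with a Matérn 5/2 kernel with automatic
relevance determination (one lengthscale per gene, in unit coordinates) and
a homoskedastic Gaussian noise term. Outputs are standardized to zero mean
and unit variance before fitting; the GP mean is the constant 0 in
standardized space. The noise term is how the optimizer "expects an error"
in assay reads: it keeps the posterior variance of evaluated designs
positive, so replicate means from different rounds (e.g. the repeated
control construct) are reconciled rather than interpolated exactly.

Hyperparameters — lengthscales, signal variance, noise variance — are set
by maximizing the log marginal likelihood with analytic gradients and a
seeded multi-start L-BFGS-B in log space. Defaults and bounds
(standardized units):

| parameter        | bounds         | start            |
|------------------|----------------|------------------|
| lengthscale (per dim) | [0.05, 5] | 0.3 + random restarts |
| signal variance  | [0.1, 10]      | 1.0              |
| noise variance   | [10⁻⁶, 1]      | 10⁻²             |

With fewer than `2d` observations the prior-default hyperparameters are
used without optimization (lengthscales are not identifiable from fewer
points than dimensions). A fitted noise floor of 10⁻⁸ and Cholesky jitter
escalation (10⁻⁸ → 10⁻⁴) guard conditioning; failure beyond that raises,
it is not hidden. Maximum marginal likelihood was chosen over Monte-Carlo
hyperparameter marginalization for determinism and testability; the
squared-exponential kernel is available behind `FitConfig(kernel="rbf")`.

## Acquisition

Expected Improvement over the incumbent (the best replicate-mean observed
so far):

    EI(x) = (μ(x) − y* − ξ) Φ(z) + σ(x) φ(z),   z = (μ(x) − y* − ξ)/σ(x)

with `ξ = 0` by default and the `σ = 0` limit `max(μ − y* − ξ, 0)`.

Batches are assembled greedily with Monte-Carlo fantasies for pending
points: after each slot's EI-argmax is chosen, `n_fantasies` (default 10)
posterior draws are taken at that point and their mean is appended as a
pretend observation with hyperparameters frozen, so later slots account
for the information the pending experiments will bring. Ties in the EI
argmax break to the lowest lexicographic enumeration index, making batch
selection fully deterministic given a seed. Evaluated designs are excluded
from candidacy; a designated control construct (the mid-ladder point
`(12,12,12)` in the canonical campaign) occupies the last slot of every
batch and is re-built every round to expose batch-to-batch drift.

The first round of a campaign bypasses the model: nothing is known, so a
space-filling design is used (Latin-hypercube strata per factor, rounded
to grid levels, de-duplicated, topped up at random). A plain uniform draw
is available via configuration.

## Campaigns and the foundry interface

A campaign runs `rounds` × `batch_size` with `replicates` biological
replicates per design; observations feed back as replicate means. The
canonical configuration (3 rounds × 46 designs × 4 replicates, control
re-built in rounds 2–3) touches 136 distinct designs — 0.98% of the grid —
and fills exactly two 96-well plates per round once the two assay controls
(no-inoculation blank and empty-plasmid, four replicates each) are added.

Lab mode is file-mediated and round-resumable: `propose_round` writes the
batch, `emit_picklist` expands it into per-part pipetting steps and a
well-to-design layout (row-major A1→H12, replicates adjacent), and
`parse_assay`/`aggregate_to_observations` ingest the measured OD₆₀₀/A₄₇₂
CSV. Ingestion is blocking: a proposed design with no surviving replicate
is reported and stops the round, because silently dropping designs would
bias the model.

Normalization: no-inoculation wells define a per-plate blank subtracted
from both channels (plates without their own blanks use the run-wide blank
mean); negative corrected values clamp to zero with a flag. The titer
proxy is `A₄₇₂ / (0.36 · OD₆₀₀)` — absorbance per g/L dry cell weight,
using the E. coli conversion 0.36 g DCW per OD₆₀₀ unit. Wells with
corrected OD₆₀₀ ≤ 0.01 are excluded as failed growth rather than zeroed:
a multiplicative normalization at near-zero biomass is meaningless. No
mg/L calibration is applied; all comparisons in this package are ratios of
the same proxy.

## Synthetic landscapes and the noise model

Benchmark ground truth is a random surface on the grid: a weighted sum of
isotropic Gaussian bumps in unit coordinates, rescaled so the grid maximum
equals 9, with the true maximum and argmax recorded by full enumeration.
The pinned generator draws a single component with width uniform in
[0.55, 1.1] and center uniform in [−1.25, 2.25]³ — wider than the grid, so
a realistic share of landscapes peak at extreme expression levels (a face
or corner of the grid), as flux-limited pathways often do. These defaults
were calibrated once so that the sequential search below exhibits the
reference difficulty (≈10 noiseless evaluations to the true maximum, ≈8
to 95% of it, with steep degradation under assay noise) and are frozen;
multi-peaked surfaces are available by raising `k_max`.

Evaluation noise is multiplicative Gaussian: each replicate is
`f(x)·(1 + ε)`, `ε ~ N(0, rate²)`, clamped at zero (titers are
nonnegative). "10% error" therefore means a 10% relative standard
deviation, the usual convention for analytical assays; 20% is about the
upper bound of colorimetric quantification. `rate = 0` reproduces
noiseless values bit-for-bit and consumes no random numbers.

What the generator does **not** emulate: heteroskedastic noise (error
growing with signal differently than proportionally), batch effects and
plate-position effects, assembly failures, level-to-strength
miscalibration (the ladder is taken as exactly ordered), and epistatic
ruggedness beyond what a smooth low-dimensional mixture expresses. Passing
benchmarks therefore demonstrate the optimizer's sample efficiency and
noise robustness *under a smooth, honestly-ordered landscape*, not
performance on arbitrarily rugged real pathways.

## Benchmarks

**Sequential search** (`run_sequential_max_search`): starts from a
`d`-point space-filling design (hyperparameters stay at prior defaults
below `2d` points regardless, so the model-driven phase begins as early as
possible), then repeatedly refits the GP and evaluates the EI-argmax among
unevaluated grid points, one single-replicate read at a time, until the
true argmax has been evaluated or a 400-evaluation cap is hit. Evaluation
counts include the initial design. Hyperparameters are refit every
iteration while fewer than 40 observations, then every fifth iteration
with a warm start — a pure speed measure; the acquisition is unchanged.

**Error robustness** (`benchmark_error_robustness`): the same seeded
landscapes are reused at every error rate (paired design), with
independent noise streams per (landscape, rate). Reported per rate:
mean evaluations before the maximum and before 95% of the maximum
(averaged over runs where the criterion was met — the success percentages
carry the failures), and the two success percentages over all runs.

**Batch-size study** (`batch_size_study`): rounds to reach 95% of the
maximum as a function of batch size, paired across sizes; batch size 1
reduces exactly to the sequential search.

**Baselines**: `random_screen` draws distinct uniform designs with the
same noise/replicate model as campaigns (paired seeds for fair
comparison); `resampled_max_stats` models the expected best of an
`n`-member random library by resampling maxima from a normal fit to the
screened titers (1000 repetitions by default).

Problem sizes: the test suite runs the robustness benchmark at 25
landscapes per rate; `scripts/acceptance.py` runs the noiseless benchmark
at 100 landscapes. Both recompute everything from scratch from a root
seed; every stochastic component (landscape draw, initial design, noise,
fantasy draws, optimizer restarts) consumes a deterministically derived
substream, so paired comparisons are exactly reproducible.

## Known limitations

- Homoskedastic noise only; heteroskedastic models are out of scope.
- The GP treats replicate means as single observations with a shared noise
  variance; replicate-count information is not propagated.
- EI with a stationary kernel spends evaluations auditing the boundary of
  the cube when the optimum is interior; on broad interior optima the
  endgame (pinning the exact argmax cell among near-equivalent neighbors)
  dominates the evaluation count.
- The picklist/layout conventions (row-major fill, controls appended last)
  are pinned conventions, not reconstructions of any particular foundry's
  plate maps.
- No outlier rejection or assembly quality control is applied to assay
  data beyond blank correction and the failed-growth exclusion.
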