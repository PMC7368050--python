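# Methods

## Model

A tumor's somatic SNVs are tabulated into the 96 canonical trinucleotide
substitution contexts (pyrimidine-strand convention; class-major canonical
order C>A, C>G, C>T, T>A, T>C, T>G, then 5′ and 3′ flank alphabetically —
the single source of truth for all row indices). The generative assumption
is two-stage: K mutational processes with known signature distributions
s_k (columns of the n×K catalog S, each summing to 1) mix with non-negative
exposures w to form a latent context distribution; the observed counts
m (Σmᵢ = N) are a multinomial sample of size N from that distribution.

The estimator maximizes the penalized joint log-likelihood

    ℓ(w, p) = Σᵢ { mᵢ log pᵢ − (α/2)(pᵢ − (Sw)ᵢ)² } − λ Σₖ c_k (γ w_k + (1−γ) w_k²)
    s.t. w ≥ 0, p ≥ 0, Σ pᵢ = 1

with α = 1/σ² the precision of the linear tie between the latent
distribution and the signature fit, λ ≥ 0 the penalty strength, γ ∈ [0,1]
the elastic-net mixing (γ = 1, pure L1, is the default), and c_k ≥ 0
per-signature penalty factors. The deviation of p from the count MLE m/N is
priced by the multinomial term in units of N, and the deviation of p from
the fit Sw in units of α, so the total mutation count directly controls how
much the data may override the linear model — the sampling-variance
awareness that motivates the joint formulation.

## Algorithm

ℓ is concave in w at fixed p and in p at fixed w (biconvex), so it is
maximized by alternating convex search starting from p⁰ = m/N:

* **w-step.** Minimize (α/2)‖p − Sw‖² + λΣ c_k(γw_k + (1−γ)w_k²) over
  w ≥ 0 by cyclic coordinate descent in Gram form with closed-form
  non-negative soft-thresholded updates (numba-compiled kernels; sweeps
  stop when the largest coordinate move is < 1e-13). Warm starts are used
  along λ paths and across outer iterations.
* **α update.** After every w-step, σ̂² = SSE/(n−k) with k the number of
  non-zero coefficients, and α = min(α_cap, max(α_min, confidence·1/σ̂²)).
  Defaults α_min = 400 and confidence = 0.1: the floor prevents gross
  overestimation of σ² in early iterations, the confidence factor guards
  against real-data violations of the linear model (unknown signatures,
  contamination). SSE = 0 maps to the finite cap α_cap = 1e8 rather than
  infinity.
* **p-step.** With p̃ = Sw fixed, the simplex-constrained maximizer is
  exact: a Lagrange multiplier Λ for Σpᵢ = 1 decouples the problem into
  per-context quadratics pᵢ² − (Λ/α + p̃ᵢ)pᵢ − mᵢ/α = 0. Only the positive
  root is kept (the negative root violates pᵢ ≥ 0), computed in a
  cancellation-free form, so pᵢ = 0 exactly where mᵢ = 0. Λ is the unique
  root of Σpᵢ(Λ) = 1 (the sum is strictly increasing in Λ), found by
  bracketed Brent iteration expanding around Λ = −N — the exact solution
  whenever m = N·p̃, in which case p = p̃ identically.
* **Stopping.** The loop ends when ‖p^{t+1} − p^t‖₂² < ε (default 1e-8) or
  after t_max = 50 iterations; in practice the median is ~4 iterations.
  Each (w-step, p-step) pair cannot decrease ℓ at fixed (λ, α), which the
  test suite asserts on recorded traces with the hyperparameters frozen.

## λ tuning

Contexts of the same substitution class are correlated, so cross-validation
blocks are class-balanced: the 96 contexts are split into 8 blocks of 12,
each holding exactly 2 random contexts per class. For every λ on a
descending 50-point log grid from λ_max (the smallest λ giving w = 0 under
the current α) down to λ_max·10⁻⁴, weights are fitted on the 84 training
contexts and scored by held-out MSE against the current p on the 12 test
contexts; the 8 blocks are cycled and the partition redrawn cv_repeats = 20
times. The chosen λ is the largest whose mean CV-MSE lies within
sd_multiplier (1.0 default, 0.5 selectable) standard deviations of the
minimum, where the SD is taken over the held-out fold scores at the
minimizing grid point. Taking the fold-level SD (rather than the SD of
per-repeat means) was a deliberate choice: it is the spread the band rule
is meant to discount, and the tighter alternative collapses the band to the
curve minimum on clean data, defeating the sparsity the rule exists to
provide. Under the elastic-net option γ is grid-searched jointly with λ
(default grid 0.1…1.0) and the largest γ, then the largest λ, inside the
band is picked. Signature columns are *not* renormalized to the 84 training
contexts — renormalization would break comparability of coefficients across
folds.

Tuning runs before the first w-step and is re-run only when p moves by more
than retune_threshold = 1e-4 (squared L2) in one iteration; otherwise λ is
frozen so partition randomness cannot stall convergence. The frozen
quantity is the penalty on the least-squares scale, λ/α: that is what the
CV folds actually validated, and it keeps the w-step problem invariant when
α is re-estimated between iterations (α routinely moves by orders of
magnitude as the fit tightens; freezing the absolute λ would silently
change the effective regularization by the same factor). A user-supplied
fixed λ is applied on the absolute scale of the objective and disables
tuning. The reported λ is the absolute value at the final iteration.

## Priors and adaptive penalties

`make_prior_penalties` sets c_k = prior_strength for signatures believed
active (typical strengths 0.5 / 0.1 / 0.01; smaller = stronger prior) and 1
elsewhere. `adaptive_penalties` sets c = 1/β with β the non-negative OLS
coefficients of p on S; β_k = 0 maps to the cap 1e6, effectively excluding
the signature unless the data strongly demand it. When both are wanted they
compose multiplicatively (c_k = prior_k/β_k); the two mechanisms are
independent uses of the same penalty-factor vector.

## Synthetic data

`simulate_sample` draws: the number of active signatures k ~ U{2..8} —
matching the empirical sparsity of per-tumor signature activity — with
weights uniform on the simplex conditioned on a 0.02 floor (rejection
sampling; acceptance probability (1−0.02k)^{k−1} ≥ 0.3 at k = 8); additive
noise |N(0, noise_level/96)| on n_noise ~ U{1..25} random contexts followed
by renormalization; and a multinomial draw of N mutations. The noise unit
is deliberately a named constant (`NOISE_SCALE_REFERENCE` = mean per-context
mixture mass 1/96): "noise level 0.1" then means half-normal perturbations
of one-tenth of a typical context's mass, a few percent of total mutation
mass over the affected contexts.

The bundled 30-signature catalog is **synthetic**: Dirichlet columns whose
concentration varies log-uniformly from spiky to flat, emulating the mix of
sharp (UV-, APOBEC-like) and diffuse (clock-like) profiles of real
catalogs, deterministic in its seed and regenerable by
`synthetic_catalog()`. Real analyses should substitute a published catalog
file (COSMIC v2 layout is read directly). Because the synthetic columns are
less collinear than real COSMIC signatures, support-recovery results on it
bound the difficulty of the simulation design, not of real tumors; the
benchmark, variance, and abstention experiments characterize the estimator,
not any specific biological catalog.

What the generator does **not** emulate: non-uniform signature prevalence
across cancer types, correlated (systematic) noise such as sequencing
artifacts, signatures absent from the catalog, and copy-number or
clonality structure. Passing the simulation suite therefore shows the
estimator solves its stated statistical problem, not that real-tumor
attributions are correct.

## Experiment scales

The default experiment sizes keep a full run to minutes on one CPU and are
the package's study conditions: the benchmark grid uses noise levels
{0, 0.1} × mutation counts {50, 500, 5000} × 25 replicates per cell with
true-signature priors at strength 0.1; the sampling-variance curve uses 50
seeds per mutation count over {50, 500, 5000, 50000} with a fixed
5-signature mixture at noise 0.1, and the low-count comparison 100 seeds at
N = 100; abstention subsamples a 20 000-mutation sample without replacement
at {all, 1000, 100, 20} × 10 draws. The parameter-recovery check fits the
rounded multinomial expectation (N = 50 000) of the noiseless mixture
0.5/0.3/0.2 of three bundled signatures (indices 8, 21, 24 in 1-based
naming: SynSig8, SynSig21, SynSig24).

## Numerical choices and edge cases

* Coordinate-descent tolerance 1e-13 on the largest move; KKT conditions of
  the w-step verified to 1e-6 against independent optimizers in tests.
* Λ root solve: xtol 1e-12; the simplex constraint holds to 1e-10 without
  renormalization.
* γ = 0 (pure ridge) has no finite λ_max; the grid anchor uses
  max(γ, 0.01).
* Ties in λ selection break toward the larger λ (sparser solution); the
  descending grid makes this the first in-band index.
* An all-zero solution across the whole grid returns the largest grid λ
  with a warning flag.
* Empty spectra are rejected (N = 0 carries no information); empty VCFs
  produce a valid all-zero spectrum with a warning.
* assigned_fraction is Σw_k raw (signature columns sum to 1, so Σ(Sw) =
  Σw); it may slightly exceed 1 and is reported unclipped. Weights are also
  reported normalized to proportions, but raw is canonical.
* One user seed drives CV partitioning and every simulation; identical
  seeds give bit-identical outputs.

## Known limitations

Single-sample fits only (no joint or hierarchical multi-sample model); no
bootstrap confidence intervals; SNV trinucleotide contexts only (no indel,
doublet or genome-build handling beyond flank lookup); the composition
order of the α floor and confidence factor is max(floor, confidence/σ̂²),
one of two readings the calibration admits; whether held-out CV error
should be measured against p or against held-out count MLEs is similarly
open — the current p is used, as it is the quantity the w-step actually
regresses on.
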