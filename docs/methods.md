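# Methods

## The model family

The package works with quadratic ordinary differential equation models of
brain electrical activity. Each model describes the latent rhythm vector
`y(t) = (y1, …, yk)` measured by EEG electrodes at `k` cortical sites:

    dy_q/dt = c_q + Σ_m a_qm y_m + yᵀ B_q y ,   q = 1 … k,

a constant drive plus linear coupling plus a full quadratic form per
channel. Observed signals are `x_q(t_i) = y_q(t_i) + ε_q(t_i)` with
i.i.d. Gaussian measurement noise ε. Three fully parameterised
three-channel instances are built in, corresponding to electrode triples
C3/C4/T5 (model 1) and P3/P4/O1 (models 2 and 3) in Parkinson's-disease
recordings. Their coefficients are stored verbatim in
`models.py::_PDI_PACKED`.

Two conventions matter and are fixed throughout:

* Cross terms. The printed equations write each cross term once with a
  doubled coefficient (`2 b_ij · y_i y_j`). The structured representation
  stores the halves symmetrically (`B[q][i,j] = B[q][j,i] = half the
  printed value`); the packed `k × j` matrix `D` (with
  `j = 1 + 2k + k(k−1)/2`) keeps the doubled value in a single column
  per pair. This makes `D · monomial_features(y) ≡ rhs(y)` an exact
  identity and pack/unpack lossless.
* Model 3's first equation contains a quadratic term with a repeated
  `y1` factor in the slot every other equation uses for the `y1·y2`
  cross product. The default reading (`model3_cross="positional"`)
  treats it as the cross term with doubled coefficient 0.235; the
  alternative (`"squared"`) folds it into the `y1²` column. Both are
  implemented; the positional reading matches the slot pattern of the
  other equations and is the default.

## Reference trajectories

Reference solutions use a fixed-step 4th-order Adams–Bashforth–Moulton
predictor–corrector in PECE form, started with three classical RK4
steps. A fixed step was chosen because the surrogate is trained on a
uniform time grid; the integrator samples exactly those nodes. The
default grid is `[0, 5]` at step 0.02, i.e. 251 nodes and, with k = 3,
753 scalar targets.

Initial states: the default is `y0 = (1, 1, 1)`, under which all three
built-in models stay bounded on `[0, 5]` (max |y| ≈ 7.6, 16.5, 7.9).
All surrogate-fit metrics measure agreement with the generated
reference and are insensitive to which bounded trajectory is used.
Quadratic systems can blow up in finite time, so the integrator aborts
with the failure time as soon as any |y| exceeds 1e6; this guard doubles
as the pre-flight check before training.

Accuracy: the scheme is verified to be order 4 (halving the step cuts
the endpoint error ≈16×) and agrees with a fine-step RK4 oracle to
≈2×10⁻⁴ at the default step on model 1 — the honest O(h⁴) level for
these dynamics — and to below 10⁻⁶ at step 0.0025. The surrogate is
trained to reproduce the integrator's output, so integrator error does
not propagate into the fit metrics.

## The surrogate network

One scalar input (time), `H` logistic hidden units, `k` linear outputs:

    out(t) = W2 σ(W1 · norm(t) + b1) + b2,  σ(z) = 1/(1+e⁻ᶻ),

with `norm` the min–max map of the fitted time range onto [−1, 1].
Targets are left in raw signal units so every reported MSE is in raw
units squared (a target-normalisation map exists but is off by
default). Weight count is `5H + 3` for k = 3 (103 / 253 / 503 at the
study widths 20 / 50 / 100).

Initialisation is a seeded Nguyen–Widrow-style scheme: hidden weights of
magnitude `0.7·H` with random signs, biases spreading the unit centres
across [−1, 1], small uniform output weights. The residual Jacobian
`∂e/∂w` is computed analytically by backpropagation and is verified
against central finite differences (relative 1e−5) in the test suite.

## Training

Both trainers are damped Gauss–Newton (Levenberg–Marquardt) loops: each
epoch solves `(Ĥ + μI) δ = −g` and inflates the damping μ (×10) until
the objective decreases, then relaxes it (×0.1). Defaults: μ₀ = 1e−3,
μ_max = 1e10, gradient stop 1e−7 (infinity norm), validation patience 6,
1000 epochs. The dataset is split 80/10/10 (validation and test sizes
`round(0.1·N)`, training the remainder) by a seeded permutation.

* LM minimises the training MSE, early-stops on the validation subset,
  and returns the best-validation-epoch weights. Training MSE is
  non-increasing across accepted steps by construction.
* BR (Bayesian regularization, MacKay's evidence framework in the
  Foresee–Hagan style) minimises `F = β E_D + α E_W` (`E_D` = sum of
  squared training residuals, `E_W` = sum of squared weights), starting
  from α = 0, β = 1, and after every accepted step re-estimates

      γ = N_w − 2α tr(H⁻¹),  H = 2β JᵀJ + 2α I
      α = γ / (2 E_W),       β = (N_D − γ) / (2 E_D)

  where γ is the effective number of parameters. γ is evaluated through
  the eigenvalues of JᵀJ (`γ = Σ βλ/(βλ+α)`), which is algebraically the
  same quantity but remains exact when β grows to ~1e10 on noise-free
  data and H becomes too ill-conditioned to invert. Guards: the α update
  is skipped while `E_W ≤ 1e−30`; the β update is skipped if `E_D` is at
  machine zero or `γ ≥ N_D`. BR keeps the 80/10/10 split but uses
  validation only for reporting — it runs to the epoch, gradient, or
  damping limit.

On the noise-free reference data β grows without bound as the fit
deepens, so the effective regularisation α/β vanishes and BR converges
to machine-precision-deep minima (final training MSE ~1e−12); under
noisy targets γ stabilises far below `N_w` and BR generalises at least
as well as LM, which is the behaviour the trainer exists to provide.

Restarts: training outcomes depend on the initialisation seed, so
scenario runs support seeded restarts, keeping the run with the lowest
final training MSE. The shipped evaluation protocol uses 3 restarts for
LM and 2 for BR at 1000 epochs each, which reaches the documented
performance levels with large margins while keeping a full evaluation
under a few minutes on one CPU.

## Metrics

Per-channel MSE `mean((y_q − ỹ_q)²)` and pooled MSE over all channels;
elementwise absolute error; the regression index R — the Pearson
correlation between flattened reference and predicted values (the
statistic fitting-tool regression plots display, not R²) — per channel
and pooled; error histograms over 20 uniform bins (configurable)
reporting the zero-straddling bin's centre; and phase-portrait
(parametric-plot) extraction of all channel pairs and the full 3-D
curve.

## Coefficient identification

The inverse problem stacks one monomial feature row
`[1, y, y², cross products]` per time sample into the design matrix `Y`,
estimates derivatives `Ẏ`, and solves `Y Dᵀ ≈ Ẏ` by ordinary least
squares (one shared factorisation for all equation rows). Derivatives
come from 4th-order finite differences — 5-point central stencils in
the interior, one-sided 4th-order stencils at the first/last two nodes —
or, for noise-free validation, from the analytic right-hand side. The
least squares is deliberately unregularised to match the exactly
determined construction; a ridge option exists for ill-conditioned noisy
fits, and rank-deficient designs (e.g. a constant trajectory) are
rejected with the offending condition number. No denoising is applied
before fitting; the noise level σ is a fixture parameter of the
synthetic measurement generator.

With noise-free data and analytic derivatives the recovery is exact to
~1e−8 on the built-in models; with finite-difference derivatives the
O(h⁴) truncation error dominates; under measurement noise the
coefficient error decreases monotonically with σ (verified over
σ ∈ {0.1, 0.01, 0.001} × 10 replicates).

## Synthetic data: what it does and does not emulate

The measurement generator produces `x = y + ε` with i.i.d. Gaussian ε —
the stated observation model. Real EEG departs from this in ways the
package intentionally does not model: coloured/structured noise,
artefacts, non-stationarity, and sensor drift. Passing tests therefore
certify the numerical machinery (integration, training, identification)
under the stated model, not robustness to real recording conditions;
denoising (e.g. multiscale PCA) is explicitly out of scope.

## Numerical choices and edge cases

* Damped systems are solved by Cholesky factorisation; μ > 0 keeps them
  SPD by construction.
* A perfect fit (zero residuals) short-circuits the LM step: the
  Gauss–Newton step is exactly zero, so the step is accepted unchanged.
* Degenerate normalisation ranges (min = max) map to 0.
* Histogram of identical residuals widens the range by ±0.5 to keep one
  occupied bin.
* The blow-up time reported on divergence is accurate to a coarse step
  or two — near a finite-time singularity a fixed-step method overshoots
  the bound within the step containing the true crossing.
* All randomness (initialisation, splits, noise) flows through
  `numpy.random.default_rng` seeds; identical (seed, config, data) give
  bit-identical results.

## Known limitations

* Fixed-step, non-stiff integration only; no adaptive or dense output.
* Single hidden layer; logistic activation only.
* The identification basis is the fixed degree-2 monomial library; no
  model selection over larger libraries.
* BR's `tr(H⁻¹)` cost is O(N_w³) per epoch — fine at the study widths
  (N_w ≤ 503), not intended for much larger networks.
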