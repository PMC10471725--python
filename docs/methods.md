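# Methods

## The model class and the inverse problem

`mlecont` calibrates deterministic dynamical models

    dx/dt = f(x, t, θ, condition),    x(0) = x₀(θ, condition),

with parameters θ in a box Ω = [lower, upper] ⊂ ℝᵖ, against a table of
measurements φ = {(tᵢ, φᵢ, σᵢ, cᵢ)} (the *calibration data*).  A
condition label per row selects an experimental regime (drug on/off) or a
measurement channel (viral load vs CD4 count); each distinct condition is
integrated once per model evaluation and the residuals are flattened into
one vector.  The observable map h turns the trajectory into one value per
data row; the misfit is the weighted sum of squares

    G(θ, φ) = Σᵢ (zᵢ(θ) − T(φᵢ))² / σᵢ²,

where z = T(y) is either the raw observable or its log10 (the
`log10_sum_of_squares` objective, standard for viral loads and cell
counts).  G is the Gaussian negative log-likelihood with fixed, known σᵢ
and all θ-independent terms dropped, so its minimiser θ* is the MLE.  σᵢ
is never estimated.

## Continuation of the MLE in data space

θ*(φ) is defined implicitly by stationarity, D_θ G(θ*, φ) = 0.  Where
the Hessian H = D²_θ G (the observed Fisher information) is invertible,
the implicit function theorem gives the data → parameter Jacobian

    DΨ = −H⁻¹ M,      M[n, i] = ∂²G/∂θₙ∂T(φᵢ) = −2 Sₜ[n, i]/σᵢ²,

with Sₜ[n, i] = ∂zᵢ/∂θₙ the local sensitivities.  The *predictor* maps a
perturbed data set to a first-order MLE estimate at zero additional model
evaluations:

    Ψ(φ + Δφ) ≈ θ* + DΨₜ · (T(φ + Δφ) − T(φ)).

The expansion is taken in the transformed data T(φ) — the variable the
likelihood actually depends on — so multiplicative perturbations of
log-compared data are handled at their natural scale.  The matrix exposed
as `ContinuationState.dpsi` is the Jacobian with respect to the *raw*
data values (chain rule: `dpsi = dpsi_transformed · T′(φ)`); sensitivity
reports, column sums and the matrix 1-norm all use it.

The *corrector* (`correct_mle`) is a bounded trust-region-reflective
least-squares refinement of the weighted residual vector, with the
package's central-difference sensitivity matrix as the Jacobian, followed
by up to three damped Newton polish steps on the free parameter subspace.
The polish exists because trust-region stopping rules leave a ~1e-4
relative wobble along flat likelihood valleys; differentiating refits
(the validation oracle below) requires refits reproducible to much better
than the probe-induced shift.  Polish steps may be accepted at a
noise-level objective increase (1e-9 relative) because the wobble they
remove lies where objective differences sit at the integrator-noise
floor.

### Active bounds

Nonlinear least-squares fits of sloppy models routinely pin one or two
parameters at a bound of Ω.  A pinned parameter cannot respond to an
infinitesimal data perturbation, so continuation acts on the *free
subspace*: DΨ rows of pinned parameters (those within one
finite-difference step of a bound) are zero and the linear system is
solved on the free block.  This matches what a brute-force refit
derivative measures, since small data perturbations keep the active set.

### Conditioning

The condition number that signals practical unidentifiability is that of
the *Jacobi-equilibrated* Hessian D H D, D = diag(1/√|Hₙₙ|).  The raw
Hessian's condition number is dominated by parameter units (an infection
rate of 2·10⁻⁵ against a burst size of 900 contributes ~10¹⁴ of spurious
conditioning); the equilibrated number measures parameter correlation,
which is the scientific signal.  Above the threshold (default 10¹⁰)
`compute_dpsi` raises and names the near-null eigendirection.  The solve
itself is performed on the equilibrated system.

## Derivatives and their steps

All derivatives are finite differences; the steps matter and are split by
order:

- **First derivatives** (sensitivities, gradient): central differences
  with per-parameter step `max(1e-4·|θₙ|, 1e-8)`.  At an active bound the
  stencil slides off the bound (offset central, first-order) rather than
  failing; it errors only when a parameter has no room at all.
- **Second derivatives**: step `max(3e-3·|θₙ|, 1e-8)`.  A second
  difference divides the objective's noise floor (~1e-10 with the default
  integrator tolerances rtol 1e-10 / atol 1e-12) by h², so its optimal
  step scales as the fourth root of the noise — roughly 3·10⁻³ — rather
  than the first-derivative scale.  Stencils are exact on quadratics,
  including the unequally-spaced variants used near bounds.

Two Hessian routes are provided:

- `hessian_fd` double-differences the objective (central or forward
  diagonal, four-point mixed stencils); at most 2p(p+1) objective
  evaluations.  Its equilibrated accuracy is limited to ~1e-4…1e-5,
  which blurs eigenvalues below that fraction of the spectrum.
- `hessian_least_squares` (the default for DΨ builds) exploits the
  least-squares structure: H = 2 Σ wᵢ [∇zᵢ∇zᵢᵀ + rᵢ ∇²zᵢ], with the
  Gauss–Newton term formed from first differences (error ~h²) and only
  the residual-weighted curvature taken from second-difference stencils
  of z, where stencil noise enters multiplied by the (small) residuals.
  Near a good fit this is one to two orders of magnitude more accurate at
  the same cost class (at most 2p(p+1)+1 model simulations), and it is
  what makes the refit-derivative validation below meet percent-level
  agreement.

Evaluation counters (model simulations, per-condition integrations,
objective evaluations) are first-class: a sensitivity matrix costs
exactly 2p simulations, a Hessian at most 2p(p+1) evaluations, and one
full DΨ build at most 2p(p+2) model simulations.  Corrector costs are
reported as total simulations consumed, the unit in which optimisers'
function counts are usually quoted (finite-difference Jacobian
evaluations included).

## Built-in models

**Viral dynamics** (`models/viral.py`): the target-cell-limited model
dT/dt = λ − βTV − dT, dI/dt = βTV − δI, dV/dt = δN·I − cV with reference
parameters β = 2·10⁻⁵, d = 0.15, δ = 0.55, c = 5.5, N = 900, λ = 80 (per
day) and fixed known initial conditions (T₀, I₀, V₀) = (600, 30, 10⁵):
an established infection observed from a high viral load, so the early
samples of the 8-point schedule {0.4, 1, 8, 14, 20, 36, 46, 58} d see
the fast virion-clearance transient.  Two observable channels are
selected by condition label: log10 V (default) and log10 T (`"cd4"`).
Bounds are one decade around the reference values.  With viral load
alone the six-parameter problem is practically unidentifiable (the
equilibrated Hessian spans ~10⁵); adding the CD4 channel — both assays
are routine in clinical studies — brings it to ~10³ and keeps noisy MLEs
interior.

**Phenotype switching** (`models/phenotype.py`): a synthetic
two-compartment analog of drug-sensitive (A) / drug-tolerant (B) NSCLC
growth: logistic competition at shared carrying capacity K = 10⁴ cells,
an Allee-type cooperation boost f(B) = 1 + B/(100 + B) on the tolerant
growth rate, a treatment switch d_A → d_A^max from day 3 in the treated
condition, tied death rates d_A = d_B, observable N = A + B compared on
the log10 scale.  Fitted vector [r_A, r_B, d_A, d_A^max] with reference
truth [0.9, 0.5, 0.15, 1.6] /d, inoculum (A₀, B₀) = (90, 10).  The
constants are chosen here (not transcribed from any published
calibration) to reproduce the qualitative phenotype-switching phenotype:
control growth, immediate post-day-3 decline, nadir near day 5.5,
tolerant-driven rebound by day 7.  The six-point design (control days
0, 2, 4, 6; treated days 4, 6) makes the day-0 row a zero-sensitivity
point — its value is the fixed inoculum — which doubles as the built-in
example of a data point the MLE cannot see.

**Linear model** (`models/linear.py`): y = Xθ wrapped as a degenerate
ModelSpec, with closed-form MLE and DΨ = (XᵀWX)⁻¹XᵀW.  Every
finite-difference path is validated against it, since all stencils are
exact there.

## Synthetic data and the study definitions

All experiments run on seeded synthetic data (`synthetic.py`); every
generator is a pure function of its inputs and one seed.  The
perturbation schemes are: additive half-normal shifts φᵢ + h·|εᵢ|
(coherently up or down with sign(h)); multiplicative log-normal noise
exp(0.8·ε); and norm-scaled log10 displacements rescaled so that
‖log10 φʲ − log10 φ⁰‖ = (0.05 + j·h)·‖log10 φ⁰‖ exactly, with ordering
constraints (treated ≤ control on shared days) enforced by seeded redraw
of the offending components.

`studies.py` freezes the reference experiments:

- the **viral oracle study**: both channels at the 8-point schedule,
  log10 noise SD 0.1 on each (a clinically plausible assay error), fit
  from the truth;
- the **stepwise study**: single-channel baseline with noise variance
  0.15 and the four h ∈ {±0.1, ±0.2} half-normal shifts;
- the **phenotype sequence**: ten norm-scaled sets with h = 0.07 (so the
  tenth reaches a 75 % relative log-norm displacement), *one* normal
  draw rescaled across j.  Reusing the draw makes the sequence a
  coherent noise trajectory — the regime an iterated
  predictor–corrector steps through; independent draws per j change the
  noise direction completely between steps and no first-order method
  tracks that.  Fresh-draw sequences remain available by varying the
  seed per j;
- the **candidate ranking**: treated-condition times
  {3.1…3.5, 5, 7} d with perturbation ±0.3·N(3.1; θ*).

What the generators emulate — and what they do not: i.i.d. Gaussian
noise on the (log) observation scale, fixed known σ, no censoring, no
measurement-time jitter, no between-replicate correlation.  Passing
tests therefore demonstrate the calculus of the method under its own
noise model, not robustness to real-world error structure.

## Validation strategy

Three independent oracles check the data→parameter Jacobian:

1. **Closed form**: the linear model, exact for every stencil.
2. **Refit derivatives**: central differences of fully re-optimised MLEs
   at φ ± ε·eₖ.  This requires the corrector reproducibility discussed
   above, probes small enough to stay in the linear response regime of
   the argmin map (ε = 0.01 on log-scale data; the map's nonlinearity,
   not the Jacobian's accuracy, dominates disagreement beyond it), and a
   study whose MLE is interior and decently conditioned — hence the
   two-channel oracle design.
3. **First-order consistency**: the predictor error against corrected
   MLEs shrinks quadratically in the perturbation scale (log–log slope
   ≈ 2 over scales {1, ½, ¼} of a fixed random direction with per-point
   RMS 0.05).

Known limitations:

- The stepwise predictor degrades for large *coherent* shifts of every
  data point at sloppy single-channel MLEs, where small rate parameters
  would be extrapolated by tens of percent; the corrector recovers the
  refit cheaply, but the uncorrected prediction can be a poor fit.  The
  package reports the computed misfits rather than assuming parity.
- All derivative quality rests on integrator determinism; raising rtol
  above ~1e-8 invalidates the default steps.
- The candidate-ranking direction statements are model-specific: in the
  phenotype analog the "lower count ⇒ higher fitted kill rate" direction
  holds at nadir-region measurements (kill-dominated), while immediately
  post-treatment the fitted response is growth-dominated and can point
  the other way.  The ± antisymmetry of the tornado is exact regardless.

Problem sizes used throughout (8–16 data rows, 4–6 parameters, ten-step
sequences) are the studies' own designs; each acceptance-style check
runs in seconds to a few minutes on one core.
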