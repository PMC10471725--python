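# mlecont

Continuation of maximum-likelihood estimators in calibration-data space
for dynamical models in biology.

When an ODE model is calibrated against data that keep changing — new
time points from an ongoing experiment, revised counts during an
epidemic — the best-fit parameters θ\*(φ) are an implicit function of the
data φ. `mlecont` computes the local Jacobian of that function and uses
it to *predict* the new best fit without re-optimising, to rank which
measurements most constrain the fit, and to score the robustness of
competing fits.

## The method

The MLE minimises the weighted least-squares misfit (the Gaussian
negative log-likelihood with fixed, known noise scales σᵢ)

```
G(θ, φ) = Σᵢ (yᵢ(θ) − φᵢ)² / σᵢ²,
```

so it satisfies the stationarity condition D_θ G(θ\*, φ) = 0. The
implicit function theorem turns this condition into a data → parameter
Jacobian

```
DΨ = −[D²_θ G]⁻¹ D²_{θ,φ} G   ∈ ℝ^{p×d},
```

built from two finite-difference objects: the observed Fisher
information H = D²_θ G (p×p) and the mixed partial M = −2 ∂yᵢ/∂θₙ / σᵢ²
(p×d), which is just the local sensitivity matrix reweighted. One full
DΨ build costs at most 2p(p+2) model simulations. The first-order
predictor

```
Ψ(φ + Δφ) = θ* + DΨ·Δφ + O(‖Δφ‖²)
```

then maps a data update to a parameter update at **zero** additional
simulations; an optimizer-backed corrector (`correct_mle`) refines it
when needed. The absolute column sums of DΨ measure how strongly each
data point steers the fit: their maximum is ‖DΨ‖₁, the argmax is the
most informative data point, and appending exactly-simulated candidate
measurements (which leave the MLE unchanged) before rebuilding DΨ ranks
future experiments.

Two worked model systems ship with the package: a target-cell-limited
viral dynamics model (HIV-1: target cells, infected cells, free virus;
observables log10 viral load and log10 CD4 count) and a synthetic
two-phenotype tumour-growth model (drug-sensitive/drug-tolerant NSCLC
populations with an Allee cooperation term and a day-3 treatment
switch). A linear model y = Xθ with closed-form MLE and DΨ anchors the
numerics. See `docs/methods.md` for the numerical design (step sizes,
the residual-split Hessian, active-bound handling, conditioning).

## Worked example

Fit the phenotype model to a seeded six-point synthetic data set, ask
which measurement the fit is most sensitive to, then predict — without
re-optimising — the best fit for a perturbed copy of the data:

```python
import numpy as np
from mlecont import MLEContinuation, most_informative_point, perturb_norm_scaled
from mlecont.studies import phenotype_baseline, PHENOTYPE_CONSTRAINTS

study = phenotype_baseline(seed=7)
est = MLEContinuation(model=study.model, objective_kind="log10_sum_of_squares")
est.fit(study.data, study.fit.theta)
print("MLE:", {n: round(v, 4) for n, v in est.theta_star_.as_dict().items()})
print("objective G(theta*, phi):", round(est.objective_value_, 5))

idx, norm = most_informative_point(est.dpsi_)
print("most informative data row:", study.data.row_labels()[idx],
      "  sensitivity:", round(norm, 5))

perturbed = perturb_norm_scaled(study.data, 1, 0.01, seed=99, base_offset=0.0,
                                constraints=PHENOTYPE_CONSTRAINTS)
print("predicted MLE for perturbed data:", np.round(est.predict(perturbed), 4))
corrected = est.correct(perturbed)
print("corrected MLE:              ", np.round(corrected.theta.values, 4))
```

Output:

```
MLE: {'r_A': 0.7484, 'r_B': 0.368, 'd_A': 0.001, 'd_A_max': 1.3329}
objective G(theta*, phi): 0.00806
most informative data row: 4@treated   sensitivity: 0.00363
predicted MLE for perturbed data: [7.4950e-01 4.3220e-01 1.0000e-03 1.5059e+00]
corrected MLE:               [7.5000e-01 4.1110e-01 1.0000e-03 1.5036e+00]
```

Reading this: the fitted growth/death rates (per day) sit at
r_A ≈ 0.75, r_B ≈ 0.37, with the shared baseline death rate pinned at
its lower bound (its DΨ row is zero — continuation acts on the free
parameters) and a treatment kill rate d_A^max ≈ 1.33. The fit responds
most strongly to the treated day-4 count (the nadir of the population
under treatment). For a ~1 % log-norm perturbation of the data the
zero-simulation prediction agrees with the fully re-optimised MLE to a
few percent in every free parameter; the treatment kill rate moves from
1.333 to ≈ 1.505 and the predictor tracks it at 1.506.

The same workflow runs from the shell (`mlecont generate | fit |
continue | design | compare-minima`); each run logs its seed, config
hash and simulation counts.

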