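# isoturn

Stable-isotope diet-switch analysis: isotopic incorporation kinetics,
half-life estimation with individual heterogeneity, diet–tissue
discrimination factors, and simulation-based evaluation of sampling
designs.

## The problem

When a consumer switches between two isotopically distinct diets, the
δ¹³C and δ¹⁵N values of its tissues relax from their initial values
toward new asymptotes. Two quantities drive every ecological inference
built on stable isotopes:

* **discrimination** Δ = δ_tissue − δ_diet (‰), the offset between a
  tissue and the diet it equilibrated on, and
* **turnover**, summarized by the **half-life**: the time for half of a
  tissue's isotopic composition to be renewed after a diet shift.

`isoturn` implements the analysis of a controlled diet-switch feeding
experiment on a structured population (for example 40 farmed arctic
foxes, balanced females/males and adults/yearlings, 20 animals shifted
from a terrestrial to a marine diet with serial blood sampling over 70
days, the rest kept as controls). Incorporation follows the
one-compartment first-order model

```
δ(t) = Φ₁ + (Φ₂ − Φ₁) · exp(−exp(Φ₃) · t),      t½ = ln 2 / exp(Φ₃)
```

with Φ₁ the asymptotic δ value, Φ₂ the initial value at the shift
(day 0) and exp(Φ₃) the fractional incorporation rate (1/day). The
population model adds a Gaussian individual random effect on Φ₃ (no two
animals renew a tissue at quite the same rate) and optional sex/age
fixed effects on Φ₃. A two-compartment (two-pool) variant is available
for overparametrization diagnostics, and the fitted curve can be
inverted as an *isotopic clock*: given an observed δ value, how long
ago did the diet shift happen?

Intended users: trophic ecologists and ecophysiologists designing or
analysing captive feeding experiments, and anyone who needs defensible
half-life and discrimination estimates with uncertainty before applying
them to field data.

## What is in the box

| module | contents |
| --- | --- |
| `isoturn.kinetics` | one-/two-compartment models, half-lives, per-individual NLS, nonlinear mixed-model fitting (adaptive Gauss–Hermite marginal likelihood; two-stage and Laplace alternatives), AIC selection (ΔAIC < 2, simplest), Wald/bootstrap CIs, isotopic clock, control-group equilibrium check |
| `isoturn.discrimination` | Δ computation, C:N-based lipid normalization of δ¹³C, group summaries, linear mixed model ladder (diet/tissue/sex/age + two-way interactions, individual random intercept, ML selection + REML refit), Welch two-diet comparison |
| `isoturn.synthgen` | seeded generators for the full experiment: shifted arm, control arm, discrimination records |
| `isoturn.design_sim` | TurnoverSim-style engine: bias/SD/quantiles of asymptote, intercept and half-life under candidate sampling schedules; SE-versus-n tables |
| `isoturn.io`, `isoturn.cli` | validated long-format CSV I/O, YAML config, reproducibility manifests, `isoturn` command with `simulate`, `fit-turnover`, `fit-discrimination`, `design-sim` subcommands |

## Worked example

```python
import isoturn as it

# Simulate the marine-shift arm: 20 animals, plasma d13C with a
# 9-day generating half-life, 0.2 permil noise, random-effect SD 0.25
# on the log-rate.
truth = it.default_trajectory_truth("plasma", "d13C")
data = it.simulate_trajectories(it.PopulationSpec(20, 20), truth, seed=42)

fit = it.fit_population(data)          # nonlinear mixed model
print(f"half-life {fit.half_life_days:.2f} d, "
      f"95% CI ({fit.half_life_ci[0]:.2f}, {fit.half_life_ci[1]:.2f})")
print(f"random-effect SD on log-rate: {fit.re_variance['phi3']**0.5:.3f}")

params = it.OneCompartmentParams(fit.estimates["phi1"],
                                 fit.estimates["phi2"],
                                 fit.estimates["phi3"])
print(f"isotopic clock: delta = -20.0 permil implies "
      f"{it.time_since_diet_shift(-20.0, params):.1f} d since the shift")
```

prints

```
half-life 9.89 d, 95% CI (8.94, 10.94)
random-effect SD on log-rate: 0.223
isotopic clock: delta = -20.0 permil implies 17.6 d since the shift
```

The fitted half-life is the population value for the log-rate intercept
(9.89 d here against a generating value of 9 d for this one simulated
dataset; the mean over many replicates is unbiased — see the acceptance
script). The clock inversion answers "how many days ago did this animal
switch diets" from a single δ observation, valid strictly between the
initial and asymptotic values.

The same pipeline from the shell:

```sh
isoturn simulate --seed 42 --out run1
isoturn fit-turnover --input run1/measurements.csv --out run1/fit
isoturn design-sim --config scenario.yaml --seed 7 --out run1/design
```

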