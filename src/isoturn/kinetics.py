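"""Isotopic incorporation kinetics for diet-switch experiments.

After a consumer switches between two isotopically distinct diets, the
isotope ratio of a metabolically active tissue relaxes from its initial
value toward a new asymptote.  The canonical description is first-order
(one-compartment) incorporation,

    delta(t) = phi1 + (phi2 - phi1) * exp(-exp(phi3) * t),

where ``phi1`` is the asymptotic delta value (permil), ``phi2`` the
initial value at the moment of the diet shift (day 0) and ``exp(phi3)``
the fractional incorporation rate (1/day).  The half-life -- the time
for half of the tissue's isotopic composition to be renewed -- is
``ln 2 / exp(phi3)``.

This module provides:

* forward prediction for one- and two-compartment models,
* half-life derivation (closed form and root-finding),
* per-individual nonlinear least-squares fitting,
* a population (mixed) fit with individual random effects and sex/age
  fixed effects on the incorporation rate,
* AIC model selection with the "delta-AIC < 2, prefer the simplest"
  rule,
* Wald and parametric-bootstrap confidence intervals,
* the isotopic-clock inversion (time elapsed since the diet shift), and
* an equilibrium check for control groups that never changed diet.

The default population estimator maximizes the exact marginal
likelihood of the random-log-rate model, integrating the individual
random effect by adaptive Gauss-Hermite quadrature.  A transparent
two-stage alternative (per-individual NLS, then a Gaussian
random-effects combination of the estimates) and a Laplace-approximate
maximizer are available behind the same interface; see
``fit_population``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OneCompartmentParams",
    "TwoCompartmentParams",
    "RandomEffectsSpec",
    "FixedEffectsDesign",
    "TurnoverFit",
    "EquilibriumReport",
    "predict_one_compartment",
    "half_life_one_compartment",
    "predict_two_compartment",
    "half_life_two_compartment",
    "fit_individual",
    "residual_normality",
    "fit_population",
    "select_model",
    "confidence_intervals",
    "time_since_diet_shift",
    "check_equilibrium",
    "phi3_for_half_life",
]

LN2 = math.log(2.0)

#: Floor on the residual variance used in Gaussian log-likelihoods, so
#: that noiseless (interpolating) fits stay on a finite, comparable
#: likelihood scale.
_SIGMA2_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class OneCompartmentParams:
    """Single-pool first-order incorporation parameters.

    phi1
        Asymptotic delta value (permil).
    phi2
        Initial delta value at day 0 (permil).
    phi3
        Log of the fractional incorporation rate (log(1/day)); the rate
        ``exp(phi3)`` is positive by construction.
    """

    phi1: float
    phi2: float
    phi3: float

    def __post_init__(self) -> None:
        _require_finite(phi1=self.phi1, phi2=self.phi2, phi3=self.phi3)


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Two-pool incorporation parameters.

    The tissue is modelled as a mixture of a fast pool (fraction ``p``,
    rate ``k1``) and a slow pool (fraction ``1 - p``, rate ``k2``), with
    the identifiability convention ``k1 >= k2``.  With ``p = 1`` (or
    ``k1 = k2``) the model collapses to the one-compartment model with
    ``exp(phi3) = k1``.
    """

    phi1: float
    phi2: float
    p: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        _require_finite(phi1=self.phi1, phi2=self.phi2, p=self.p,
                        k1=self.k1, k2=self.k2)
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"pool fraction p must lie in [0, 1], got {self.p}")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rates k1 and k2 must be positive")
        if self.k1 < self.k2:
            raise ValueError("identifiability convention requires k1 >= k2")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Which parameters carry an individual-level Gaussian deviation.

    At least one parameter must carry a random effect: the population
    model always acknowledges individual heterogeneity somewhere.
    """

    parameters_with_re: tuple[str, ...] = ("phi3",)
    sd_by_parameter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.parameters_with_re:
            raise ValueError("at least one parameter must carry a random effect")
        bad = set(self.parameters_with_re) - {"phi1", "phi2", "phi3"}
        if bad:
            raise ValueError(f"unknown random-effect parameters: {sorted(bad)}")
        for name, sd in self.sd_by_parameter.items():
            if sd < 0:
                raise ValueError(f"random-effect sd for {name} must be >= 0")


@dataclass(frozen=True)
class FixedEffectsDesign:
    """Population-structure covariates acting on one parameter.

    ``covariates`` is a subset of ``{"sex", "age", "sex:age"}`` (the
    interaction requires both main effects); ``target_parameter`` is the
    phi the covariates shift additively (default the log-rate ``phi3``).
    """

    covariates: tuple[str, ...] = ()
    target_parameter: str = "phi3"

    def __post_init__(self) -> None:
        bad = set(self.covariates) - {"sex", "age", "sex:age"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")
        if "sex:age" in self.covariates and not {"sex", "age"} <= set(self.covariates):
            raise ValueError("sex:age interaction requires both main effects")
        if self.target_parameter not in {"phi1", "phi2", "phi3"}:
            raise ValueError(f"unknown target parameter {self.target_parameter!r}")


@dataclass
class TurnoverFit:
    """Result of a turnover fit (individual or population).

    ``aic`` is always recomputable as ``-2 * loglik + 2 * n_params``.
    When ``converged`` is False the estimates are flagged unusable and
    no half-life is reported.
    """

    model_kind: str
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ci: dict[str, tuple[float, float]]
    half_life_days: float | None
    half_life_ci: tuple[float, float] | None
    aic: float
    loglik: float
    n_params: int
    converged: bool
    re_variance: dict[str, float]
    n_individuals: int
    n_observations: int
    n_fixed_effects: int = 0
    n_random_effects: int = 0
    rate_identifiable: bool = True
    boundary: bool = False
    group_half_lives: dict[str, float] = field(default_factory=dict)
    notes: tuple[str, ...] = ()
    residual_sd: float | None = None
    _boot: dict | None = field(default=None, repr=False)

    @property
    def complexity_rank(self) -> tuple[int, int, int]:
        """Lexicographic complexity used to break delta-AIC < 2 ties."""
        return (self.n_params, self.n_fixed_effects, self.n_random_effects)


# ---------------------------------------------------------------------------
# Forward models and half-lives
# ---------------------------------------------------------------------------

def predict_one_compartment(params: OneCompartmentParams, t):
    """Predicted delta value (permil) at time ``t`` days after the shift."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time points must be finite")
    if np.any(t < 0):
        raise ValueError("time since diet shift must be >= 0")
    out = params.phi1 + (params.phi2 - params.phi1) * np.exp(-math.exp(params.phi3) * t)
    return float(out) if out.ndim == 0 else out


def half_life_one_compartment(phi3: float) -> float:
    """Half-life ``ln 2 / exp(phi3)`` in days; strictly decreasing in phi3."""
    _require_finite(phi3=phi3)
    return LN2 * math.exp(-phi3)


def phi3_for_half_life(half_life_days: float) -> float:
    """Inverse of :func:`half_life_one_compartment`."""
    if not np.isfinite(half_life_days) or half_life_days <= 0:
        raise ValueError("half-life must be a positive finite number of days")
    return math.log(LN2 / half_life_days)


def predict_two_compartment(params: TwoCompartmentParams, t):
    """Predicted delta value under the two-pool mixture model."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time points must be finite")
    if np.any(t < 0):
        raise ValueError("time since diet shift must be >= 0")
    mix = params.p * np.exp(-params.k1 * t) + (1.0 - params.p) * np.exp(-params.k2 * t)
    out = params.phi1 + (params.phi2 - params.phi1) * mix
    return float(out) if out.ndim == 0 else out


def half_life_two_compartment(params: TwoCompartmentParams) -> float:
    """Time at which half of the initial-to-asymptotic gap has been traversed.

    Solves ``p exp(-k1 t) + (1 - p) exp(-k2 t) = 1/2`` by bracketed root
    search; for a single active pool this is ``ln 2 / k``.
    """
    if params.phi1 == params.phi2:
        raise ValueError("half-life undefined: initial and asymptotic values equal")
    if params.p == 1.0:
        return LN2 / params.k1
    if params.p == 0.0:
        return LN2 / params.k2

    def gap(t: float) -> float:
        return (params.p * math.exp(-params.k1 * t)
                + (1.0 - params.p) * math.exp(-params.k2 * t) - 0.5)

    hi = LN2 / params.k2
    while gap(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-14))


def time_since_diet_shift(delta_obs: float, params: OneCompartmentParams) -> float:
    """Isotopic clock: invert the incorporation curve for elapsed time.

    ``delta_obs`` must lie strictly between the asymptote and the
    initial value (inclusive of the initial value, where the elapsed
    time is zero); at the asymptote the elapsed time is infinite and an
    error is raised.
    """
    _require_finite(delta_obs=delta_obs)
    if params.phi1 == params.phi2:
        raise ValueError("clock undefined: flat trajectory (phi1 == phi2)")
    frac = (delta_obs - params.phi1) / (params.phi2 - params.phi1)
    if frac == 0.0:
        raise ValueError("delta equals the asymptote: elapsed time is infinite")
    if frac < 0.0 or frac > 1.0:
        lo, hi = sorted((params.phi1, params.phi2))
        raise ValueError(
            f"observed delta {delta_obs} outside the trajectory range ({lo}, {hi})")
    return -math.log(frac) / math.exp(params.phi3)


# ---------------------------------------------------------------------------
# One-compartment nonlinear least squares (profiled on the rate)
# ---------------------------------------------------------------------------
# Given the rate k = exp(phi3) the model is linear in (phi1, phi2):
#   y = phi1 * (1 - e^{-kt}) + phi2 * e^{-kt}
# so the sum of squares is profiled down to one dimension and minimized
# by a coarse log-spaced grid followed by local refinement.  This avoids
# the multi-start machinery a 3-parameter optimizer would need.

def _profile_sse(k: np.ndarray, t: np.ndarray, y: np.ndarray):
    """Vectorized profiled SSE over an array of candidate rates."""
    e = np.exp(-np.outer(k, t))            # (G, n)
    x1 = 1.0 - e
    a11 = np.einsum("gn,gn->g", x1, x1)
    a12 = np.einsum("gn,gn->g", x1, e)
    a22 = np.einsum("gn,gn->g", e, e)
    b1 = x1 @ y
    b2 = e @ y
    det = a11 * a22 - a12 * a12
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    phi1 = (a22 * b1 - a12 * b2) / det
    phi2 = (a11 * b2 - a12 * b1) / det
    sse = y @ y - (phi1 * b1 + phi2 * b2)
    return sse, phi1, phi2


def _fit_onecomp_core(t: np.ndarray, y: np.ndarray, n_grid: int = 64):
    """Profiled NLS for the one-compartment model.

    Returns ``(phi1, phi2, phi3, sse, rate_identifiable)``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tmax = float(t.max())
    dt_min = float(np.diff(np.unique(t)).min())
    # Half-life search window: a fraction of the tightest spacing up to
    # far beyond the experiment's duration.
    hl_lo, hl_hi = dt_min / 8.0, 50.0 * tmax
    k_grid = LN2 / np.geomspace(hl_lo, hl_hi, n_grid)
    sse, _, _ = _profile_sse(k_grid, t, y)
    good = np.isfinite(sse)
    sse_grid = np.where(good, sse, np.inf)
    i = int(np.argmin(sse_grid))
    lo = math.log(k_grid[min(i + 1, n_grid - 1)])
    hi = math.log(k_grid[max(i - 1, 0)])
    if lo >= hi:
        logk_hat = math.log(k_grid[i])
    else:
        res = optimize.minimize_scalar(
            lambda lk: float(_profile_sse(np.array([math.exp(lk)]), t, y)[0][0]),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        logk_hat = float(res.x)
    sse_hat, phi1_hat, phi2_hat = _profile_sse(np.array([math.exp(logk_hat)]), t, y)
    phi1_hat, phi2_hat, sse_hat = float(phi1_hat[0]), float(phi2_hat[0]), float(sse_hat[0])
    sse_hat = max(sse_hat, 0.0)

    # Rate identifiability: a flat trajectory leaves the profiled SSE
    # indifferent to k.  Compare against the constant-mean model.
    sse_const = float(np.sum((y - y.mean()) ** 2))
    scale = max(sse_const, 1e-12)
    identifiable = (sse_const - sse_hat) > 1e-7 * scale
    if not identifiable:
        mean = float(y.mean())
        return mean, mean, logk_hat, sse_const, False
    return phi1_hat, phi2_hat, logk_hat, sse_hat, True


def _onecomp_jacobian(phi1: float, phi2: float, phi3: float, t: np.ndarray) -> np.ndarray:
    k = math.exp(phi3)
    e = np.exp(-k * t)
    return np.column_stack([1.0 - e, e, (phi2 - phi1) * (-t) * e * k])


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, _SIGMA2_FLOOR)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _wald_ci(est: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return (est - z * se, est + z * se)


def _half_life_ci_from_phi3(ci_phi3: tuple[float, float]) -> tuple[float, float]:
    lo, hi = ci_phi3
    return (LN2 * math.exp(-hi), LN2 * math.exp(-lo))


def _clean_trajectory(days, deltas) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(days, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("days and deltas must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("trajectory contains non-finite values")
    if np.any(t < 0):
        raise ValueError("days must be >= 0 (day 0 is the moment of the diet shift)")
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


def fit_individual(days: Sequence[float], deltas: Sequence[float],
                   model_kind: str = "one_compartment",
                   level: float = 0.95) -> TurnoverFit:
    """Nonlinear least-squares fit of one trajectory.

    Requires at least 4 distinct time points for the one-compartment
    model and 6 for the two-compartment model (free parameters plus a
    residual degree of freedom).  Non-convergence is reported through
    ``converged=False``, never as an exception.
    """
    t, y = _clean_trajectory(days, deltas)
    n_distinct = np.unique(t).size
    if model_kind == "one_compartment":
        if n_distinct < 4:
            raise ValueError(
                f"one-compartment fit needs >= 4 distinct time points, got {n_distinct}")
        return _fit_individual_onecomp(t, y, level)
    if model_kind == "two_compartment":
        if n_distinct < 6:
            raise ValueError(
                f"two-compartment fit needs >= 6 distinct time points, got {n_distinct}")
        return _fit_individual_twocomp(t, y, level)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _fit_individual_onecomp(t: np.ndarray, y: np.ndarray, level: float) -> TurnoverFit:
    n = t.size
    phi1, phi2, phi3, sse, identifiable = _fit_onecomp_core(t, y)
    dof = max(n - 3, 1)
    sigma2 = sse / dof
    J = _onecomp_jacobian(phi1, phi2, phi3, t)
    jtj = J.T @ J
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        cov_ok = bool(np.all(np.isfinite(ses)))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
        cov_ok = False
    if not identifiable:
        # Flat trajectory: the rate is meaningless; report huge
        # uncertainty on phi3 rather than a spurious precision.
        ses = np.array([math.sqrt(max(sigma2 / n, 0.0))] * 2 + [np.inf])
        cov_ok = True

    names = ("phi1", "phi2", "phi3")
    estimates = dict(zip(names, (phi1, phi2, phi3)))
    standard_errors = dict(zip(names, map(float, ses)))
    ci = {k: _wald_ci(estimates[k], standard_errors[k], level) for k in names}
    loglik = _gaussian_loglik(sse, n)
    n_params = 4  # phi1, phi2, phi3, residual sd
    hl = half_life_one_compartment(phi3) if identifiable else None
    hl_ci = _half_life_ci_from_phi3(ci["phi3"]) if identifiable else None
    notes = () if identifiable else (
        "rate unidentifiable: trajectory indistinguishable from constant",)
    fitted = predict_one_compartment(OneCompartmentParams(phi1, phi2, phi3), t)
    return TurnoverFit(
        model_kind="one_compartment",
        estimates=estimates, standard_errors=standard_errors, ci=ci,
        half_life_days=hl, half_life_ci=hl_ci,
        aic=-2.0 * loglik + 2.0 * n_params, loglik=loglik, n_params=n_params,
        converged=cov_ok, re_variance={}, n_individuals=1, n_observations=n,
        rate_identifiable=identifiable,
        residual_sd=math.sqrt(sigma2),
        notes=notes,
        _boot={"kind": "individual", "t": t, "y": y,
               "fitted": np.asarray(fitted),
               "sigma": math.sqrt(max(sse / n, 0.0)), "model_kind": "one_compartment"},
    )


def _expit(x: float) -> float:
    return float(stats.logistic.cdf(x))


def _fit_individual_twocomp(t: np.ndarray, y: np.ndarray, level: float) -> TurnoverFit:
    n = t.size

    def unpack(u):
        phi1, phi2, q, a, d = u
        k1 = math.exp(a)
        k2 = k1 * _expit(d)        # enforces k2 <= k1
        p = _expit(q)
        return phi1, phi2, p, k1, k2

    def resid(u):
        phi1, phi2, p, k1, k2 = unpack(u)
        mix = p * np.exp(-k1 * t) + (1.0 - p) * np.exp(-k2 * t)
        return phi1 + (phi2 - phi1) * mix - y

    # Start from the one-compartment solution; jittered multi-start
    # because the two-pool objective is multi-modal.
    p1, p2, p3, _, _ = _fit_onecomp_core(t, y)
    base = np.array([p1, p2, 0.0, p3 + LN2, 0.0])  # k1 = 2k, k2 = k
    rng = np.random.default_rng(12345)
    starts = [base] + [base + rng.normal(0.0, [0.5, 0.5, 1.0, 0.8, 1.5])
                       for _ in range(4)]
    best = None
    for u0 in starts:
        try:
            res = optimize.least_squares(resid, u0, method="lm",
                                         xtol=1e-9, ftol=1e-9, gtol=1e-8,
                                         max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return _failed_fit("two_compartment", n)

    phi1, phi2, p, k1, k2 = unpack(best.x)
    sse = float(2.0 * best.cost)
    J = best.jac
    jtj = J.T @ J
    cond = np.linalg.cond(jtj)
    boundary = abs(best.x[2]) > 4.6 or best.x[3] - math.log(max(k2, 1e-300)) < 1e-3
    converged = bool(best.success) and np.isfinite(cond) and cond < 1e10
    dof = max(n - 5, 1)
    sigma2 = sse / dof
    try:
        cov_u = sigma2 * np.linalg.inv(jtj)
        ses_u = np.sqrt(np.clip(np.diag(cov_u), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses_u = np.full(5, np.nan)
        converged = False

    # Delta-method SEs on the natural scale.
    dp = p * (1.0 - p)
    ep = _expit(best.x[4])
    ses = {
        "phi1": float(ses_u[0]),
        "phi2": float(ses_u[1]),
        "p": float(abs(dp) * ses_u[2]),
        "k1": float(k1 * ses_u[3]),
        "k2": float(math.hypot(k2 * ses_u[3], k1 * ep * (1 - ep) * ses_u[4])),
    }
    estimates = {"phi1": phi1, "phi2": phi2, "p": p, "k1": k1, "k2": k2}
    ci = {k: _wald_ci(estimates[k], ses[k], level) for k in estimates}
    loglik = _gaussian_loglik(sse, n)
    n_params = 6  # 5 curve parameters + residual sd
    hl = None
    if converged and phi1 != phi2:
        try:
            hl = half_life_two_compartment(
                TwoCompartmentParams(phi1, phi2, p, max(k1, k2), min(k1, k2)))
        except ValueError:
            hl = None
    return TurnoverFit(
        model_kind="two_compartment",
        estimates=estimates, standard_errors=ses, ci=ci,
        half_life_days=hl, half_life_ci=None,
        aic=-2.0 * loglik + 2.0 * n_params, loglik=loglik, n_params=n_params,
        converged=converged, re_variance={}, n_individuals=1, n_observations=n,
        boundary=boundary,
        residual_sd=math.sqrt(sigma2),
        notes=("boundary estimate: pool fraction or rates degenerate",) if boundary else (),
    )


def _failed_fit(model_kind: str, n_obs: int, n_individuals: int = 1) -> TurnoverFit:
    return TurnoverFit(
        model_kind=model_kind, estimates={}, standard_errors={}, ci={},
        half_life_days=None, half_life_ci=None,
        aic=math.inf, loglik=-math.inf,
        n_params=6 if model_kind == "two_compartment" else 4,
        converged=False, re_variance={}, n_individuals=n_individuals,
        n_observations=n_obs,
        notes=("optimization failed",))


# ---------------------------------------------------------------------------
# Population (mixed) fitting: two-stage estimator
# ---------------------------------------------------------------------------

def _design_matrix(info: pd.DataFrame, covariates: tuple[str, ...]):
    """Build a treatment-coded design for sex/age covariates.

    ``info`` has one row per individual with whatever label columns the
    data carried.  The first level in sorted order is the reference.
    """
    cols = [np.ones(len(info))]
    names = ["intercept"]
    dummies: dict[str, tuple[np.ndarray, str]] = {}
    for cov in ("sex", "age"):
        if cov not in covariates:
            continue
        if cov not in info.columns:
            raise ValueError(f"covariate {cov!r} requested but column missing from data")
        levels = sorted(info[cov].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level {levels}; "
                             "cannot estimate its effect")
        if len(levels) > 2:
            raise ValueError(f"covariate {cov!r} must be binary, got levels {levels}")
        dummy = (info[cov].astype(str) == levels[1]).to_numpy(float)
        cols.append(dummy)
        names.append(f"{cov}[{levels[1]}]")
        dummies[cov] = (dummy, levels[1])
    if "sex:age" in covariates:
        (ds, ls), (da, la) = dummies["sex"], dummies["age"]
        cols.append(ds * da)
        names.append(f"sex[{ls}]:age[{la}]")
    return np.column_stack(cols), names


def _re_ml(y: np.ndarray, v: np.ndarray, X: np.ndarray, with_re: bool):
    """Gaussian random-effects combination of per-individual estimates.

    Marginal model: ``y_i ~ N(x_i' beta, v_i + tau2)``.  Maximum
    likelihood in ``tau2`` (profile over beta via GLS); ``tau2 = 0``
    when ``with_re`` is False.
    Returns ``(beta, cov_beta, tau2, loglik)``.
    """
    def nll_at(tau2: float):
        w = 1.0 / (v + tau2)
        xtw = X.T * w
        a = xtw @ X
        beta = np.linalg.solve(a, xtw @ y)
        r = y - X @ beta
        nll = 0.5 * float(np.sum(np.log(2.0 * math.pi / w) + w * r * r))
        return nll, beta, a

    if not with_re:
        nll, beta, a = nll_at(0.0)
        return beta, np.linalg.inv(a), 0.0, -nll

    spread = max(float(np.var(y)), 1e-8)
    res = optimize.minimize_scalar(
        lambda lt: nll_at(math.exp(lt))[0],
        bounds=(math.log(1e-10), math.log(100.0 * spread)),
        method="bounded", options={"xatol": 1e-9})
    tau2 = math.exp(float(res.x))
    nll, beta, a = nll_at(tau2)
    nll0, beta0, a0 = nll_at(0.0)
    if nll0 < nll:  # boundary solution tau2 -> 0
        tau2, nll, beta, a = 0.0, nll0, beta0, a0
    return beta, np.linalg.inv(a), tau2, -nll


def _group_labels(info: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    keys = [c for c in ("sex", "age") if c in covariates]
    combos = info[keys].astype(str).drop_duplicates().sort_values(keys)
    return combos.reset_index(drop=True)


def _group_half_lives(info: pd.DataFrame, covariates: tuple[str, ...],
                      beta: np.ndarray, coef_names: list[str]) -> dict[str, float]:
    """Half-life per observed covariate combination, from the phi3 coefs."""
    out: dict[str, float] = {}
    combos = _group_labels(info, covariates)
    for _, combo in combos.iterrows():
        phi3_g = 0.0
        for c, name in enumerate(coef_names):
            if name == "intercept":
                phi3_g += beta[c]
                continue
            # e.g. "sex[M]" or "sex[M]:age[yearling]"
            active = all(str(combo[f.split("[")[0]]) == f.split("[")[1].rstrip("]")
                         for f in name.split(":"))
            if active:
                phi3_g += beta[c]
        key = "|".join(str(combo[c]) for c in combos.columns)
        out[key] = half_life_one_compartment(float(phi3_g))
    return out


def fit_population(data: pd.DataFrame,
                   model_kind: str = "one_compartment",
                   fixed: FixedEffectsDesign | None = None,
                   random: RandomEffectsSpec | None = None,
                   method: str = "marginal",
                   level: float = 0.95) -> TurnoverFit:
    """Population turnover fit with individual heterogeneity.

    ``data`` is a long-format table with columns ``individual_id``,
    ``day``, ``delta_permil`` and, when fixed effects are requested,
    ``sex`` / ``age`` labels.

    The default estimator (``method="marginal"``) maximizes the exact
    marginal likelihood of the one-compartment model with a Gaussian
    random effect on the log-rate, integrating the random effect by
    adaptive Gauss-Hermite quadrature; its AIC is on the
    observation-level likelihood scale.  ``method="two_stage"`` is a
    transparent fallback (per-individual NLS, then a Gaussian
    random-effects combination of the estimates) that also supports
    random effects on phi1/phi2 and the two-compartment model;
    ``method="laplace"`` maximizes a Laplace approximation.  AICs are
    only comparable between fits produced by the same method.
    """
    fixed = fixed or FixedEffectsDesign()
    random = random or RandomEffectsSpec()
    required = {"individual_id", "day", "delta_permil"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing required columns: {sorted(missing)}")
    ids = data["individual_id"].unique()
    if len(ids) < 2:
        raise ValueError("population fit requires at least 2 individuals")
    if method == "laplace":
        return _fit_population_laplace(data, fixed=fixed, random=random, level=level)
    if method == "marginal":
        if (model_kind == "one_compartment"
                and random.parameters_with_re == ("phi3",)
                and fixed.target_parameter == "phi3"):
            return _fit_population_marginal(data, fixed=fixed, random=random,
                                            level=level)
        # Random effects beyond a log-rate intercept fall back to the
        # two-stage combination, which handles them parameter by
        # parameter.
        method = "two_stage"
    if method != "two_stage":
        raise ValueError(f"unknown estimation method {method!r}")
    if model_kind not in {"one_compartment", "two_compartment"}:
        raise ValueError(f"unknown model kind {model_kind!r}")

    # Stage 1: per-individual NLS.
    label_cols = [c for c in ("sex", "age") if c in data.columns]
    rows, ests, variances = [], [], []
    n_obs = 0
    n_failed = 0
    sse_total, dof_total = 0.0, 0
    schedules: dict[str, np.ndarray] = {}
    for ind, grp in data.groupby("individual_id", sort=True):
        t = grp["day"].to_numpy(float)
        y = grp["delta_permil"].to_numpy(float)
        n_obs += len(t)
        fit = fit_individual(t, y, model_kind=model_kind)
        if model_kind == "two_compartment":
            # Two-stage combination is defined on the 3-parameter scale;
            # a two-compartment population fit succeeds only if every
            # individual fit converges away from the boundary.
            if not fit.converged or fit.boundary:
                n_failed += 1
                continue
        if not fit.converged or not fit.rate_identifiable:
            n_failed += 1
            continue
        names = ("phi1", "phi2", "phi3")
        ests.append([fit.estimates[k] for k in names])
        variances.append([max(fit.standard_errors[k] ** 2, 1e-12) for k in names])
        row = {"individual_id": ind}
        for c in label_cols:
            row[c] = str(grp[c].iloc[0])
        rows.append(row)
        schedules[str(ind)] = t
        sse_total += (fit.residual_sd or 0.0) ** 2 * max(len(t) - 3, 1)
        dof_total += max(len(t) - 3, 1)

    if len(ests) < 2:
        out = _failed_fit(model_kind, n_obs, n_individuals=len(ids))
        out.notes = ("fewer than 2 individuals produced usable stage-1 fits",)
        return out

    info = pd.DataFrame(rows)
    E = np.asarray(ests)       # (I, 3)
    V = np.asarray(variances)  # (I, 3)
    sigma_resid = math.sqrt(sse_total / max(dof_total, 1))

    # Stage 2: per-parameter random-effects combination.
    estimates: dict[str, float] = {}
    ses: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    re_variance: dict[str, float] = {}
    loglik = 0.0
    n_params = 0
    beta_by_param: dict[str, tuple[np.ndarray, list[str]]] = {}
    for j, name in enumerate(("phi1", "phi2", "phi3")):
        covs = fixed.covariates if fixed.target_parameter == name else ()
        X, names_j = _design_matrix(info, covs)
        with_re = name in random.parameters_with_re
        beta, cov_beta, tau2, ll = _re_ml(E[:, j], V[:, j], X, with_re)
        loglik += ll
        n_params += X.shape[1] + (1 if with_re else 0)
        if with_re:
            re_variance[name] = tau2
        beta_by_param[name] = (beta, names_j)
        for c, coef_name in enumerate(names_j):
            key = name if coef_name == "intercept" else f"{name}:{coef_name}"
            estimates[key] = float(beta[c])
            ses[key] = float(math.sqrt(max(cov_beta[c, c], 0.0)))
            ci[key] = _wald_ci(estimates[key], ses[key], level)

    hl = half_life_one_compartment(estimates["phi3"])
    hl_ci = _half_life_ci_from_phi3(ci["phi3"])

    # Per-group half-lives when fixed effects act on the log-rate.
    group_hl: dict[str, float] = {}
    if fixed.covariates and fixed.target_parameter == "phi3":
        beta, names_j = beta_by_param["phi3"]
        group_hl = _group_half_lives(info, fixed.covariates, beta, names_j)

    n_fixed = len(fixed.covariates)
    n_re = len(random.parameters_with_re)
    notes = ()
    if n_failed:
        notes = (f"{n_failed} individual fit(s) failed and were excluded",)
    return TurnoverFit(
        model_kind=model_kind,
        estimates=estimates, standard_errors=ses, ci=ci,
        half_life_days=hl, half_life_ci=hl_ci,
        aic=-2.0 * loglik + 2.0 * n_params, loglik=loglik, n_params=n_params,
        converged=True, re_variance=re_variance,
        n_individuals=len(ests), n_observations=n_obs,
        n_fixed_effects=n_fixed, n_random_effects=n_re,
        group_half_lives=group_hl,
        residual_sd=sigma_resid,
        notes=notes,
        _boot={"kind": "population", "info": info,
               "schedules": schedules, "fixed": fixed, "random": random,
               "beta_by_param": beta_by_param, "re_variance": dict(re_variance),
               "sigma": sigma_resid, "model_kind": model_kind},
    )


# --- Exact marginal likelihood via adaptive Gauss-Hermite quadrature -------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(20)
_LOG_SIGMA_FLOOR = math.log(1e-6)


def _fit_population_marginal(data: pd.DataFrame, fixed: FixedEffectsDesign,
                             random: RandomEffectsSpec, level: float) -> TurnoverFit:
    """Maximum marginal likelihood for the random-log-rate model.

    The scalar random effect on phi3 is integrated out by Gauss-Hermite
    quadrature whose nodes are centred and scaled per individual on the
    stage-1 NLS estimate of phi3 (adaptive quadrature at fixed
    reference points), so a 20-node rule resolves even sharply
    identified individual rates.  The log-likelihood is the exact
    observation-level marginal likelihood up to quadrature error.
    """
    label_cols = [c for c in ("sex", "age") if c in data.columns]
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    rows = []
    centers, scales, phi3_hats, phi1_hats, phi2_hats = [], [], [], [], []
    sse_total, n_obs = 0.0, 0
    for ind, grp in data.groupby("individual_id", sort=True):
        t = grp["day"].to_numpy(float)
        y = grp["delta_permil"].to_numpy(float)
        n_obs += len(t)
        groups.append((t, y))
        rows.append({"individual_id": ind,
                     **{c: str(grp[c].iloc[0]) for c in label_cols}})
        ifit = fit_individual(t, y, model_kind="one_compartment")
        phi3_i = ifit.estimates["phi3"]
        se_i = ifit.standard_errors["phi3"]
        if not (ifit.converged and ifit.rate_identifiable and np.isfinite(se_i)):
            se_i = 1.0
        centers.append(phi3_i)
        scales.append(1.5 * min(max(se_i, 0.08), 1.0))
        phi3_hats.append(phi3_i)
        phi1_hats.append(ifit.estimates["phi1"])
        phi2_hats.append(ifit.estimates["phi2"])
        sse_total += (ifit.residual_sd or 0.2) ** 2 * max(len(t) - 3, 1)
    info = pd.DataFrame(rows)
    X, coef_names = _design_matrix(info, fixed.covariates)
    n_ind = len(groups)
    p_beta = X.shape[1]

    centers = np.asarray(centers)
    scales = np.asarray(scales)
    # Pad ragged schedules into masked (I, T) arrays so every
    # quadrature evaluation is a single vectorized expression.
    t_len = max(len(t) for t, _ in groups)
    T = np.zeros((n_ind, t_len))
    Y = np.zeros((n_ind, t_len))
    M = np.zeros((n_ind, t_len))
    for i, (t, y) in enumerate(groups):
        T[i, :len(t)] = t
        Y[i, :len(t)] = y
        M[i, :len(t)] = 1.0
    n_per_ind = M.sum(axis=1)

    def nll(theta: np.ndarray) -> float:
        phi1, phi2 = theta[0], theta[1]
        beta = theta[2:2 + p_beta]
        log_sigma = max(theta[-2], _LOG_SIGMA_FLOOR)
        sigma2 = math.exp(2.0 * log_sigma)
        tau = math.exp(max(theta[-1], _LOG_SIGMA_FLOOR))
        tau2 = tau * tau
        mu3 = X @ beta                                  # (I,)

        # Adaptive step: locate each individual's posterior mode of the
        # random effect b (deviation of phi3 from mu3) by damped Newton
        # with a Gauss-Newton curvature, vectorized over individuals.
        se2 = (scales / 1.5) ** 2
        b = (centers - mu3) * (tau2 / (tau2 + se2))
        b = np.clip(b, -5.0 * tau - 0.5, 5.0 * tau + 0.5)
        gap = phi2 - phi1
        for _ in range(12):
            k = np.exp(mu3 + b)[:, None]                # (I, 1)
            decay = np.exp(-k * T) * M
            resid = (Y - (phi1 + gap * decay)) * M
            dpred = gap * (-T) * decay * k              # d pred / d b
            grad = -np.einsum("it,it->i", resid, dpred) / sigma2 + b / tau2
            curv = np.einsum("it,it->i", dpred, dpred) / sigma2 + 1.0 / tau2
            step = np.clip(grad / curv, -0.5, 0.5)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        s = 1.0 / np.sqrt(curv)                         # (I,)

        nodes = b[:, None] + math.sqrt(2.0) * s[:, None] * _GH_NODES[None, :]
        log_wq = (np.log(_GH_WEIGHTS)[None, :] + _GH_NODES[None, :] ** 2
                  + np.log(math.sqrt(2.0) * s)[:, None])
        rates = np.exp(mu3[:, None] + nodes)            # (I, Q)
        decay = np.exp(-rates[:, :, None] * T[:, None, :]) * M[:, None, :]
        resid = (Y[:, None, :] - (phi1 + gap * decay)) * M[:, None, :]
        sse = np.einsum("iqt,iqt->iq", resid, resid)
        log_lik = (-0.5 * sse / sigma2
                   - 0.5 * n_per_ind[:, None] * math.log(2.0 * math.pi * sigma2))
        log_prior = (-0.5 * nodes ** 2 / tau2
                     - math.log(tau) - 0.5 * math.log(2.0 * math.pi))
        log_integrand = log_wq + log_prior + log_lik
        m = log_integrand.max(axis=1, keepdims=True)
        ll_i = m[:, 0] + np.log(np.sum(np.exp(log_integrand - m), axis=1))
        return -float(np.sum(ll_i))

    # Start values from the stage-1 estimates.
    phi3_hats = np.asarray(phi3_hats)
    beta0 = np.linalg.lstsq(X, phi3_hats, rcond=None)[0]
    resid0 = phi3_hats - X @ beta0
    tau0 = math.sqrt(max(float(np.mean(resid0 ** 2)) - float(np.mean(scales / 1.5) ** 2),
                         1e-4))
    sigma0 = math.sqrt(max(sse_total / max(n_obs - 3 * n_ind, 1), 1e-6))
    theta0 = np.concatenate([
        [float(np.median(phi1_hats)), float(np.median(phi2_hats))], beta0,
        [math.log(sigma0), math.log(tau0)]])

    opt = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-7,
                                     "maxiter": 6000, "maxfev": 6000})
    theta = opt.x
    loglik = -float(opt.fun)
    n_params = len(theta)
    converged = bool(opt.success)

    # Wald covariance from a central-difference Hessian of the nll.
    steps = np.maximum(1e-4, 1e-4 * np.abs(theta))
    k = len(theta)
    H = np.empty((k, k))
    f0 = float(opt.fun)
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k); ea[a] = steps[a]
            eb = np.zeros(k); eb[b] = steps[b]
            if a == b:
                H[a, a] = (nll(theta + ea) - 2.0 * f0 + nll(theta - ea)) / steps[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    nll(theta + ea + eb) - nll(theta + ea - eb)
                    - nll(theta - ea + eb) + nll(theta - ea - eb)
                ) / (4.0 * steps[a] * steps[b])
    try:
        cov = np.linalg.inv(H)
        se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if not np.all(np.isfinite(se_theta[:2 + p_beta])):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se_theta = np.full(k, np.nan)
        converged = False

    phi1, phi2 = float(theta[0]), float(theta[1])
    beta = theta[2:2 + p_beta]
    sigma = math.exp(max(float(theta[-2]), _LOG_SIGMA_FLOOR))
    tau2 = math.exp(2.0 * max(float(theta[-1]), _LOG_SIGMA_FLOOR))
    estimates = {"phi1": phi1, "phi2": phi2}
    ses = {"phi1": float(se_theta[0]), "phi2": float(se_theta[1])}
    for c, nm in enumerate(coef_names):
        key = "phi3" if nm == "intercept" else f"phi3:{nm}"
        estimates[key] = float(beta[c])
        ses[key] = float(se_theta[2 + c])
    ci = {key: _wald_ci(estimates[key], ses[key], level) for key in estimates}
    hl = half_life_one_compartment(estimates["phi3"])
    hl_ci = _half_life_ci_from_phi3(ci["phi3"])

    group_hl: dict[str, float] = {}
    if fixed.covariates:
        group_hl = _group_half_lives(info, fixed.covariates, beta, coef_names)

    beta_by_param = {"phi1": (np.array([phi1]), ["intercept"]),
                     "phi2": (np.array([phi2]), ["intercept"]),
                     "phi3": (beta, coef_names)}
    return TurnoverFit(
        model_kind="one_compartment",
        estimates=estimates, standard_errors=ses, ci=ci,
        half_life_days=hl, half_life_ci=hl_ci,
        aic=-2.0 * loglik + 2.0 * n_params, loglik=loglik, n_params=n_params,
        converged=converged, re_variance={"phi3": tau2},
        n_individuals=n_ind, n_observations=n_obs,
        n_fixed_effects=len(fixed.covariates), n_random_effects=1,
        group_half_lives=group_hl,
        residual_sd=sigma,
        _boot={"kind": "population",
               "info": info,
               "schedules": {str(r["individual_id"]): groups[i][0]
                             for i, (_, r) in enumerate(info.iterrows())},
               "fixed": fixed, "random": random,
               "beta_by_param": beta_by_param,
               "re_variance": {"phi3": tau2},
               "sigma": sigma, "model_kind": "one_compartment"},
    )


# --- Laplace-approximate marginal likelihood (optional estimator) ----------

def _fit_population_laplace(data: pd.DataFrame, fixed: FixedEffectsDesign,
                            random: RandomEffectsSpec, level: float) -> TurnoverFit:
    """Maximize the Laplace-approximate marginal likelihood.

    Supports the one-compartment model with a scalar random effect on
    phi3 (optionally with sex/age fixed effects on phi3).  Slower but
    free of the stage-1 plug-in approximation of the default estimator;
    its AIC is on the observation-level likelihood scale and is only
    comparable between fits produced by this method.
    """
    if random.parameters_with_re != ("phi3",):
        raise ValueError("laplace estimator supports a random effect on phi3 only")
    if fixed.target_parameter != "phi3":
        raise ValueError("laplace estimator supports fixed effects on phi3 only")

    label_cols = [c for c in ("sex", "age") if c in data.columns]
    groups = []
    rows = []
    for ind, grp in data.groupby("individual_id", sort=True):
        groups.append((grp["day"].to_numpy(float), grp["delta_permil"].to_numpy(float)))
        rows.append({"individual_id": ind,
                     **{c: str(grp[c].iloc[0]) for c in label_cols}})
    info = pd.DataFrame(rows)
    X, coef_names = _design_matrix(info, fixed.covariates)
    n_obs = sum(len(t) for t, _ in groups)

    start = fit_population(data, fixed=fixed, random=random, method="two_stage")
    if not start.converged:
        return _failed_fit("one_compartment", n_obs, n_individuals=len(groups))
    beta0 = np.array([start.estimates.get(
        "phi3" if nm == "intercept" else f"phi3:{nm}", 0.0) for nm in coef_names])
    tau0 = math.sqrt(max(start.re_variance.get("phi3", 1e-4), 1e-4))
    sig0 = max(start.residual_sd or 0.2, 1e-3)
    theta0 = np.concatenate([
        [start.estimates["phi1"], start.estimates["phi2"]], beta0,
        [math.log(sig0), math.log(tau0)]])

    def nll(theta: np.ndarray) -> float:
        phi1, phi2 = theta[0], theta[1]
        beta = theta[2:2 + len(coef_names)]
        sigma = math.exp(theta[-2])
        tau = math.exp(theta[-1])
        total = 0.0
        for i, (t, y) in enumerate(groups):
            mu3 = float(X[i] @ beta)

            def g(b: float) -> float:
                pred = phi1 + (phi2 - phi1) * np.exp(-math.exp(mu3 + b) * t)
                r = y - pred
                return (0.5 * float(r @ r) / sigma ** 2
                        + len(t) * math.log(sigma)
                        + 0.5 * b * b / tau ** 2 + math.log(tau))

            res = optimize.minimize_scalar(g, bounds=(-6 * tau - 1.0, 6 * tau + 1.0),
                                           method="bounded", options={"xatol": 1e-8})
            b_star = float(res.x)
            h = 1e-4
            hess = (g(b_star + h) - 2.0 * g(b_star) + g(b_star - h)) / h ** 2
            hess = max(hess, 1e-8)
            total += res.fun + 0.5 * math.log(hess) - 0.5 * math.log(2.0 * math.pi)
            total += 0.5 * len(t) * math.log(2.0 * math.pi)
        return total

    opt = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 4000})
    theta = opt.x
    phi1, phi2 = float(theta[0]), float(theta[1])
    beta = theta[2:2 + len(coef_names)]
    sigma, tau = math.exp(theta[-2]), math.exp(theta[-1])
    loglik = -float(opt.fun)
    n_params = len(theta)

    estimates = {"phi1": phi1, "phi2": phi2}
    for c, nm in enumerate(coef_names):
        estimates["phi3" if nm == "intercept" else f"phi3:{nm}"] = float(beta[c])
    hl = half_life_one_compartment(estimates["phi3"])
    return TurnoverFit(
        model_kind="one_compartment",
        estimates=estimates,
        standard_errors={k: math.nan for k in estimates},
        ci={},
        half_life_days=hl, half_life_ci=None,
        aic=-2.0 * loglik + 2.0 * n_params, loglik=loglik, n_params=n_params,
        converged=bool(opt.success), re_variance={"phi3": tau ** 2},
        n_individuals=len(groups), n_observations=n_obs,
        n_fixed_effects=len(fixed.covariates), n_random_effects=1,
        residual_sd=sigma,
        notes=("laplace marginal-likelihood estimates; AIC on the "
               "observation-level scale",),
    )


# ---------------------------------------------------------------------------
# Model selection and confidence intervals
# ---------------------------------------------------------------------------

def select_model(candidate_fits: Sequence[TurnoverFit]) -> TurnoverFit:
    """AIC selection with the "delta-AIC < 2, prefer the simplest" rule.

    Non-converged candidates are excluded.  Among candidates within 2
    AIC units of the minimum, the one with the lowest complexity rank
    (free parameters, then fixed effects, then random effects) wins.
    """
    usable = [f for f in candidate_fits if f.converged]
    if not usable:
        raise ValueError("no converged candidate fits to select from")
    aic_min = min(f.aic for f in usable)
    near = [f for f in usable if f.aic - aic_min < 2.0]
    return min(near, key=lambda f: (f.complexity_rank, f.aic))


def confidence_intervals(fit: TurnoverFit, method: str = "wald",
                         level: float = 0.95, n_boot: int = 1000,
                         seed: int | None = None) -> dict:
    """Per-parameter and half-life confidence intervals.

    ``wald``: estimate +/- z * SE on the fitting scale; the half-life
    interval is the monotone image of the phi3 interval.
    ``parametric_bootstrap``: refit ``n_boot`` datasets simulated from
    the fitted model (resampling random effects and residuals);
    percentile intervals.  A seed is mandatory for the bootstrap.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if method == "wald":
        out = {k: _wald_ci(fit.estimates[k], fit.standard_errors[k], level)
               for k in fit.estimates}
        if "phi3" in out:
            out["half_life_days"] = _half_life_ci_from_phi3(out["phi3"])
        return out
    if method != "parametric_bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    if seed is None:
        raise ValueError("parametric bootstrap requires an explicit seed")
    if fit._boot is None:
        raise ValueError("this fit does not carry bootstrap information")
    rng = np.random.default_rng(seed)
    spec = fit._boot
    draws: dict[str, list[float]] = {k: [] for k in fit.estimates}
    draws["half_life_days"] = []
    for _ in range(n_boot):
        if spec["kind"] == "individual":
            y_star = spec["fitted"] + rng.normal(0.0, spec["sigma"], size=len(spec["t"]))
            refit = fit_individual(spec["t"], y_star, model_kind=spec["model_kind"])
            if not refit.converged:
                continue
            for k in fit.estimates:
                draws[k].append(refit.estimates.get(k, math.nan))
            if refit.half_life_days is not None:
                draws["half_life_days"].append(refit.half_life_days)
        else:
            sim = _simulate_from_population_fit(spec, rng)
            refit = fit_population(sim, model_kind=spec["model_kind"],
                                   fixed=spec["fixed"], random=spec["random"])
            if not refit.converged:
                continue
            for k in fit.estimates:
                if k in refit.estimates:
                    draws[k].append(refit.estimates[k])
            if refit.half_life_days is not None:
                draws["half_life_days"].append(refit.half_life_days)
    lo_q, hi_q = 50.0 * (1.0 - level), 50.0 * (1.0 + level)
    out = {}
    for k, vals in draws.items():
        if vals:
            arr = np.asarray(vals, dtype=float)
            out[k] = (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q)))
    return out


def _simulate_from_population_fit(spec: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one dataset from a fitted population model (for bootstrap)."""
    info: pd.DataFrame = spec["info"]
    beta_by_param = spec["beta_by_param"]
    re_var = spec["re_variance"]
    sigma = spec["sigma"]
    fixed: FixedEffectsDesign = spec["fixed"]
    records = []
    for i, row in info.iterrows():
        values = {}
        for name in ("phi1", "phi2", "phi3"):
            beta, _ = beta_by_param[name]
            covs = fixed.covariates if fixed.target_parameter == name else ()
            Xi, _ = _design_matrix(info.iloc[[i]], covs)
            mu = float(Xi[0] @ beta)
            if name in re_var and re_var[name] > 0:
                mu += rng.normal(0.0, math.sqrt(re_var[name]))
            values[name] = mu
        t = spec["schedules"][str(row["individual_id"])]
        y = predict_one_compartment(
            OneCompartmentParams(values["phi1"], values["phi2"], values["phi3"]), t)
        y = np.asarray(y) + rng.normal(0.0, sigma, size=len(t))
        for ti, yi in zip(t, y):
            rec = {"individual_id": row["individual_id"], "day": float(ti),
                   "delta_permil": float(yi)}
            for c in info.columns:
                if c != "individual_id":
                    rec[c] = row[c]
            records.append(rec)
    return pd.DataFrame(records)


def residual_normality(fit: TurnoverFit) -> tuple[float, float]:
    """Lilliefors-type normality check on standardized fit residuals.

    Returns ``(statistic, p_value)`` of the Kolmogorov-Smirnov test
    with estimated mean and variance.  Purely diagnostic: the result is
    reported, never used as an automatic gate on a fit.
    """
    if fit._boot is None or fit._boot.get("kind") != "individual":
        raise ValueError("residual diagnostics are available for individual "
                         "fits with stored residual information")
    from statsmodels.stats.diagnostic import lilliefors
    resid = np.asarray(fit._boot["y"]) - np.asarray(fit._boot["fitted"])
    scale = resid.std(ddof=1)
    if scale == 0:
        return 0.0, 1.0
    stat, pval = lilliefors((resid - resid.mean()) / scale, dist="norm")
    return float(stat), float(pval)


# ---------------------------------------------------------------------------
# Equilibrium check for control groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumReport:
    """Constant-mean vs one-compartment comparison for control data.

    ``delta_aic`` is ``aic_kinetic - aic_constant`` (positive when the
    constant model is better); ``constant_selected`` applies the
    delta-AIC < 2 simplest-model rule, under which the constant model
    wins any tie.
    """

    aic_constant: float
    aic_kinetic: float
    delta_aic: float
    constant_selected: bool
    mean_delta: float
    individual_slopes: dict[str, float]


def check_equilibrium(control: pd.DataFrame | Iterable) -> EquilibriumReport:
    """Test whether never-shifted individuals are at isotopic equilibrium.

    Accepts the long-format table (``individual_id``, ``day``,
    ``delta_permil``) or an iterable of ``(days, deltas)`` trajectories.
    Fits a constant-mean model and the one-compartment model to the
    pooled observations and compares them by AIC; also reports a
    per-individual linear slope of delta against day, which should be
    near zero at equilibrium.
    """
    if isinstance(control, pd.DataFrame):
        trajectories = [(str(ind), grp["day"].to_numpy(float),
                         grp["delta_permil"].to_numpy(float))
                        for ind, grp in control.groupby("individual_id", sort=True)]
    else:
        trajectories = [(str(i), np.asarray(t, float), np.asarray(y, float))
                        for i, (t, y) in enumerate(control)]
    if not trajectories:
        raise ValueError("no control trajectories supplied")
    t_all = np.concatenate([t for _, t, _ in trajectories])
    y_all = np.concatenate([y for _, _, y in trajectories])
    if np.unique(t_all).size < 3:
        raise ValueError("equilibrium check needs >= 3 distinct time points")

    n = len(y_all)
    sse_const = float(np.sum((y_all - y_all.mean()) ** 2))
    ll_const = _gaussian_loglik(sse_const, n)
    aic_const = -2.0 * ll_const + 2.0 * 2  # mean + residual sd

    _, _, _, sse_kin, _ = _fit_onecomp_core(t_all, y_all)
    ll_kin = _gaussian_loglik(sse_kin, n)
    aic_kin = -2.0 * ll_kin + 2.0 * 4

    slopes = {}
    for ind, t, y in trajectories:
        if np.unique(t).size >= 2:
            slopes[ind] = float(np.polyfit(t, y, 1)[0])
    return EquilibriumReport(
        aic_constant=aic_const, aic_kinetic=aic_kin,
        delta_aic=aic_kin - aic_const,
        constant_selected=aic_const < aic_kin + 2.0,
        mean_delta=float(y_all.mean()),
        individual_slopes=slopes,
    )
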