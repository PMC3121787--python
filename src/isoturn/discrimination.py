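"""Diet-tissue discrimination analysis.

Discrimination (trophic enrichment) is the difference between a
consumer tissue's delta value and that of its diet for one isotope:

    Delta = delta_tissue - delta_diet   (permil)

This module computes per-record discrimination factors with an optional
C:N-based lipid normalization of delta-13C, summarizes them over any
grouping of tissue, diet, sex and age, fits the group-structured linear
mixed model (diet/tissue/sex/age fixed effects with two-way
interactions and an individual random intercept, ML for the AIC ladder
and a REML refit of the selected model), and provides the Welch
two-sample comparison used for tissues with too few records for the
full model (liver, marine vs terrestrial diet).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "DietSignature",
    "DiscriminationRecord",
    "GroupSummary",
    "MixedModelResult",
    "TwoSampleResult",
    "lipid_normalize_d13c",
    "compute_discrimination",
    "discrimination_records",
    "summarize_groups",
    "fit_discrimination_model",
    "compare_diets_two_sample",
]

GROUPING_KEYS = ("tissue", "diet", "sex", "age", "isotope")

#: Default C:N-based normalization coefficients for delta-13C
#: (delta' = delta - 3.32 + 0.99 * C:N); injectable via the ``slope``
#: and ``offset`` arguments.
_LIPID_OFFSET = -3.32
_LIPID_SLOPE = 0.99


@dataclass(frozen=True)
class DietSignature:
    """Bulk isotope signature of one experimental diet."""

    diet: str
    d13c: float
    d15n: float
    c_n_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d13c) and np.isfinite(self.d15n)):
            raise ValueError("diet delta values must be finite")

    def delta(self, isotope: str) -> float:
        if isotope == "d13C":
            return self.d13c
        if isotope == "d15N":
            return self.d15n
        raise ValueError(f"unknown isotope {isotope!r}")


@dataclass(frozen=True)
class DiscriminationRecord:
    """One individual x tissue x diet x isotope discrimination value."""

    individual_id: str
    sex: str
    age: str
    tissue: str
    diet: str
    isotope: str
    discrimination_permil: float
    lipid_corrected: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD discrimination for one group cell.

    The SD uses the n-1 denominator and is reported only for n >= 2.
    """

    keys: dict
    mean: float
    sd: float | None
    n: int


def lipid_normalize_d13c(d13c_raw: float, c_n_ratio: float | None,
                         offset: float = _LIPID_OFFSET,
                         slope: float = _LIPID_SLOPE) -> float:
    """C:N-based lipid normalization of a delta-13C value.

    Lipids are depleted in 13C relative to protein, so lipid-rich
    samples (high C:N) read low; the default arithmetic normalization
    ``delta' = delta + offset + slope * C:N`` corrects for this and is
    strictly increasing in C:N.  Passing ``c_n_ratio=None`` is
    pass-through (no correction).
    """
    if not np.isfinite(d13c_raw):
        raise ValueError("delta-13C must be finite")
    if c_n_ratio is None:
        return float(d13c_raw)
    if not np.isfinite(c_n_ratio) or c_n_ratio <= 0:
        raise ValueError(f"C:N ratio must be positive, got {c_n_ratio!r}")
    return float(d13c_raw + offset + slope * c_n_ratio)


def compute_discrimination(tissue_delta: float, diet_delta: float,
                           tissue_isotope: str | None = None,
                           diet_isotope: str | None = None) -> float:
    """Delta = delta_tissue - delta_diet for one isotope (permil)."""
    if not (np.isfinite(tissue_delta) and np.isfinite(diet_delta)):
        raise ValueError("delta values must be finite")
    if (tissue_isotope is not None and diet_isotope is not None
            and tissue_isotope != diet_isotope):
        raise ValueError(
            f"isotope mismatch: tissue {tissue_isotope!r} vs diet {diet_isotope!r}")
    return float(tissue_delta - diet_delta)


def discrimination_records(measurements: pd.DataFrame,
                           signatures: Sequence[DietSignature] | pd.DataFrame,
                           lipid_correct: bool = True) -> pd.DataFrame:
    """Turn raw tissue measurements into discrimination records.

    ``measurements`` is the long-format table (``individual_id, sex,
    age, diet, tissue, isotope, day, delta_permil`` and optionally
    ``c_n_ratio``).  delta-13C values are lipid-normalized when a C:N
    ratio is present and ``lipid_correct`` is on; records without C:N
    are left uncorrected and flagged, never imputed.
    """
    if isinstance(signatures, pd.DataFrame):
        sig_map = {(str(r["diet"]), str(r["isotope"])): float(r["delta_permil"])
                   for _, r in signatures.iterrows()}
    else:
        sig_map = {(s.diet, iso): s.delta(iso)
                   for s in signatures for iso in ("d13C", "d15N")}
    has_cn = "c_n_ratio" in measurements.columns
    records = []
    for _, row in measurements.iterrows():
        diet, isotope = str(row["diet"]), str(row["isotope"])
        if (diet, isotope) not in sig_map:
            raise KeyError(f"no diet signature for diet={diet!r}, isotope={isotope!r}")
        delta = float(row["delta_permil"])
        corrected = False
        if isotope == "d13C" and lipid_correct and has_cn and pd.notna(row["c_n_ratio"]):
            delta = lipid_normalize_d13c(delta, float(row["c_n_ratio"]))
            corrected = True
        records.append({
            "individual_id": str(row["individual_id"]),
            "sex": str(row["sex"]), "age": str(row["age"]),
            "tissue": str(row["tissue"]), "diet": diet, "isotope": isotope,
            "discrimination_permil": compute_discrimination(delta, sig_map[(diet, isotope)]),
            "lipid_corrected": corrected,
        })
    return pd.DataFrame(records)


def summarize_groups(records: pd.DataFrame,
                     grouping_keys: Sequence[str]) -> list[GroupSummary]:
    """Per-group mean, SD (n-1 denominator, n >= 2 only) and n.

    Groups are returned in deterministic (sorted) order.  An "overall"
    mean over sub-cells equals the n-weighted mean of the cell means,
    i.e. the plain mean over records.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    bad = set(grouping_keys) - set(GROUPING_KEYS)
    if bad:
        raise ValueError(f"unknown grouping keys: {sorted(bad)}; "
                         f"allowed: {GROUPING_KEYS}")
    keys = list(grouping_keys)
    out = []
    if not keys:
        vals = records["discrimination_permil"].to_numpy(float)
        out.append(GroupSummary(keys={}, mean=float(vals.mean()),
                                sd=float(vals.std(ddof=1)) if len(vals) >= 2 else None,
                                n=len(vals)))
        return out
    for key_vals, grp in records.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        vals = grp["discrimination_permil"].to_numpy(float)
        out.append(GroupSummary(
            keys=dict(zip(keys, map(str, key_vals))),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) >= 2 else None,
            n=len(vals)))
    return out


def summary_table(records: pd.DataFrame,
                  grouping_keys: Sequence[str] = ("isotope", "tissue", "diet",
                                                  "sex", "age")) -> pd.DataFrame:
    """Discrimination summary as a tidy table (mean, sd, n per cell)."""
    rows = []
    for s in summarize_groups(records, grouping_keys):
        rows.append({**s.keys, "mean": s.mean, "sd": s.sd, "n": s.n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-model analysis
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Selected linear mixed model for discrimination.

    ``aic_table`` lists every candidate (ML fit) with its AIC and
    complexity; ``params``/``ci`` come from the REML refit of the
    selected fixed-effect structure.
    """

    isotope: str
    formula: str
    fixed_terms: tuple[str, ...]
    params: pd.Series
    ci: pd.DataFrame
    re_variance: float
    aic_table: pd.DataFrame
    n_records: int
    n_individuals: int
    notes: tuple[str, ...] = ()


def _fit_mixedlm(formula: str, data: pd.DataFrame, reml: bool):
    """Fit a MixedLM, trying several optimizers; None when all fail.

    A fit with a non-finite likelihood (a degenerate optimum some
    gradient methods land on) counts as failed.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt_method in ("lbfgs", "nm", "powell"):
            try:
                fit = smf.mixedlm(formula, data, groups=data["individual_id"]).fit(
                    reml=reml, method=opt_method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if bool(fit.converged) and math.isfinite(float(fit.llf)):
                return fit
    return None


def _candidate_formulas(factors: Sequence[str]) -> list[tuple[str, ...]]:
    """Ladder from intercept-only to all mains + all two-way interactions."""
    mains = list(chain.from_iterable(
        combinations(factors, r) for r in range(len(factors) + 1)))
    ladder = [tuple(m) for m in mains]
    if len(factors) >= 2:
        full = tuple(factors) + tuple(
            f"{a}:{b}" for a, b in combinations(factors, 2))
        ladder.append(full)
    return ladder


def _complexity(terms: tuple[str, ...], data: pd.DataFrame) -> int:
    # Free fixed-effect parameters under treatment coding.
    n = 1
    levels = {f: data[f].nunique() for f in data.columns if f in GROUPING_KEYS}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            n += (levels[a] - 1) * (levels[b] - 1)
        else:
            n += levels[term] - 1
    return n


def fit_discrimination_model(records: pd.DataFrame, isotope: str,
                             factors: Sequence[str] | None = None) -> MixedModelResult:
    """Fit and select the discrimination mixed model for one isotope.

    Fixed-effect candidates run from intercept-only to all main effects
    plus all two-way interactions among the factors with at least two
    observed levels (subset of diet, tissue, sex, age); individuals are
    always a random intercept.  Candidates are fitted by maximum
    likelihood and compared by AIC with the delta-AIC < 2 /
    simplest-model rule; the winning structure is refitted by REML for
    the reported coefficients and 95% confidence intervals.
    """
    data = records[records["isotope"] == isotope].copy()
    if data.empty:
        raise ValueError(f"no records for isotope {isotope!r}")
    if data["individual_id"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 individuals")
    if factors is None:
        factors = [f for f in ("diet", "tissue", "sex", "age")
                   if f in data.columns and data[f].nunique() >= 2]
    else:
        for f in factors:
            if data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    # Rank check: every two-way cell of the fullest model must be occupied.
    for a, b in combinations(factors, 2):
        counts = data.groupby([a, b]).size()
        full_cells = data[a].nunique() * data[b].nunique()
        if len(counts) < full_cells:
            present = set(counts.index)
            missing = [(x, y) for x in data[a].unique() for y in data[b].unique()
                       if (x, y) not in present]
            raise ValueError(f"empty design cell(s) for {a} x {b}: {missing}")

    rows = []
    for terms in _candidate_formulas(factors):
        rhs = " + ".join(terms) if terms else "1"
        formula = f"discrimination_permil ~ {rhs}"
        fit = _fit_mixedlm(formula, data, reml=False)
        converged = fit is not None
        aic = float(fit.aic) if converged else math.inf
        rows.append({"terms": " + ".join(terms) if terms else "(intercept)",
                     "_terms": terms, "aic": aic,
                     "n_fixed_params": _complexity(terms, data),
                     "converged": converged})
    aic_table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    usable = aic_table[aic_table["converged"]]
    if usable.empty:
        raise ValueError("no discrimination candidate model converged")
    aic_min = usable["aic"].min()
    near = usable[usable["aic"] - aic_min < 2.0]
    best_row = near.sort_values(["n_fixed_params", "aic"]).iloc[0]
    best_terms = best_row["_terms"]

    rhs = " + ".join(best_terms) if best_terms else "1"
    formula = f"discrimination_permil ~ {rhs}"
    final = _fit_mixedlm(formula, data, reml=True)
    if final is None:
        raise ValueError(f"restricted-likelihood refit failed for {formula!r}")
    ci = final.conf_int(alpha=0.05)
    ci.columns = ["lower95", "upper95"]
    return MixedModelResult(
        isotope=isotope, formula=formula, fixed_terms=best_terms,
        params=final.params, ci=ci,
        re_variance=float(np.asarray(final.cov_re).ravel()[0]),
        aic_table=aic_table.drop(columns="_terms"),
        n_records=len(data),
        n_individuals=data["individual_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# Welch two-sample comparison (small-sample tissues)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoSampleResult:
    """Welch two-sample comparison of discrimination between two diets."""

    diet_a: str
    diet_b: str
    mean_difference: float
    ci: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int


def compare_diets_two_sample(records: pd.DataFrame, isotope: str,
                             tissue: str | None = None,
                             diets: tuple[str, str] | None = None,
                             level: float = 0.95) -> TwoSampleResult:
    """Welch comparison of mean discrimination between two diet types.

    Reports the mean difference (diet_a - diet_b), its confidence
    interval on the Welch-Satterthwaite degrees of freedom, the t
    statistic and the p value.  Each diet needs at least 2 records.
    """
    data = records[records["isotope"] == isotope]
    if tissue is not None:
        data = data[data["tissue"] == tissue]
    if diets is None:
        found = sorted(data["diet"].unique())
        if len(found) != 2:
            raise ValueError(f"expected exactly two diets, found {found}")
        diets = (found[0], found[1])
    a = data.loc[data["diet"] == diets[0], "discrimination_permil"].to_numpy(float)
    b = data.loc[data["diet"] == diets[1], "discrimination_permil"].to_numpy(float)
    for name, vals in zip(diets, (a, b)):
        if len(vals) < 2:
            raise ValueError(f"diet {name!r} has fewer than 2 records")
    t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    se = math.sqrt(va + vb)
    if se > 0:
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        df = float(len(a) + len(b) - 2)
    diff = float(a.mean() - b.mean())
    half = stats.t.ppf(0.5 * (1 + level), df) * se if se > 0 else 0.0
    return TwoSampleResult(
        diet_a=diets[0], diet_b=diets[1], mean_difference=diff,
        ci=(diff - half, diff + half),
        t_statistic=float(t_stat) if np.isfinite(t_stat) else 0.0,
        df=float(df), p_value=float(p_val) if np.isfinite(p_val) else 1.0,
        n_a=len(a), n_b=len(b))
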