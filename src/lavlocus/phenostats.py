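"""Phenotype-association statistics for the lavender/wild-type comparison.

Three computations, mirroring how dilution-mutant cohorts are analysed in
poultry genetics:

* **Growth** — per-bird monomolecular (Brody) curves
  ``W(t) = A - B * exp(-k t)`` fitted by nonlinear least squares, where A is
  the asymptotic body weight (g), B the weight range from hatch to asymptote
  (g), and k the relative growth rate (1/day).

* **Residual feed intake (RFI)** — the residual of an ordinary
  least-squares regression of feed intake on production and maintenance
  covariates, fitted separately by sex: females FI ~ BWG + MBW + EM, males
  FI ~ BWG + MBW (egg mass only exists for females).  RFI measures feed
  consumed beyond expectation; its per-sex mean is zero by construction.

* **Full vs reduced linear models** — R-squared of a model with family,
  sex and genotype versus the same model without genotype; the difference
  (delta R-squared) attributes variance to the mutation, with the nested-
  model F test as the genotype significance test.  Traits measured with a
  body-size covariate (body temperature, dissection weights) use ANCOVA by
  adding the covariate to both models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import least_squares

__all__ = [
    "GrowthParams",
    "GrowthFit",
    "ModelComparison",
    "monomolecular",
    "fit_growth",
    "compute_rfi",
    "compare_models",
    "significance_code",
]


def monomolecular(t, A, B, k):
    """Brody growth curve W(t) = A - B exp(-k t)."""
    t = np.asarray(t, dtype=float)
    return A - B * np.exp(-k * t)


@dataclass(frozen=True)
class GrowthParams:
    A: float  # asymptotic body weight, g
    B: float  # weight range hatch -> asymptote, g
    k: float  # relative growth rate, 1/day

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0 and self.k > 0):
            raise ValueError("growth parameters must be positive")


@dataclass
class GrowthFit:
    params: Optional[GrowthParams]
    converged: bool
    r_squared: float
    residual_sd: float
    message: str = ""
    best_candidate: Optional[tuple[float, float, float]] = None


def fit_growth(ages: Sequence[float], weights: Sequence[float],
               rel_tol: float = 1e-8, n_starts: int = 4) -> GrowthFit:
    """Fit the monomolecular model by multi-start nonlinear least squares.

    Requires >= 4 observations at >= 4 distinct ages.  Starts are spread
    over plausible (A, B, k) ranges derived from the data; convergence is
    declared at relative parameter change below ``rel_tol``.  Degenerate
    data (e.g. flat weights driving B to the zero boundary) yields a
    fit-failure report carrying the best candidate, never a silent wrong
    answer.
    """
    t = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.size < 4 or np.unique(t).size < 4:
        raise ValueError("need >= 4 observations at >= 4 distinct ages")

    wmax = float(w.max())
    spread = float(w.max() - w.min())
    starts = []
    for fa in (1.05, 1.3):
        for fk in (0.02, 0.08):
            starts.append((max(wmax * fa, 1.0), max(spread, 1.0) * fa, fk))
    starts = starts[:n_starts]

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: monomolecular(t, *p) - w, x0=np.array(x0),
                bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, 10.0]),
                xtol=rel_tol, ftol=rel_tol, gtol=rel_tol,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GrowthFit(None, False, np.nan, np.nan, "all starts failed")

    A, B, k = best.x
    ss_res = float(2 * best.cost)
    ss_tot = float(((w - w.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = max(t.size - 3, 1)
    sd = float(np.sqrt(ss_res / dof))

    boundary = B <= 1e-6 or k <= 1e-6 or not best.success
    if boundary:
        return GrowthFit(None, False, r2, sd,
                         "boundary or non-convergent fit", tuple(best.x))
    return GrowthFit(GrowthParams(A=float(A), B=float(B), k=float(k)),
                     True, r2, sd)


# ---------------------------------------------------------------------------
# Residual feed intake


FEMALE_COVARIATES = ("BWG", "MBW", "EM")
MALE_COVARIATES = ("BWG", "MBW")


def compute_rfi(records: pd.DataFrame, sex: str) -> tuple[pd.DataFrame, pd.Series, float]:
    """Fill RFI for one sex by OLS of FI on the sex-specific covariates.

    Returns (records with an ``RFI`` column, fitted coefficients including
    the intercept, model R-squared).  Residuals are orthogonal to every
    covariate and have mean zero up to numerical tolerance.
    """
    covs = FEMALE_COVARIATES if sex == "F" else MALE_COVARIATES
    sub = records[records["sex"] == sex].copy()
    if len(sub) < len(covs) + 2:
        raise ValueError(f"need >= {len(covs) + 2} records for sex {sex}")
    X = sm.add_constant(sub[list(covs)].astype(float))
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = sub[list(covs)].corr().abs()
        np.fill_diagonal(corr.values, 0)
        a, b = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"collinear covariates for sex {sex}: {corr.index[a]} ~ {corr.columns[b]}"
        )
    model = sm.OLS(sub["FI"].astype(float), X).fit()
    sub["RFI"] = model.resid
    return sub, model.params, float(model.rsquared)


# ---------------------------------------------------------------------------
# Full vs reduced models


@dataclass(frozen=True)
class ModelComparison:
    trait: str
    r2_full: float
    r2_reduced: float
    delta_r2: float
    f_statistic: float
    p_value: float
    significance: str

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2_reduced <= self.r2_full + 1e-9 <= 1 + 1e-9):
            raise ValueError("need 0 <= R2_reduced <= R2_full <= 1")


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def compare_models(table: pd.DataFrame, trait: str,
                   factors: Sequence[str] = ("family", "sex", "genotype"),
                   covariate: Optional[str] = None) -> ModelComparison:
    """Fit the full model (all factors, optional covariate) and the reduced
    model without genotype; report both R-squared values and the nested F
    test for the genotype factor.

    Factors are treated as categorical with treatment coding; the genotype
    test is the nested-model F comparison, which is invariant to
    sums-of-squares type.
    """
    if "genotype" not in factors:
        raise ValueError("factors must include 'genotype'")
    data = table.dropna(subset=[trait] + list(factors) + ([covariate] if covariate else []))
    for f in factors:
        counts = data[f].value_counts()
        if (counts == 0).any() or data[f].nunique() < 1:
            raise ValueError(f"empty level in factor {f}")

    def formula(fs):
        terms = [f"C({f})" for f in fs]
        if covariate:
            terms.append(covariate)
        return f"Q('{trait}') ~ " + " + ".join(terms)

    full = smf.ols(formula(factors), data=data).fit()
    reduced_factors = [f for f in factors if f != "genotype"]
    reduced = smf.ols(formula(reduced_factors), data=data).fit()

    df_num = reduced.df_resid - full.df_resid
    f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / full.df_resid)
    from scipy.stats import f as f_dist

    p = float(f_dist.sf(f_stat, df_num, full.df_resid))
    return ModelComparison(
        trait=trait,
        r2_full=float(full.rsquared),
        r2_reduced=float(reduced.rsquared),
        delta_r2=float(full.rsquared - reduced.rsquared),
        f_statistic=float(f_stat),
        p_value=p,
        significance=significance_code(p),
    )
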