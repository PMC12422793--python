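"""Phenotypic dose-response analyses of an hourly exposure.

Three complementary views of the exposure-outcome association, each as a
covariate-adjusted least-squares fit on the included (complete-case)
rows:

* :func:`fit_linear` — the exposure entered linearly (one slope in
  outcome units per hour);
* :func:`fit_categorical` — the exposure entered as indicator variables
  for whole-hour categories contrasted against a 7 h/d reference;
* :func:`fit_rcs` — a restricted (natural) cubic spline with four knots
  at the 5th/35th/65th/95th exposure percentiles, with a joint Wald test
  of the nonlinear terms.

:func:`stratify` splits a cohort by sex or by an age cutoff (median by
default) for subgroup re-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .simulate import CohortTable

__all__ = [
    "RegressionResult",
    "SplineFit",
    "DEFAULT_OBS_COVARIATES",
    "fit_linear",
    "fit_categorical",
    "rcs_basis",
    "fit_rcs",
    "stratify",
]

#: Covariate set used by the adjusted phenotypic models when none is given
#: (columns absent from the table are silently dropped).  Leukocyte count
#: is conventionally added only for the telomere-like outcome.
DEFAULT_OBS_COVARIATES = (
    "age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5",
    "education", "bmi", "smoking", "drinking", "activity",
    "cvd", "hypertension", "diabetes",
)

_THREE_LEVEL = {"smoking", "drinking", "activity"}
_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class RegressionResult:
    term_names: list[str]
    estimates: np.ndarray
    standard_errors: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.estimates,
                "se": self.standard_errors,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


@dataclass
class SplineFit:
    """Restricted-cubic-spline dose-response fit.

    ``curve`` maps exposure values to the adjusted outcome difference
    versus the reference exposure (0 at the reference by construction);
    ``curve_band`` additionally returns a 95% pointwise Wald band.
    """

    knots: np.ndarray
    term_names: list[str]
    coefficients: np.ndarray
    cov: np.ndarray
    p_nonlinearity: float
    reference: float
    n_used: int
    curve: Callable[[np.ndarray], np.ndarray]
    curve_band: Callable[[np.ndarray], pd.DataFrame]


def _expand_columns(ph: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Build covariate columns, one-hot encoding the 3-level factors."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in covariates:
        v = ph[c]
        if c in _THREE_LEVEL:
            levels = sorted(v.dropna().unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{c}[{int(lev)}]")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(ph), 0))
    return X, names


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [names[piv[i]] for i in range(len(d)) if d[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """OLS estimates and homoskedastic covariance, with a rank check."""
    _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov


def _wald_result(names, beta, cov, n_used) -> RegressionResult:
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return RegressionResult(
        list(names), beta, se, beta - _Z95 * se, beta + _Z95 * se, p, n_used
    )


def _prepare(cohort: CohortTable, outcome: str, covariates: Sequence[str] | None):
    ph = cohort.phenotypes.loc[cohort.included_mask]
    if covariates is None:
        covariates = [c for c in DEFAULT_OBS_COVARIATES if c in ph.columns]
        if outcome in ("ltl", "telomere") and "leukocyte_count" in ph.columns:
            covariates = covariates + ["leukocyte_count"]
    cols = ["reported_exposure", outcome, *covariates]
    ph = ph.dropna(subset=[c for c in cols if c in ph.columns])
    return ph, list(covariates)


def fit_linear(cohort: CohortTable, outcome: str,
               covariates: Sequence[str] | None = None) -> RegressionResult:
    """Adjusted OLS of the outcome on the exposure entered linearly.

    The first term of the result is the exposure slope (outcome units per
    additional hour).
    """
    ph, covariates = _prepare(cohort, outcome, covariates)
    if ph["reported_exposure"].nunique() < 2:
        raise ValueError("need at least 2 distinct exposure values")
    Z, znames = _expand_columns(ph, covariates)
    X = np.column_stack([ph["reported_exposure"].to_numpy(dtype=float), np.ones(len(ph)), Z])
    names = ["reported_exposure", "intercept", *znames]
    beta, cov = _ols(X, ph[outcome].to_numpy(dtype=float), names)
    return _wald_result(names, beta, cov, len(ph))


#: Whole-hour exposure categories contrasted against the reference.
#: Bounds are post-exclusion: "<5" spans 2-4 h/d and ">9" spans 10-12 h/d.
EXPOSURE_CATEGORIES = ("<5", "5", "6", "8", "9", ">9")
REFERENCE_CATEGORY = 7


def _category_of(values: np.ndarray) -> np.ndarray:
    out = np.empty(len(values), dtype=object)
    for i, v in enumerate(values):
        if v < 5:
            out[i] = "<5"
        elif v > 9:
            out[i] = ">9"
        elif v == REFERENCE_CATEGORY:
            out[i] = "ref"
        else:
            out[i] = str(int(v))
    return out


def fit_categorical(cohort: CohortTable, outcome: str,
                    covariates: Sequence[str] | None = None) -> RegressionResult:
    """Indicator-variable contrasts of each exposure category vs 7 h/d."""
    ph, covariates = _prepare(cohort, outcome, covariates)
    cat = _category_of(ph["reported_exposure"].to_numpy(dtype=float))
    if not np.any(cat == "ref"):
        raise ValueError("reference category (7 h/d) is empty")
    cols, names = [], []
    for c in EXPOSURE_CATEGORIES:
        ind = (cat == c).astype(float)
        if ind.sum() == 0:
            warnings.warn(f"exposure category {c!r} is empty; contrast omitted")
            continue
        cols.append(ind)
        names.append(f"exposure[{c}]")
    Z, znames = _expand_columns(ph, covariates)
    X = np.column_stack([*cols, np.ones(len(ph)), Z])
    all_names = [*names, "intercept", *znames]
    beta, cov = _ols(X, ph[outcome].to_numpy(dtype=float), all_names)
    return _wald_result(all_names, beta, cov, len(ph))


def rcs_basis(x, knots) -> np.ndarray:
    """Two nonlinear restricted-cubic-spline columns for four knots.

    Standard truncated-power natural-spline parameterization: with knots
    ``t1 < t2 < t3 < t4`` and ``(u)+ = max(u, 0)``,

    ``c_j(x) = [(x-t_j)+^3 - (x-t3)+^3 (t4-t_j)/(t4-t3)
                + (x-t4)+^3 (t3-t_j)/(t4-t3)] / (t4-t1)^2``  for j = 1, 2,

    which together with the raw linear term (supplied by the caller)
    spans every cubic spline that is linear below t1 and above t4.  The
    ``(t4-t1)^2`` normalization keeps the columns on the exposure scale.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.shape != (4,) or np.any(np.diff(t) <= 0):
        raise ValueError("knots must be 4 strictly increasing values")
    scale = (t[3] - t[0]) ** 2

    def plus3(u):
        return np.maximum(u, 0.0) ** 3

    cols = []
    for j in range(2):
        cj = (
            plus3(x - t[j])
            - plus3(x - t[2]) * (t[3] - t[j]) / (t[3] - t[2])
            + plus3(x - t[3]) * (t[2] - t[j]) / (t[3] - t[2])
        ) / scale
        cols.append(cj)
    return np.column_stack(cols)


def fit_rcs(
    cohort: CohortTable,
    outcome: str,
    covariates: Sequence[str] | None = None,
    knot_percentiles: Sequence[float] = (5, 35, 65, 95),
    reference: float = 7.0,
) -> SplineFit:
    """Restricted-cubic-spline dose-response with a nonlinearity test.

    Knots sit at the stated percentiles of the included exposure; the
    model is covariates + linear exposure + the two nonlinear basis
    columns; ``p_nonlinearity`` is the joint Wald chi-square (2 df) test
    that both nonlinear coefficients vanish.  The fitted curve is
    reported as the difference vs the reference exposure.
    """
    ph, covariates = _prepare(cohort, outcome, covariates)
    x = ph["reported_exposure"].to_numpy(dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct exposure values for a 4-knot spline")
    knots = np.percentile(x, knot_percentiles)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"degenerate exposure distribution: tied knots {knots.tolist()}")

    S = rcs_basis(x, knots)
    Z, znames = _expand_columns(ph, covariates)
    X = np.column_stack([x, S, np.ones(len(ph)), Z])
    names = ["exposure_linear", "spline1", "spline2", "intercept", *znames]
    y = ph[outcome].to_numpy(dtype=float)
    beta, cov = _ols(X, y, names)

    b_nl = beta[1:3]
    c_nl = cov[1:3, 1:3]
    w = float(b_nl @ np.linalg.solve(c_nl, b_nl))
    p_nonlin = float(stats.chi2.sf(w, df=2))

    b_exp = beta[:3]
    cov_exp = cov[:3, :3]

    def _contrast(grid: np.ndarray) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        ref_row = np.concatenate([[reference], rcs_basis(reference, knots).ravel()])
        rows = np.column_stack([grid, rcs_basis(grid, knots)])
        return rows - ref_row

    def curve(grid):
        return _contrast(grid) @ b_exp

    def curve_band(grid):
        C = _contrast(grid)
        fit = C @ b_exp
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, cov_exp, C))
        g = np.atleast_1d(np.asarray(grid, dtype=float))
        return pd.DataFrame(
            {"exposure": g, "difference": fit,
             "ci_low": fit - _Z95 * se, "ci_high": fit + _Z95 * se}
        )

    return SplineFit(knots, names, beta, cov, p_nonlin, reference, len(ph), curve, curve_band)


def stratify(cohort: CohortTable, by: str, age_cutoff: float | None = None) -> dict[str, CohortTable]:
    """Partition the included rows by sex or by an age cutoff.

    ``by="sex"`` returns ``{"female", "male"}`` sub-cohorts (coding
    0 = female).  ``by="age"`` splits at ``age_cutoff`` (default the
    within-sample median, 58 years in the motivating cohort) into
    ``{"age_lt_<c>", "age_ge_<c>"}`` with the cutoff in the upper group.
    """
    inc = cohort.included()
    ph = inc.phenotypes
    if by == "sex":
        groups = {"female": ph["sex"] == 0, "male": ph["sex"] == 1}
    elif by == "age":
        cutoff = float(np.median(ph["age"])) if age_cutoff is None else float(age_cutoff)
        groups = {
            f"age_lt_{cutoff:g}": ph["age"] < cutoff,
            f"age_ge_{cutoff:g}": ph["age"] >= cutoff,
        }
    else:
        raise ValueError("stratifier must be 'sex' or 'age'")
    out = {}
    for label, mask in groups.items():
        if int(mask.sum()) == 0:
            warnings.warn(f"stratum {label!r} is empty")
        out[label] = inc.subset(mask.to_numpy())
    return out
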