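"""Two-stage (2SLS) instrumental-variable estimation with an allele score.

One-sample individual-level Mendelian randomization: stage 1 regresses
the observed exposure on the genetic risk score plus covariates; stage 2
regresses the outcome on the stage-1 fitted exposure plus the same
covariates.  The coefficient on fitted exposure estimates the average
causal effect per unit of genetically-predicted exposure.  Standard
errors use the structural residual (outcome minus the causal effect of
the *observed* exposure), the proper 2SLS variance, not the naive
stage-2 OLS variance; a heteroskedasticity-robust sandwich is available.

The default covariate set is the genetic-analysis list — age, sex,
age^2, age*sex, age^2*sex, the top five ancestry PCs, and the genotyping
array indicator — with the derived age terms constructed internally from
the raw ``age`` and ``sex`` columns so callers cannot supply
inconsistent versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observational import _expand_columns, _check_rank
from .simulate import CohortTable

__all__ = [
    "MrEstimate",
    "DEFAULT_MR_COVARIATES",
    "two_stage_estimate",
    "sensitivity_estimates",
    "mr_design",
]

DEFAULT_MR_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5", "array")

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MrEstimate:
    """Causal-effect estimate per 1-unit increase in predicted exposure."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    first_stage_f: float
    label: str = "two-stage"

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else float("inf")


def mr_design(ph: pd.DataFrame, covariates: Sequence[str] | None = None,
              extra: Sequence[str] = ()) -> tuple[np.ndarray, list[str]]:
    """Covariate design (with intercept) for the two-stage regressions.

    When both ``age`` and ``sex`` are among the covariates, the derived
    terms age^2, age*sex and age^2*sex are appended automatically (age is
    mean-centred before powers are formed, a conditioning choice that
    leaves the exposure coefficient unchanged).
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_MR_COVARIATES if c in ph.columns]
    covariates = list(covariates) + [c for c in extra if c not in covariates]
    Z, names = _expand_columns(ph, covariates)
    blocks = [np.ones((len(ph), 1)), Z]
    names = ["intercept", *names]
    if "age" in covariates and "sex" in covariates:
        age = ph["age"].to_numpy(dtype=float)
        sex = ph["sex"].to_numpy(dtype=float)
        a = age - age.mean()
        blocks.append(np.column_stack([a * a, a * sex, a * a * sex]))
        names += ["age_sq", "age_x_sex", "age_sq_x_sex"]
    return np.hstack(blocks), names


def _two_stage_core(
    y: np.ndarray,
    x: np.ndarray,
    score: np.ndarray,
    Z: np.ndarray,
    robust: bool = False,
) -> tuple[float, float, float, int]:
    """Fast 2SLS on raw arrays; ``Z`` must include the intercept.

    Returns (beta, se, first_stage_partial_f, n).
    """
    n = len(y)
    W = np.column_stack([score, Z])
    if n < W.shape[1] + 2:
        raise ValueError("too few observations for the two-stage model")

    # stage 1 + partial F of the score given covariates
    g1, _, _, _ = np.linalg.lstsq(W, x, rcond=None)
    xhat = W @ g1
    rss1 = float(np.sum((x - xhat) ** 2))
    g0, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    rss0 = float(np.sum((x - Z @ g0) ** 2))
    dof1 = n - W.shape[1]
    if rss0 - rss1 <= 1e-12 * max(rss0, 1.0):
        raise ValueError("degenerate first stage: score adds no exposure variance")
    f1 = float("inf") if rss1 == 0 else (rss0 - rss1) / (rss1 / dof1)

    Xh = np.column_stack([xhat, Z])
    Xo = np.column_stack([x, Z])
    bhat, _, _, _ = np.linalg.lstsq(Xh, y, rcond=None)

    # structural residuals use the observed exposure
    e = y - Xo @ bhat
    k = Xh.shape[1]
    A = np.linalg.inv(Xh.T @ Xh)
    if robust:
        meat = Xh.T @ (Xh * (e * e)[:, None])
        V = A @ meat @ A
    else:
        sigma2 = float(e @ e) / (n - k)
        V = sigma2 * A
    return float(bhat[0]), float(np.sqrt(V[0, 0])), float(f1), n


def two_stage_estimate(
    cohort: CohortTable,
    outcome: str,
    score: np.ndarray | pd.Series | str = "grs",
    covariates: Sequence[str] | None = None,
    extra_covariates: Sequence[str] = (),
    robust: bool = False,
    label: str = "two-stage",
) -> MrEstimate:
    """Average causal effect of the exposure via the two-stage method.

    ``score`` may be a column name in the phenotype table or a vector
    aligned with the full cohort index.  Only included, complete-case
    rows enter the fit.  ``extra_covariates`` appends columns (e.g. the
    observational confounder list) to the default genetic covariate set.
    """
    ph_all = cohort.phenotypes
    if isinstance(score, str):
        s_all = ph_all[score].to_numpy(dtype=float)
    else:
        s_all = np.asarray(score, dtype=float)
        if len(s_all) != len(ph_all):
            raise ValueError("score vector must align with the full cohort")

    if covariates is None:
        covariates = [c for c in DEFAULT_MR_COVARIATES if c in ph_all.columns]
    needed = ["reported_exposure", outcome, *covariates, *extra_covariates]
    mask = cohort.included_mask.to_numpy() & ~ph_all[needed].isna().any(axis=1).to_numpy()
    mask &= np.isfinite(s_all)
    ph = ph_all.loc[mask]

    Z, names = mr_design(ph, covariates, extra=extra_covariates)
    _check_rank(Z, names)
    beta, se, f1, n = _two_stage_core(
        ph[outcome].to_numpy(dtype=float),
        ph["reported_exposure"].to_numpy(dtype=float),
        s_all[mask],
        Z,
        robust=robust,
    )
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return MrEstimate(beta, se, beta - _Z95 * se, beta + _Z95 * se, p, n, f1, label)


@dataclass
class SensitivityReport:
    primary: MrEstimate
    with_extra_covariates: MrEstimate
    reduced_score: MrEstimate
    flags: list[str]


def sensitivity_estimates(
    cohort: CohortTable,
    outcome: str,
    score_full,
    score_reduced,
    extra_covariates: Sequence[str] = (),
    covariates: Sequence[str] | None = None,
) -> SensitivityReport:
    """Re-estimate with extra confounders and with a pleiotropy-pruned score.

    Returns the primary estimate, the extra-covariate estimate and the
    reduced-score estimate, with consistency flags raised when a
    sensitivity estimate changes sign or its 95% CI fails to overlap the
    primary CI.
    """
    primary = two_stage_estimate(cohort, outcome, score_full, covariates, label="primary")
    with_cov = two_stage_estimate(
        cohort, outcome, score_full, covariates,
        extra_covariates=extra_covariates, label="extra-covariates",
    )
    reduced = two_stage_estimate(cohort, outcome, score_reduced, covariates, label="reduced-score")
    flags: list[str] = []
    for est in (with_cov, reduced):
        if np.sign(est.beta) != np.sign(primary.beta) and primary.p_value < 0.05:
            flags.append(f"{est.label}: sign change vs primary")
        if est.ci_low > primary.ci_high or est.ci_high < primary.ci_low:
            flags.append(f"{est.label}: CI does not overlap primary CI")
    if flags:
        warnings.warn("sensitivity inconsistency: " + "; ".join(flags))
    return SensitivityReport(primary, with_cov, reduced, flags)
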