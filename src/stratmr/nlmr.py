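"""Nonlinear Mendelian randomization via doubly-ranked stratification.

The population is sorted by the genetic risk score into small pre-strata
(default 50 individuals), then re-ranked by observed exposure within
each pre-stratum; taking the j-th exposure slice from every pre-stratum
yields final strata that are (by construction) uncorrelated with the
score while their mean observed exposure rises monotonically.  A
two-stage IV estimate inside each stratum is a localized average causal
effect (LACE) — an estimate of the causal dose-response derivative
``h'(x)`` near that stratum's exposure level.

Because an hourly-coarsened exposure produces heavy ties, ranking uses a
single seeded random permutation as the tie-breaker, and estimates are
stabilized by bootstrap averaging: a small number of individuals
(default 12) is removed at random, stratification and estimation are
repeated (default 100 times), and the per-stratum estimates are pooled
with Rubin's rules.  Nonlinearity is assessed two ways: an
inverse-variance-weighted meta-regression of the LACE estimates on the
stratum mean exposures (the primary test), and a fractional-polynomial
fit of the derivative with a likelihood-ratio test against a constant
derivative (a linear causal effect).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr import MrEstimate, mr_design, two_stage_estimate, _two_stage_core
from .observational import _check_rank
from .simulate import CohortTable

__all__ = [
    "StratumResult",
    "FpFit",
    "NlmrConfig",
    "NlmrResult",
    "doubly_ranked_strata",
    "stratum_estimates",
    "rubin_rules",
    "bootstrap_average",
    "trend_meta_regression",
    "fractional_polynomial_fit",
    "heterogeneity_q",
    "run_nlmr",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class StratumResult:
    """One exposure stratum's localized average causal effect."""

    stratum_index: int
    n: int
    mean_exposure: float
    lace_beta: float
    lace_se: float
    ci_low: float
    ci_high: float

    @property
    def usable(self) -> bool:
        return math.isfinite(self.lace_beta) and self.lace_se > 0


@dataclass
class FpFit:
    """Fractional-polynomial fit of the dose-response derivative.

    ``powers`` is empty when the constant-derivative (linear-effect)
    model maximizes the likelihood; ``curve`` is the analytic integral of
    the fitted derivative, anchored to 0 at the reference exposure.
    """

    powers: tuple[float, ...]
    coefficients: tuple[float, ...]
    loglik: float
    p_nonlinearity: float
    reference: float
    curve: Callable[[np.ndarray], np.ndarray]


@dataclass
class NlmrConfig:
    n_strata: int = 5
    prestratum_size: int = 50
    n_remove: int = 12
    reps: int = 100
    seed: int = 0
    power_set: tuple[float, ...] = FP_POWERS
    reference_exposure: float = 7.0
    fp_degree: int = 1
    robust: bool = False


@dataclass
class NlmrResult:
    strata: list[StratumResult]
    trend_slope: float
    trend_se: float
    p_nonlinearity_trend: float
    fp: FpFit
    overall: MrEstimate
    bootstrap_reps: int
    removed_per_rep: int
    config: NlmrConfig = field(repr=False, default_factory=NlmrConfig)

    def strata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": [s.stratum_index for s in self.strata],
                "n": [s.n for s in self.strata],
                "mean_exposure": [s.mean_exposure for s in self.strata],
                "beta": [s.lace_beta for s in self.strata],
                "se": [s.lace_se for s in self.strata],
                "ci_low": [s.ci_low for s in self.strata],
                "ci_high": [s.ci_high for s in self.strata],
            }
        )

    def to_dict(self) -> dict:
        return {
            "overall": {
                "beta": self.overall.beta, "se": self.overall.se,
                "ci_low": self.overall.ci_low, "ci_high": self.overall.ci_high,
                "p": self.overall.p_value, "n": self.overall.n_used,
                "first_stage_f": self.overall.first_stage_f,
            },
            "strata": self.strata_frame().to_dict(orient="records"),
            "trend": {
                "slope": self.trend_slope, "se": self.trend_se,
                "p_nonlinearity": self.p_nonlinearity_trend,
            },
            "fractional_polynomial": {
                "powers": list(self.fp.powers),
                "coefficients": list(self.fp.coefficients),
                "p_nonlinearity": self.fp.p_nonlinearity,
            },
            "bootstrap": {"reps": self.bootstrap_reps, "removed_per_rep": self.removed_per_rep},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# stratification

def _doubly_ranked(score: np.ndarray, exposure: np.ndarray, n_strata: int,
                   prestratum_size: int, rng: np.random.Generator) -> np.ndarray:
    n = len(score)
    priority = np.empty(n)
    priority[rng.permutation(n)] = np.arange(n)  # one seeded tie-break shared by both sorts
    order = np.lexsort((priority, score))
    m = prestratum_size // n_strata
    assignment = np.zeros(n, dtype=np.int64)
    n_full = n // prestratum_size
    for b in range(n_full):
        block = order[b * prestratum_size:(b + 1) * prestratum_size]
        ranked = block[np.lexsort((priority[block], exposure[block]))]
        for k in range(n_strata):
            assignment[ranked[k * m:(k + 1) * m]] = k + 1
    rem = n - n_full * prestratum_size
    if rem:
        block = order[n_full * prestratum_size:]
        ranked = block[np.lexsort((priority[block], exposure[block]))]
        # incomplete final pre-stratum: assign by scaled exposure rank
        ranks = np.arange(1, rem + 1)
        assignment[ranked] = np.ceil(ranks * n_strata / rem).astype(np.int64)
    return assignment


def doubly_ranked_strata(score, exposure, n_strata: int = 5, prestratum_size: int = 50,
                         seed: int = 0) -> np.ndarray:
    """Assign every individual to one of ``n_strata`` exposure strata.

    Individuals are sorted by ``score`` (ties broken by a seeded random
    permutation) into consecutive pre-strata of ``prestratum_size``, then
    ranked by ``exposure`` within each pre-stratum (same tie-breaker);
    the lowest ``prestratum_size / n_strata`` exposure ranks of every
    pre-stratum form stratum 1, and so on.  A final incomplete
    pre-stratum (when N is not divisible by ``prestratum_size``)
    distributes its members by scaled exposure rank, so every individual
    receives exactly one label in 1..n_strata.
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if score.shape != exposure.shape or score.ndim != 1:
        raise ValueError("score and exposure must be equal-length vectors")
    if prestratum_size % n_strata != 0:
        raise ValueError(
            f"prestratum_size ({prestratum_size}) must be divisible by n_strata ({n_strata})"
        )
    if len(score) < prestratum_size:
        raise ValueError("fewer individuals than one pre-stratum")
    return _doubly_ranked(score, exposure, n_strata, prestratum_size,
                          np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# per-stratum estimation

def _extract_arrays(cohort: CohortTable, outcome: str, score, covariates):
    ph_all = cohort.phenotypes
    if isinstance(score, str):
        s_all = ph_all[score].to_numpy(dtype=float)
    else:
        s_all = np.asarray(score, dtype=float)
    if covariates is None:
        from .mr import DEFAULT_MR_COVARIATES
        covariates = [c for c in DEFAULT_MR_COVARIATES if c in ph_all.columns]
    needed = ["reported_exposure", outcome, *covariates]
    mask = cohort.included_mask.to_numpy() & ~ph_all[needed].isna().any(axis=1).to_numpy()
    mask &= np.isfinite(s_all)
    ph = ph_all.loc[mask]
    Z, names = mr_design(ph, covariates)
    _check_rank(Z, names)
    y = ph[outcome].to_numpy(dtype=float)
    x = ph["reported_exposure"].to_numpy(dtype=float)
    return y, x, s_all[mask], Z, mask


def _lace_for_assignment(y, x, s, Z, assignment, n_strata, robust):
    """Per-stratum (beta, var, mean_exposure, n); NaNs where degenerate."""
    betas = np.full(n_strata, np.nan)
    variances = np.full(n_strata, np.nan)
    mean_exp = np.full(n_strata, np.nan)
    ns = np.zeros(n_strata, dtype=int)
    for k in range(1, n_strata + 1):
        idx = assignment == k
        ns[k - 1] = int(idx.sum())
        if ns[k - 1] == 0:
            continue
        mean_exp[k - 1] = float(x[idx].mean())
        try:
            b, se, _, _ = _two_stage_core(y[idx], x[idx], s[idx], Z[idx], robust=robust)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"stratum {k}: estimate unavailable ({exc})")
            continue
        betas[k - 1] = b
        variances[k - 1] = se * se
    return betas, variances, mean_exp, ns


def stratum_estimates(
    cohort: CohortTable,
    outcome: str,
    score,
    covariates: Sequence[str] | None,
    assignment: np.ndarray,
    robust: bool = False,
) -> list[StratumResult]:
    """Two-stage LACE estimate within each stratum of ``assignment``.

    ``assignment`` is aligned with the rows that enter the analysis (the
    included complete-case rows, in cohort order), with labels 1..K; the
    first stage is re-fit within each stratum.
    """
    y, x, s, Z, _ = _extract_arrays(cohort, outcome, score, covariates)
    assignment = np.asarray(assignment)
    if len(assignment) != len(y):
        raise ValueError("assignment does not cover the analysis rows")
    K = int(assignment.max())
    betas, variances, mean_exp, ns = _lace_for_assignment(y, x, s, Z, assignment, K, robust)
    out = []
    for k in range(K):
        se = float(np.sqrt(variances[k])) if np.isfinite(variances[k]) else float("nan")
        b = float(betas[k])
        out.append(StratumResult(k + 1, int(ns[k]), float(mean_exp[k]), b, se,
                                 b - _Z95 * se, b + _Z95 * se))
    return out


# ---------------------------------------------------------------------------
# pooling and tests

def rubin_rules(estimates, variances) -> tuple[float, float]:
    """Pool repeated estimates: (mean, within + (1 + 1/B) * between).

    ``within`` is the mean of the supplied variances and ``between`` the
    sample variance of the estimates (0 when B = 1).
    """
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape or q.ndim != 1 or len(q) < 1:
        raise ValueError("estimates and variances must be equal-length non-empty vectors")
    if np.any(v < 0):
        raise ValueError("negative variance input")
    B = len(q)
    pooled = float(q.mean())
    within = float(v.mean())
    between = float(q.var(ddof=1)) if B > 1 else 0.0
    return pooled, within + (1.0 + 1.0 / B) * between


def bootstrap_average(
    cohort: CohortTable,
    outcome: str,
    score="grs",
    covariates: Sequence[str] | None = None,
    n_strata: int = 5,
    prestratum_size: int = 50,
    n_remove: int = 12,
    reps: int = 100,
    seed: int = 0,
    robust: bool = False,
) -> list[StratumResult]:
    """Bootstrap-averaged doubly-ranked stratum estimates.

    Each replicate removes ``n_remove`` individuals uniformly at random,
    re-runs the doubly-ranked stratification (fresh seeded tie-break) and
    the within-stratum two-stage estimates; per-stratum results are
    pooled across replicates with Rubin's rules.  Replicates whose
    stratification fails outright are dropped with a warning; more than
    20% dropped replicates is an error.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    y, x, s, Z, _ = _extract_arrays(cohort, outcome, score, covariates)
    n = len(y)
    if n_remove >= n:
        raise ValueError("n_remove must be smaller than the analysis sample")
    if prestratum_size % n_strata != 0:
        raise ValueError(
            f"prestratum_size ({prestratum_size}) must be divisible by n_strata ({n_strata})"
        )

    child = np.random.SeedSequence(seed).spawn(reps)
    betas = np.full((reps, n_strata), np.nan)
    variances = np.full((reps, n_strata), np.nan)
    mean_exp = np.full((reps, n_strata), np.nan)
    ns = np.zeros((reps, n_strata))
    dropped = 0
    for r in range(reps):
        # with n_remove = 0 there is nothing to average over: every replicate
        # reuses the parent seed and reproduces the single-shot stratification
        rng = np.random.default_rng(child[r] if n_remove else seed)
        keep = np.ones(n, dtype=bool)
        if n_remove:
            keep[rng.choice(n, size=n_remove, replace=False)] = False
        try:
            assignment = _doubly_ranked(s[keep], x[keep], n_strata, prestratum_size, rng)
            b, v, me, nk = _lace_for_assignment(y[keep], x[keep], s[keep], Z[keep],
                                                assignment, n_strata, robust)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"bootstrap replicate {r} dropped: {exc}")
            dropped += 1
            continue
        betas[r], variances[r], mean_exp[r], ns[r] = b, v, me, nk
    if dropped > 0.2 * reps:
        raise RuntimeError(f"{dropped}/{reps} bootstrap replicates failed")

    out = []
    for k in range(n_strata):
        ok = np.isfinite(betas[:, k]) & np.isfinite(variances[:, k])
        if not ok.any():
            out.append(StratumResult(k + 1, 0, float("nan"), float("nan"),
                                     float("nan"), float("nan"), float("nan")))
            continue
        pooled, total = rubin_rules(betas[ok, k], variances[ok, k])
        se = float(np.sqrt(total))
        out.append(
            StratumResult(
                k + 1,
                int(round(ns[ok, k].mean())),
                float(np.nanmean(mean_exp[ok, k])),
                pooled, se, pooled - _Z95 * se, pooled + _Z95 * se,
            )
        )
    return out


def trend_meta_regression(strata: Sequence[StratumResult]) -> tuple[float, float, float]:
    """Inverse-variance-weighted meta-regression of LACE on mean exposure.

    Fixed-effect weighted least squares of the stratum estimates on the
    stratum mean exposures with weights 1/se^2 and known-variance
    (meta-analytic) standard errors; the two-sided normal p-value on the
    slope is the primary nonlinearity test.
    """
    use = [s for s in strata if s.usable and math.isfinite(s.mean_exposure)]
    if len(use) < 3:
        raise ValueError(f"need >= 3 usable strata, got {len(use)}")
    xs = np.array([s.mean_exposure for s in use])
    ys = np.array([s.lace_beta for s in use])
    w = np.array([1.0 / s.lace_se**2 for s in use])
    X = np.column_stack([np.ones(len(xs)), xs])
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx)
    coef = cov @ (X.T @ (w * ys))
    slope = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.norm.sf(abs(slope) / se)) if se > 0 else float("nan")
    return slope, se, p


def heterogeneity_q(strata: Sequence[StratumResult]) -> tuple[float, float]:
    """Cochran's Q for homogeneity of the stratum estimates."""
    use = [s for s in strata if s.usable]
    if len(use) < 2:
        raise ValueError("need >= 2 usable strata")
    b = np.array([s.lace_beta for s in use])
    w = np.array([1.0 / s.lace_se**2 for s in use])
    pooled = float((w * b).sum() / w.sum())
    q = float((w * (b - pooled) ** 2).sum())
    return q, float(stats.chi2.sf(q, df=len(use) - 1))


# ---------------------------------------------------------------------------
# fractional polynomials on the derivative scale

def _fp_term(x: np.ndarray, p: float) -> np.ndarray:
    return np.log(x) if p == 0 else x**p


def _fp_antideriv(p: float) -> Callable[[np.ndarray], np.ndarray]:
    if p == 0:  # derivative term ln(x)
        return lambda x: x * np.log(x) - x
    if p == -1:
        return lambda x: np.log(x)
    return lambda x: x ** (p + 1) / (p + 1)


def _wls_loglik(G: np.ndarray, b: np.ndarray, w: np.ndarray, se2: np.ndarray):
    """Known-variance Gaussian WLS of b on columns G; returns (theta, ll)."""
    A = G.T @ (G * w[:, None])
    theta = np.linalg.solve(A, G.T @ (w * b))
    resid = b - G @ theta
    ll = float(-0.5 * np.sum(np.log(2 * np.pi * se2) + w * resid**2))
    return theta, ll


def fractional_polynomial_fit(
    strata: Sequence[StratumResult],
    reference: float = 7.0,
    powers: Sequence[float] = FP_POWERS,
    degree: int = 1,
) -> FpFit:
    """Fit the causal dose-response derivative as a fractional polynomial.

    The stratum LACE estimates are treated as noisy observations of
    ``h'(x)`` at the stratum mean exposures.  A degree-1 model
    ``h'(x) = theta * x^p`` (``x^0`` read as ln x) is fitted by weighted
    Gaussian likelihood for every power in ``powers``; with
    ``degree = 2``, pairs of distinct powers are also searched.  The
    constant-derivative model ``h'(x) = c`` (a linear causal effect) is a
    candidate too, and the reported curve integrates whichever model
    maximizes the likelihood, anchored to 0 at ``reference``.
    ``p_nonlinearity`` is a likelihood-ratio chi-square of the best
    power model against the constant model with ``2*degree - 1`` df
    (each selected power counts one df).
    """
    use = [s for s in strata if s.usable and math.isfinite(s.mean_exposure)]
    if len(use) < 3:
        raise ValueError(f"need >= 3 usable strata, got {len(use)}")
    xs = np.array([s.mean_exposure for s in use])
    if np.any(xs <= 0):
        raise ValueError("mean exposures must be positive for fractional powers")
    b = np.array([s.lace_beta for s in use])
    se2 = np.array([s.lace_se**2 for s in use])
    w = 1.0 / se2

    theta_c, ll_const = _wls_loglik(np.ones((len(xs), 1)), b, w, se2)

    candidates: list[tuple[tuple[float, ...], np.ndarray, float]] = []
    for p in powers:
        th, ll = _wls_loglik(_fp_term(xs, p)[:, None], b, w, se2)
        candidates.append(((float(p),), th, ll))
    if degree >= 2:
        plist = list(powers)
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                G = np.column_stack([_fp_term(xs, plist[i]), _fp_term(xs, plist[j])])
                try:
                    th, ll = _wls_loglik(G, b, w, se2)
                except np.linalg.LinAlgError:
                    continue
                candidates.append(((float(plist[i]), float(plist[j])), th, ll))

    best_powers, best_theta, ll_best = max(candidates, key=lambda c: c[2])
    lr = max(0.0, 2.0 * (ll_best - ll_const))
    p_nonlin = float(stats.chi2.sf(lr, df=2 * degree - 1))

    if ll_const >= ll_best:
        c = float(theta_c[0])

        def curve(x):
            return c * (np.asarray(x, dtype=float) - reference)

        return FpFit((), (c,), ll_const, p_nonlin, reference, curve)

    antids = [_fp_antideriv(p) for p in best_powers]
    coefs = tuple(float(t) for t in best_theta)

    def curve(x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for t, F in zip(coefs, antids):
            out = out + t * (F(x) - F(reference))
        return out

    return FpFit(tuple(best_powers), coefs, ll_best, p_nonlin, reference, curve)


# ---------------------------------------------------------------------------
# orchestration

def run_nlmr(
    cohort: CohortTable,
    outcome: str,
    score="grs",
    covariates: Sequence[str] | None = None,
    config: NlmrConfig | None = None,
) -> NlmrResult:
    """Full nonlinear-MR analysis of one outcome.

    Runs the overall two-stage estimate, bootstrap-averaged doubly-ranked
    stratification, the trend meta-regression, and the
    fractional-polynomial fit, deterministically for a given config seed.
    """
    cfg = config or NlmrConfig()
    overall = two_stage_estimate(cohort, outcome, score, covariates, robust=cfg.robust)
    strata = bootstrap_average(
        cohort, outcome, score, covariates,
        n_strata=cfg.n_strata, prestratum_size=cfg.prestratum_size,
        n_remove=cfg.n_remove, reps=cfg.reps, seed=cfg.seed, robust=cfg.robust,
    )
    slope, se, p_trend = trend_meta_regression(strata)
    fp = fractional_polynomial_fit(
        strata, reference=cfg.reference_exposure, powers=cfg.power_set, degree=cfg.fp_degree
    )
    return NlmrResult(strata, slope, se, p_trend, fp, overall, cfg.reps, cfg.n_remove, cfg)
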