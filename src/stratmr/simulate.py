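"""Synthetic cohort generation for genetic dose-response studies.

This module builds individual-level cohorts with the statistical structure
that one-sample Mendelian randomization analyses of a self-reported,
hourly-coarsened exposure assume:

* additive genotype dosages at independent biallelic loci drawn under
  Hardy-Weinberg equilibrium,
* a latent continuous exposure (hours/day) driven by the genetic score,
  a shared latent confounder ``U`` and Gaussian noise,
* continuous outcomes (years of biological-age acceleration, or SD units
  for a telomere-like trait) generated from a configurable causal
  dose-response function ``h(x)`` plus confounding and noise,
* an observed exposure obtained by coarsening the latent exposure to
  whole hours, with range-based exclusion of extreme responses.

The generated tables use the same on-disk contract (phenotype TSV, dosage
TSV, variant-info TSV) that the downstream analysis modules consume, so a
real cohort in the same format can be substituted for a simulated one.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "DoseResponseSpec",
    "CohortTable",
    "ExclusionCounts",
    "simulate_variants",
    "generate_cohort",
    "coarsen_exposure",
    "apply_exclusions",
    "write_cohort",
    "read_cohort",
    "read_variants",
]

_VALID_ALLELES = frozenset("ACGT")

#: Default observed-exposure inclusion range (hours/day); values strictly
#: below the lower bound or strictly above the upper bound are excluded,
#: the bounds themselves are retained.
EXPOSURE_RANGE = (2, 12)

#: Default number of instrument loci emulated by :func:`simulate_variants`.
DEFAULT_N_VARIANTS = 83


@dataclass(frozen=True)
class VariantRecord:
    """One instrument SNP.

    Parameters
    ----------
    variant_id : str
        Unique identifier (rs-style or synthetic).
    effect_allele : str
        Allele whose dosage is counted; one of A/C/G/T.
    other_allele : str
        The alternative allele.
    gwas_beta : float
        Published GWAS effect on the exposure, in hours of exposure per
        copy of the effect allele.  Its sign orients the allele score.
    allele_freq : float
        Effect-allele frequency in [0, 1].
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    gwas_beta: float
    allele_freq: float

    def __post_init__(self) -> None:
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be one of A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if ea == oa:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError(f"{self.variant_id}: allele_freq {self.allele_freq} outside [0, 1]")
        if not math.isfinite(self.gwas_beta):
            raise ValueError(f"{self.variant_id}: non-finite gwas_beta")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)


@dataclass(frozen=True)
class DoseResponseSpec:
    """The true causal dose-response function h(x) plus nuisance structure.

    ``shape`` selects the functional form of h:

    ``linear``
        ``h(x) = slope * x`` (params: ``slope``).
    ``threshold``
        continuous piecewise-linear with a single breakpoint,
        ``h(x) = left_slope*(min(x, b) - b) + right_slope*(max(x, b) - b)``
        (params: ``breakpoint``, ``left_slope``, ``right_slope``).
    ``ushape``
        parabola ``h(x) = curvature * (x - vertex)**2``
        (params: ``vertex``, ``curvature``).
    ``piecewise``
        continuous piecewise-linear through arbitrary knots
        (params: ``knots`` ascending list, ``slopes`` of length
        ``len(knots) + 1``; anchored so h(knots[0]) = 0).

    The remaining fields describe the data-generating nuisance structure:
    a single standard-normal confounder ``U`` loads on the exposure with
    weight ``confounder_effect_on_exposure`` and on the outcome with
    weight ``confounder_effect_on_outcome``; independent Gaussian noise
    is added to each.  ``exposure_mean`` sets the population mean of the
    latent exposure (the generator solves for the intercept given the
    variant panel).  ``genetic_effect_sd`` switches on per-individual
    lognormal (mean-one) multipliers on the genetic effects, the
    effect-heterogeneity scenario that motivates doubly-ranked
    stratification; it is off (0) by default.

    Defaults emulate a biobank-scale sleep-duration study: exposure
    mean 7.16 h/d with SD ~1.1, an age-acceleration outcome with residual
    SD 4.0 years, and moderate shared confounding (0.5 on each side).
    """

    shape: str = "linear"
    params: Mapping[str, object] = field(default_factory=lambda: {"slope": -0.3})
    confounder_effect_on_exposure: float = 0.5
    confounder_effect_on_outcome: float = 0.5
    exposure_noise_sd: float = 0.9
    outcome_noise_sd: float = 4.0
    exposure_mean: float = 7.16
    genetic_effect_sd: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        scalars = [
            self.confounder_effect_on_exposure,
            self.confounder_effect_on_outcome,
            self.exposure_noise_sd,
            self.outcome_noise_sd,
            self.exposure_mean,
            self.genetic_effect_sd,
            self.missing_rate,
        ]
        for v in self.params.values():
            scalars.extend(np.atleast_1d(np.asarray(v, dtype=float)).tolist())
        for v in scalars:
            if not math.isfinite(float(v)):
                raise ValueError("non-finite parameter in DoseResponseSpec")
        if self.exposure_noise_sd < 0 or self.outcome_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.shape not in ("linear", "threshold", "ushape", "piecewise"):
            raise ValueError(f"unknown dose-response shape {self.shape!r}")
        self.h  # validate shape params eagerly

    @property
    def h(self) -> Callable[[np.ndarray], np.ndarray]:
        """Vectorized causal function h(x)."""
        p = self.params
        if self.shape == "linear":
            slope = float(p["slope"])
            return lambda x: slope * np.asarray(x, dtype=float)
        if self.shape == "threshold":
            b = float(p["breakpoint"])
            ls, rs = float(p["left_slope"]), float(p["right_slope"])
            return lambda x: (
                ls * (np.minimum(np.asarray(x, dtype=float), b) - b)
                + rs * (np.maximum(np.asarray(x, dtype=float), b) - b)
            )
        if self.shape == "ushape":
            v, c = float(p["vertex"]), float(p["curvature"])
            return lambda x: c * (np.asarray(x, dtype=float) - v) ** 2
        # piecewise
        knots = np.asarray(p["knots"], dtype=float)
        slopes = np.asarray(p["slopes"], dtype=float)
        if knots.ndim != 1 or np.any(np.diff(knots) <= 0):
            raise ValueError("piecewise knots must be strictly increasing")
        if len(slopes) != len(knots) + 1:
            raise ValueError("piecewise needs len(knots) + 1 slopes")

        def _h(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            # integrate the piecewise-constant derivative from knots[0]
            out = np.where(x < knots[0], slopes[0] * (x - knots[0]), 0.0)
            lo = knots[0]
            for i in range(len(knots)):
                hi = knots[i + 1] if i + 1 < len(knots) else np.inf
                seg = np.clip(x, lo, hi) - lo
                out = out + slopes[i + 1] * np.where(x > lo, seg, 0.0)
                lo = hi
            return out

        return _h


@dataclass
class ExclusionCounts:
    """Per-rule accounting of excluded records."""

    missing_exposure: int = 0
    below_range: int = 0
    above_range: int = 0
    missing_outcome: int = 0
    missing_covariate: int = 0

    @property
    def total(self) -> int:
        return (
            self.missing_exposure
            + self.below_range
            + self.above_range
            + self.missing_outcome
            + self.missing_covariate
        )


@dataclass
class CohortTable:
    """Individual-level cohort: phenotypes + dosages + variant metadata.

    ``phenotypes`` is one row per individual with (at least) columns
    ``latent_exposure``, ``reported_exposure``, ``confounder``, ``age``,
    ``sex``, ``pc1``..``pc5``, ``array``, the outcome columns, and an
    ``included`` flag.  ``dosages`` is aligned on the same index with one
    column per ``variant_id``.
    """

    phenotypes: pd.DataFrame
    dosages: pd.DataFrame
    variants: list[VariantRecord]
    outcome_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phenotypes.index.equals(self.dosages.index):
            raise ValueError("phenotype and dosage tables must share an index")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def included_mask(self) -> pd.Series:
        return self.phenotypes["included"].astype(bool)

    def included(self) -> "CohortTable":
        """Return the sub-cohort of included rows."""
        m = self.included_mask.to_numpy()
        return CohortTable(
            self.phenotypes.loc[m].copy(),
            self.dosages.loc[m].copy(),
            list(self.variants),
            self.outcome_names,
        )

    def subset(self, mask) -> "CohortTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            ph = self.phenotypes.loc[mask]
            ds = self.dosages.loc[mask]
        else:
            ph = self.phenotypes.iloc[mask]
            ds = self.dosages.iloc[mask]
        return CohortTable(ph.copy(), ds.copy(), list(self.variants), self.outcome_names)


def simulate_variants(
    n_variants: int = DEFAULT_N_VARIANTS,
    seed: int = 0,
    beta_range: tuple[float, float] = (0.02, 0.06),
    freq_range: tuple[float, float] = (0.10, 0.90),
) -> list[VariantRecord]:
    """Draw a panel of synthetic instrument SNPs.

    Effect magnitudes are uniform on ``beta_range`` (hours/allele; the
    2.4-3.6 min/allele scale typical of genome-wide significant hits for
    a behavioural trait) with random sign, and effect-allele frequencies
    uniform on ``freq_range``.  Alleles are drawn so that roughly the
    natural fraction (~1/3) of variants is palindromic-free by design:
    palindromic pairs (A/T, C/G) are avoided here because instrument
    panels are assumed already quality-controlled; use explicit records
    to exercise palindrome filtering.
    """
    rng = np.random.default_rng(seed)
    non_palindromic = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
    out = []
    for j in range(n_variants):
        mag = rng.uniform(*beta_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ea, oa = non_palindromic[int(rng.integers(len(non_palindromic)))]
        out.append(
            VariantRecord(
                variant_id=f"rs{900000 + j}",
                effect_allele=ea,
                other_allele=oa,
                gwas_beta=sign * mag,
                allele_freq=float(rng.uniform(*freq_range)),
            )
        )
    return out


def coarsen_exposure(latent):
    """Round a latent exposure to whole hours, halves away from zero.

    Emulates an hourly self-report item.  Accepts a scalar or array;
    returns the same shape.  Non-finite input is rejected.
    """
    x = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("coarsen_exposure requires finite input")
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if np.ndim(latent) == 0:
        return int(rounded)
    return rounded.astype(int)


def generate_cohort(
    n: int,
    variants: Sequence[VariantRecord],
    spec: DoseResponseSpec | Mapping[str, DoseResponseSpec],
    seed: int,
    include_lifestyle: bool = True,
) -> CohortTable:
    """Generate a cohort of ``n`` individuals.

    Dosages are the count of effect alleles from two Bernoulli draws at
    each variant's allele frequency (Hardy-Weinberg, independent loci).
    The latent exposure is

    ``X* = intercept + sum_j beta_j * dosage_j + kappa_U * U + N(0, sd_x)``

    with the intercept solved so that ``E[X*]`` equals the spec's
    ``exposure_mean``.  Each outcome is ``h(X*) + delta_U * U + N(0, sd_y)``.
    The observed exposure is ``coarsen_exposure(X*)``, with optional
    missingness at the spec's ``missing_rate``.  Identical arguments
    reproduce the identical table.

    Parameters
    ----------
    spec : DoseResponseSpec or mapping of outcome name to spec
        With a mapping, one outcome column is generated per entry; the
        exposure-side parameters (confounder loading, exposure noise,
        mean, heterogeneity, missingness) are taken from the first entry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(spec, DoseResponseSpec):
        specs: dict[str, DoseResponseSpec] = {"age_accel": spec}
    else:
        specs = dict(spec)
        if not specs:
            raise ValueError("at least one outcome spec required")
    primary = next(iter(specs.values()))

    rng = np.random.default_rng(seed)
    m = len(variants)
    freqs = np.array([v.allele_freq for v in variants])
    betas = np.array([v.gwas_beta for v in variants])

    dosages = rng.binomial(2, freqs[None, :], size=(n, m)).astype(float) if m else np.zeros((n, 0))

    u = rng.standard_normal(n)
    genetic = dosages @ betas if m else np.zeros(n)
    if primary.genetic_effect_sd > 0:
        s = primary.genetic_effect_sd
        mult = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)
        genetic = genetic * mult
    intercept = primary.exposure_mean - float(2.0 * freqs @ betas) if m else primary.exposure_mean
    latent = (
        intercept
        + genetic
        + primary.confounder_effect_on_exposure * u
        + rng.normal(0.0, primary.exposure_noise_sd, size=n)
    )

    reported = coarsen_exposure(latent).astype(float)
    if primary.missing_rate > 0:
        miss = rng.random(n) < primary.missing_rate
        reported[miss] = np.nan

    ph = pd.DataFrame(index=pd.RangeIndex(n, name="iid"))
    ph["latent_exposure"] = latent
    ph["reported_exposure"] = reported
    ph["confounder"] = u
    ph["age"] = rng.uniform(40.0, 70.0, size=n)
    ph["sex"] = rng.binomial(1, 0.54, size=n)
    for k in range(1, 6):
        ph[f"pc{k}"] = rng.standard_normal(n)
    ph["array"] = rng.binomial(1, 0.9, size=n)
    if include_lifestyle:
        # marginals loosely matched to a middle-aged European biobank
        ph["education"] = rng.binomial(1, 0.83, size=n)
        ph["bmi"] = rng.normal(27.4, 4.75, size=n)
        ph["smoking"] = rng.choice(3, size=n, p=[0.54, 0.36, 0.10])
        ph["drinking"] = rng.choice(3, size=n, p=[0.032, 0.035, 0.933])
        ph["activity"] = rng.choice(3, size=n, p=[0.19, 0.41, 0.40])
        ph["cvd"] = rng.binomial(1, 0.057, size=n)
        ph["hypertension"] = rng.binomial(1, 0.27, size=n)
        ph["diabetes"] = rng.binomial(1, 0.048, size=n)
        ph["leukocyte_count"] = rng.normal(6.9, 2.0, size=n)

    for name, sp in specs.items():
        ph[name] = (
            sp.h(latent)
            + sp.confounder_effect_on_outcome * u
            + rng.normal(0.0, sp.outcome_noise_sd, size=n)
        )

    ph["included"] = True
    dose_df = pd.DataFrame(dosages, index=ph.index, columns=[v.variant_id for v in variants])
    cohort = CohortTable(ph, dose_df, list(variants), tuple(specs))
    cohort, _ = apply_exclusions(cohort)
    return cohort


def apply_exclusions(
    cohort: CohortTable,
    exposure_range: tuple[float, float] = EXPOSURE_RANGE,
    required_covariates: Sequence[str] = ("age", "sex"),
) -> tuple[CohortTable, ExclusionCounts]:
    """Set ``included`` flags by the observed-exposure range rule.

    A record is excluded if the reported exposure is missing, strictly
    below ``exposure_range[0]`` or strictly above ``exposure_range[1]``
    (extreme responses are treated like non-response), or if any outcome
    or required covariate is missing (complete-case rule).  Returns the
    flagged cohort and a per-rule count of exclusions; earlier rules
    claim a record first.
    """
    ph = cohort.phenotypes
    lo, hi = exposure_range
    rep = ph["reported_exposure"]
    counts = ExclusionCounts()

    miss = rep.isna()
    below = (~miss) & (rep < lo)
    above = (~miss) & (rep > hi)
    bad_outcome = pd.Series(False, index=ph.index)
    for name in cohort.outcome_names:
        if name in ph:
            bad_outcome |= ph[name].isna()
    bad_cov = pd.Series(False, index=ph.index)
    for c in required_covariates:
        if c in ph:
            bad_cov |= ph[c].isna()

    counts.missing_exposure = int(miss.sum())
    counts.below_range = int(below.sum())
    counts.above_range = int(above.sum())
    claimed = miss | below | above
    counts.missing_outcome = int((bad_outcome & ~claimed).sum())
    claimed = claimed | bad_outcome
    counts.missing_covariate = int((bad_cov & ~claimed).sum())

    included = ~(claimed | bad_cov)
    ph = ph.copy()
    ph["included"] = included
    return CohortTable(ph, cohort.dosages, list(cohort.variants), cohort.outcome_names), counts


# ---------------------------------------------------------------------------
# On-disk contract: phenotype TSV + dosage TSV + variant-info TSV, "NA" for
# missing.  Downstream modules consume these, so real data can be swapped in.

def write_cohort(cohort: CohortTable, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / f"{prefix}.phenotypes.tsv",
        "dosages": outdir / f"{prefix}.dosages.tsv",
        "variants": outdir / f"{prefix}.variants.tsv",
    }
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", na_rep="NA")
    cohort.dosages.to_csv(paths["dosages"], sep="\t", na_rep="NA")
    pd.DataFrame(
        [dataclasses.asdict(v) for v in cohort.variants],
        columns=["variant_id", "effect_allele", "other_allele", "gwas_beta", "allele_freq"],
    ).to_csv(paths["variants"], sep="\t", index=False, na_rep="NA")
    return paths


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return [
        VariantRecord(
            str(r.variant_id), str(r.effect_allele), str(r.other_allele),
            float(r.gwas_beta), float(r.allele_freq),
        )
        for r in df.itertuples(index=False)
    ]


def read_cohort(outdir: str | Path, prefix: str = "cohort",
                outcome_names: Sequence[str] | None = None) -> CohortTable:
    outdir = Path(outdir)
    ph = pd.read_csv(outdir / f"{prefix}.phenotypes.tsv", sep="\t", na_values="NA", index_col=0)
    ds = pd.read_csv(outdir / f"{prefix}.dosages.tsv", sep="\t", na_values="NA", index_col=0)
    variants = read_variants(outdir / f"{prefix}.variants.tsv")
    if outcome_names is None:
        known = {
            "latent_exposure", "reported_exposure", "confounder", "age", "sex",
            "array", "included", "education", "bmi", "smoking", "drinking",
            "activity", "cvd", "hypertension", "diabetes", "leukocyte_count", "grs",
        } | {f"pc{k}" for k in range(1, 6)}
        outcome_names = [c for c in ph.columns if c not in known]
    ph["included"] = ph["included"].astype(bool)
    return CohortTable(ph, ds, variants, tuple(outcome_names))
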