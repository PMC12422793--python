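"""Unweighted genetic risk score (allele score) construction and diagnostics.

The score is the per-individual count of exposure-increasing alleles
across the instrument SNPs: variants with a positive published effect
contribute their effect-allele dosage, variants with a negative effect
contribute the complementary dosage (2 - dosage).  Palindromic variants
(A/T or C/G) are removed because their strand orientation is ambiguous,
and an arbitrary user-supplied drop list supports pleiotropy sensitivity
analyses.  Instrument strength is summarised by the variance explained
and the F-statistic of a simple linear regression of the exposure on the
score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import VariantRecord, _VALID_ALLELES

__all__ = ["GrsResult", "detect_palindromic", "compute_grs", "instrument_strength"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GrsResult:
    """Allele score vector plus bookkeeping and strength diagnostics."""

    scores: np.ndarray
    used_variants: list[str]
    excluded_palindromic: list[str]
    excluded_user_list: list[str]
    r_squared: float = float("nan")
    f_statistic: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "used_variants": self.used_variants,
            "excluded_palindromic": self.excluded_palindromic,
            "excluded_user_list": self.excluded_user_list,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "n": int(len(self.scores)),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def detect_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        raise ValueError(f"alleles must be in A/C/G/T, got {effect_allele!r}/{other_allele!r}")
    return _COMPLEMENT[ea] == oa


def compute_grs(
    dosages: pd.DataFrame | np.ndarray,
    variants: Sequence[VariantRecord],
    drop_list: Sequence[str] = (),
) -> GrsResult:
    """Sum exposure-increasing allele counts across the retained variants.

    Palindromic variants and any in ``drop_list`` are excluded; a variant
    with ``gwas_beta == 0`` has no defined increasing allele and is
    excluded with a warning.  Dosage columns must match the variant list
    order (or carry variant_id column labels) and lie in [0, 2].
    """
    if isinstance(dosages, pd.DataFrame):
        mat = dosages[[v.variant_id for v in variants]].to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(variants):
        raise ValueError("dosage matrix does not match the variant list")
    if mat.size and (np.nanmin(mat) < 0 or np.nanmax(mat) > 2):
        raise ValueError("dosages outside [0, 2]")

    known = {v.variant_id for v in variants}
    unknown = [d for d in drop_list if d not in known]
    if unknown:
        warnings.warn(f"drop_list variants not in the panel, ignored: {unknown}")
    drop = set(drop_list) & known

    used: list[str] = []
    pal: list[str] = []
    user: list[str] = []
    scores = np.zeros(mat.shape[0])
    for j, v in enumerate(variants):
        if detect_palindromic(v.effect_allele, v.other_allele):
            pal.append(v.variant_id)
            continue
        if v.variant_id in drop:
            user.append(v.variant_id)
            continue
        if v.gwas_beta == 0:
            warnings.warn(f"{v.variant_id}: gwas_beta = 0, no increasing allele; excluded")
            user.append(v.variant_id)
            continue
        col = mat[:, j]
        scores += col if v.gwas_beta > 0 else 2.0 - col
        used.append(v.variant_id)
    return GrsResult(scores, used, pal, user)


def instrument_strength(exposure, scores) -> tuple[float, float]:
    """(r_squared, f_statistic) from simple OLS of exposure on score.

    ``f = (n - 2) * r2 / (1 - r2)``; a perfectly collinear pair yields
    r2 = 1 and an infinite F (with a warning), a constant score yields
    (0, 0) with a warning, and a constant exposure is an error.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(exposure, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("exposure and scores must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(y) == 0:
        raise ValueError("constant exposure: variance explained undefined")
    if np.var(x) == 0:
        warnings.warn("constant score: instrument carries no information")
        return 0.0, 0.0
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0 - 1e-15:
        warnings.warn("exposure exactly linear in score; F-statistic infinite")
        return 1.0, float("inf")
    return r2, float((n - 2) * r2 / (1.0 - r2))
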