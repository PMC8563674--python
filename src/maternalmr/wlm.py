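"""Weighted linear model (WLM) decomposition of maternal and fetal effects.

A SNP's association with *own* birthweight mixes the carrier's fetal effect
with half of the correlated maternal effect (a mother transmits half her
alleles), and its association with *offspring* birthweight mixes the maternal
effect with half the fetal effect:

    E[beta_own] = beta_fetal   + 0.5 * beta_maternal
    E[beta_off] = beta_maternal + 0.5 * beta_fetal

Inverting this two-equation system per SNP gives independent maternal and
fetal genetic effects without requiring genotyped mother-child pairs:

    beta_maternal = (4 beta_off - 2 beta_own) / 3
    beta_fetal    = (4 beta_own - 2 beta_off) / 3

with sampling variances propagated linearly.  This is the linear
approximation to the full structural-equation decomposition, and is
equivalent (up to sampling error) to regressing offspring birthweight jointly
on maternal and fetal genotype in mother-child duos.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateCovarianceError(ValueError):
    """The supplied own/offspring sampling covariance implies variance <= 0."""


@dataclass(frozen=True)
class DuoGwasPair:
    """One SNP's marginal effects on own and on offspring birthweight (SD units)."""

    snp_id: str
    beta_own: float
    se_own: float
    beta_off: float
    se_off: float
    cov_own_off: float = 0.0

    def __post_init__(self) -> None:
        if not (self.se_own > 0 and self.se_off > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be positive")
        if abs(self.cov_own_off) > self.se_own * self.se_off:
            raise ValueError(f"{self.snp_id}: |cov_own_off| exceeds se_own*se_off")


@dataclass(frozen=True)
class MaternalFetalEffects:
    """Decomposed maternal and fetal genetic effects on birthweight for one SNP."""

    snp_id: str
    beta_maternal: float
    se_maternal: float
    beta_fetal: float
    se_fetal: float

    def __post_init__(self) -> None:
        for se in (self.se_maternal, self.se_fetal):
            if not (se > 0 and math.isfinite(se)):
                raise ValueError(f"{self.snp_id}: SEs must be positive and finite")


def wlm_forward(beta_maternal: float, beta_fetal: float) -> tuple[float, float]:
    """Expected (beta_own, beta_off) implied by maternal and fetal effects."""
    return beta_fetal + 0.5 * beta_maternal, beta_maternal + 0.5 * beta_fetal


def wlm_decompose(pair: DuoGwasPair) -> MaternalFetalEffects:
    """Decompose one SNP's own/offspring birthweight betas into maternal and fetal effects."""
    bm = (4.0 * pair.beta_off - 2.0 * pair.beta_own) / 3.0
    bf = (4.0 * pair.beta_own - 2.0 * pair.beta_off) / 3.0
    var_m = (16.0 * pair.se_off**2 + 4.0 * pair.se_own**2 - 16.0 * pair.cov_own_off) / 9.0
    var_f = (16.0 * pair.se_own**2 + 4.0 * pair.se_off**2 - 16.0 * pair.cov_own_off) / 9.0
    if var_m <= 0 or var_f <= 0:
        raise DegenerateCovarianceError(
            f"{pair.snp_id}: decomposed variance is non-positive "
            f"(cov_own_off={pair.cov_own_off})"
        )
    return MaternalFetalEffects(
        snp_id=pair.snp_id,
        beta_maternal=bm,
        se_maternal=math.sqrt(var_m),
        beta_fetal=bf,
        se_fetal=math.sqrt(var_f),
    )


def wlm_decompose_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised decomposition of a table with snp, beta_own, se_own, beta_off, se_off[, cov].

    Returns the input with beta_maternal, se_maternal, beta_fetal, se_fetal
    columns appended.  Per-SNP, no shrinkage across rows.
    """
    required = {"snp", "beta_own", "se_own", "beta_off", "se_off"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    cov = df["cov"].to_numpy(float) if "cov" in df.columns else np.zeros(len(df))
    se_own = df["se_own"].to_numpy(float)
    se_off = df["se_off"].to_numpy(float)
    if np.any(se_own <= 0) or np.any(se_off <= 0):
        raise ValueError("standard errors must be positive")
    bo = df["beta_own"].to_numpy(float)
    bp = df["beta_off"].to_numpy(float)
    var_m = (16 * se_off**2 + 4 * se_own**2 - 16 * cov) / 9.0
    var_f = (16 * se_own**2 + 4 * se_off**2 - 16 * cov) / 9.0
    if np.any(var_m <= 0) or np.any(var_f <= 0):
        bad = df["snp"][(var_m <= 0) | (var_f <= 0)].tolist()
        raise DegenerateCovarianceError(f"non-positive decomposed variance for: {bad}")
    out = df.copy()
    out["beta_maternal"] = (4 * bp - 2 * bo) / 3.0
    out["se_maternal"] = np.sqrt(var_m)
    out["beta_fetal"] = (4 * bo - 2 * bp) / 3.0
    out["se_fetal"] = np.sqrt(var_f)
    return out


def wlm_combine(estimates) -> tuple[float, float]:
    """Inverse-variance-weighted combination of independent (beta, se) estimates.

    Used to pool maternal-effect estimates across disjoint sample classes
    (own-birthweight-only, offspring-birthweight-only, both).
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    betas = np.array([b for b, _ in estimates], float)
    ses = np.array([s for _, s in estimates], float)
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    return float(np.sum(w * betas) / np.sum(w)), float(math.sqrt(1.0 / np.sum(w)))
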