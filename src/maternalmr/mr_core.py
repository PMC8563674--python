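"""Two-sample Mendelian randomisation estimators and sensitivity analyses.

All estimators consume harmonised records (exposure-increasing orientation,
``beta_x >= 0``) and return :class:`MrEstimate` objects:

* per-SNP Wald ratios and their fixed-effect / multiplicative-random-effects
  inverse-variance-weighted (IVW) pool — the main analysis;
* Cochran's Q and I-squared heterogeneity across the ratios;
* MR-Egger regression (slope = pleiotropy-adjusted effect, intercept =
  directional-pleiotropy test);
* the weighted-median estimator with a parametric-bootstrap SE, consistent
  when at least half the instrument weight is valid;
* leave-one-out re-estimation;
* radial MR, whose per-SNP contributions to Q flag outlier instruments;
* multivariable MR for joint/direct effects of several exposures
  (used for glucose-mediation adjustment of the BMI effect).

Wald-ratio SEs use the first-order approximation (outcome SE divided by the
absolute exposure beta; exposure-side sampling error ignored), appropriate
for strong instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimates import MrEstimate, HeterogeneityStats
from .summary_io import HarmonisedRecord

__all__ = [
    "WaldRatio",
    "RadialRow",
    "MrEstimate",
    "HeterogeneityStats",
    "wald_ratio",
    "wald_ratios",
    "ivw_pool",
    "cochran_q",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "radial_mr",
    "mvmr",
    "CollinearityError",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate: outcome beta / exposure beta."""

    snp_id: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not self.se_theta > 0 or not np.isfinite(self.se_theta):
            raise ValueError(f"{self.snp_id}: se_theta must be positive and finite")

    @property
    def weight(self) -> float:
        return 1.0 / self.se_theta**2


@dataclass(frozen=True)
class RadialRow:
    """One SNP's contribution to the radial-MR global Q statistic."""

    snp_id: str
    q_contribution: float
    q_pvalue: float
    is_outlier: bool


def wald_ratio(beta_y: float, se_y: float, beta_x: float, snp_id: str = "") -> WaldRatio:
    """Single-SNP Wald ratio with first-order SE (se_y / |beta_x|)."""
    if beta_x == 0:
        raise ZeroDivisionError(f"{snp_id}: exposure beta is zero, ratio undefined")
    if not se_y > 0:
        raise ValueError(f"{snp_id}: se_y must be positive")
    return WaldRatio(snp_id=snp_id, theta=beta_y / beta_x, se_theta=se_y / abs(beta_x))


def _included(records: Sequence[HarmonisedRecord]) -> list[HarmonisedRecord]:
    return [r for r in records if not r.excluded]


def wald_ratios(records: Sequence[HarmonisedRecord]) -> list[WaldRatio]:
    """Wald ratios for every retained harmonised record (beta_x = 0 is skipped)."""
    out = []
    for r in _included(records):
        if r.beta_x == 0:
            continue
        out.append(wald_ratio(r.beta_y, r.se_y, r.beta_x, snp_id=r.snp_id))
    return out


def _arrays(ratios: Sequence[WaldRatio]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([r.theta for r in ratios], float)
    w = np.array([r.weight for r in ratios], float)
    return theta, w


def ivw_pool(
    ratios: Sequence[WaldRatio],
    model: str = "fixed",
    unit_label: str = "SD outcome per SD exposure",
) -> MrEstimate:
    """Inverse-variance-weighted pool of Wald ratios.

    ``model="fixed"`` is the classical fixed-effect pool (algebraically the
    slope of a weighted regression of beta_y on beta_x through the origin).
    ``model="multiplicative_random"`` keeps the same point estimate but
    inflates the SE by sqrt(max(1, Q/df)) to absorb heterogeneity.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown model {model!r}")
    ratios = list(ratios)
    if not ratios:
        raise ValueError("need at least one Wald ratio")
    theta, w = _arrays(ratios)
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    method = "wald_ivw_fixed"
    if model == "multiplicative_random":
        method = "ivw_mre"
        if len(ratios) >= 2:
            q = float(np.sum(w * (theta - beta) ** 2))
            se *= np.sqrt(max(1.0, q / (len(ratios) - 1)))
    return MrEstimate.from_beta_se(method, beta, se, n_snps=len(ratios), unit_label=unit_label)


def cochran_q(ratios: Sequence[WaldRatio], pooled_beta: Optional[float] = None) -> HeterogeneityStats:
    """Cochran's Q, I-squared and chi-square p-value across Wald ratios."""
    ratios = list(ratios)
    if len(ratios) < 2:
        raise ValueError("heterogeneity requires at least two Wald ratios")
    if pooled_beta is None:
        pooled_beta = ivw_pool(ratios).beta
    theta, w = _arrays(ratios)
    q = float(np.sum(w * (theta - pooled_beta) ** 2))
    return HeterogeneityStats.from_q(q, len(ratios) - 1)


def _record_arrays(records: Sequence[HarmonisedRecord]) -> tuple[np.ndarray, ...]:
    inc = _included(records)
    bx = np.array([r.beta_x for r in inc], float)
    sx = np.array([r.se_x for r in inc], float)
    by = np.array([r.beta_y for r in inc], float)
    sy = np.array([r.se_y for r in inc], float)
    ids = [r.snp_id for r in inc]
    return bx, sx, by, sy, ids


def mr_egger(
    records: Sequence[HarmonisedRecord],
    unit_label: str = "SD outcome per SD exposure",
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger weighted regression of beta_y on beta_x with an intercept.

    Requires the exposure-increasing orientation (all beta_x >= 0); the slope
    estimates the causal effect allowing directional pleiotropy, and a nonzero
    intercept is evidence of it.  SEs use multiplicative overdispersion
    floored at 1.
    """
    bx, _, by, sy, _ = _record_arrays(records)
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    if np.any(bx < 0):
        raise ValueError("records must be oriented to the exposure-increasing allele")
    if np.ptp(bx) == 0:
        raise CollinearityError("all exposure betas identical; Egger slope not identified")
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    scale = max(1.0, float(res.scale))  # res.scale = weighted residual Q / (n-2)
    se = np.sqrt(np.diag(res.cov_params(scale=scale)))
    intercept = MrEstimate.from_beta_se(
        "egger_intercept", res.params[0], se[0], n_snps=n, unit_label="SD outcome per allele"
    )
    slope = MrEstimate.from_beta_se(
        "egger_slope", res.params[1], se[1], n_snps=n, unit_label=unit_label
    )
    return slope, intercept


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta = theta[order]
    w = w[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, theta))


def weighted_median(
    records: Sequence[HarmonisedRecord],
    n_boot: int = 1000,
    seed: int = 0,
    unit_label: str = "SD outcome per SD exposure",
) -> MrEstimate:
    """Weighted-median MR estimate with parametric-bootstrap standard error.

    Wald ratios are ordered and the estimate interpolates the inverse-variance
    cumulative-weight function at 0.5; it is consistent when valid instruments
    carry at least half the total weight.  The SE is the SD of the estimate
    over ``n_boot`` parametric resamples of (beta_x, beta_y) from normal
    distributions centred on the observed values.
    """
    bx, sx, by, sy, _ = _record_arrays(records)
    n = len(bx)
    if n < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy", stacklevel=2)
    theta = by / bx
    w = (bx / sy) ** 2
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(by, sy, size=(n_boot, n))
    theta_b = by_b / bx_b
    w_b = (bx_b / sy) ** 2
    order = np.argsort(theta_b, axis=1)
    theta_s = np.take_along_axis(theta_b, order, axis=1)
    w_s = np.take_along_axis(w_b, order, axis=1)
    p = (np.cumsum(w_s, axis=1) - 0.5 * w_s) / np.sum(w_s, axis=1, keepdims=True)
    boots = np.array([np.interp(0.5, p[i], theta_s[i]) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", est, se, n_snps=n, unit_label=unit_label)


def leave_one_out(
    records: Sequence[HarmonisedRecord],
    unit_label: str = "SD outcome per SD exposure",
) -> list[tuple[str, MrEstimate]]:
    """Fixed-effect IVW re-estimated with each SNP excluded in turn."""
    ratios = wald_ratios(records)
    if len(ratios) < 3:
        raise ValueError("leave-one-out requires at least 3 SNPs")
    out = []
    for i, r in enumerate(ratios):
        rest = ratios[:i] + ratios[i + 1 :]
        out.append((r.snp_id, ivw_pool(rest, unit_label=unit_label)))
    return out


def radial_mr(
    records: Sequence[HarmonisedRecord],
    alpha: float = 0.05,
    model: str = "ivw",
    unit_label: str = "SD outcome per SD exposure",
) -> tuple[MrEstimate, list[RadialRow]]:
    """Radial MR with per-SNP Q contributions for outlier detection.

    The radial transform regresses beta_y/se_y on beta_x/se_y (through the
    origin for IVW; with an intercept for the Egger variant), using
    first-order weights.  Each squared standardised residual is that SNP's
    contribution to the global Q and is referred to chi-square(1); SNPs with
    q_pvalue < alpha are flagged.  For the IVW variant the contributions sum
    exactly to Cochran's Q.
    """
    if model not in ("ivw", "egger"):
        raise ValueError(f"unknown radial model {model!r}")
    bx, _, by, sy, ids = _record_arrays(records)
    n = len(bx)
    if n < 3:
        raise ValueError("radial MR requires at least 3 SNPs")
    resp = by / sy
    pred = bx / sy
    if model == "ivw":
        slope = float(np.sum(resp * pred) / np.sum(pred**2))
        se = float(np.sqrt(1.0 / np.sum(pred**2)))
        resid = resp - slope * pred
        estimate = MrEstimate.from_beta_se("radial_ivw", slope, se, n_snps=n, unit_label=unit_label)
    else:
        X = sm.add_constant(pred)
        res = sm.OLS(resp, X).fit()
        scale = max(1.0, float(res.scale))
        se = float(np.sqrt(res.cov_params(scale=scale)[1, 1]))
        resid = np.asarray(res.resid)
        estimate = MrEstimate.from_beta_se(
            "radial_egger", float(res.params[1]), se, n_snps=n, unit_label=unit_label
        )
    q = resid**2
    pvals = stats.chi2.sf(q, 1)
    rows = [
        RadialRow(snp_id=ids[j], q_contribution=float(q[j]), q_pvalue=float(pvals[j]),
                  is_outlier=bool(pvals[j] < alpha))
        for j in range(n)
    ]
    return estimate, rows


def mvmr(
    beta_y: np.ndarray,
    se_y: np.ndarray,
    exposure_matrix: np.ndarray,
    exposure_names: Optional[Sequence[str]] = None,
    unit_label: str = "SD outcome per SD exposure",
) -> list[MrEstimate]:
    """Multivariable MR: direct effects of K exposures estimated jointly.

    Weighted least squares of the SNP-outcome betas on the K columns of
    SNP-exposure betas, without intercept, weights 1/se_y^2.  Each returned
    estimate is one exposure's effect conditional on the others — used to ask
    how much of the BMI effect on birthweight survives adjustment for its
    effect on fasting glucose.  SEs use multiplicative overdispersion floored
    at 1, as in MR-Egger.
    """
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    X = np.atleast_2d(np.asarray(exposure_matrix, float))
    if X.ndim != 2 or X.shape[0] != len(beta_y):
        raise ValueError("exposure_matrix must be n_snps x K")
    n, k = X.shape
    if k < 1:
        raise ValueError("need at least one exposure column")
    if n <= k:
        raise ValueError(f"need more SNPs ({n}) than exposures ({k})")
    names = list(exposure_names) if exposure_names is not None else [f"exposure_{j}" for j in range(k)]
    if len(names) != k:
        raise ValueError("exposure_names length must match the number of columns")

    if np.linalg.matrix_rank(X) < k:
        # name the offending columns from the QR diagonal
        _, r_ = np.linalg.qr(X)
        diag = np.abs(np.diag(r_))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
        bad = [names[j] for j in range(k) if diag[j] <= tol]
        raise CollinearityError(f"exposure matrix is rank deficient; offending columns: {bad or names}")

    res = sm.WLS(beta_y, X, weights=1.0 / se_y**2).fit()
    scale = max(1.0, float(res.scale))
    ses = np.sqrt(np.diag(res.cov_params(scale=scale)))
    return [
        MrEstimate.from_beta_se(
            "mvmr", float(res.params[j]), float(ses[j]), n_snps=n,
            unit_label=f"{unit_label} [{names[j]}]",
        )
        for j in range(k)
    ]
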