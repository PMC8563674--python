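"""Shared result containers for pooled causal-effect estimates and heterogeneity.

These are deliberately small frozen records: every estimator in the package
returns an :class:`MrEstimate`, and every heterogeneity computation returns a
:class:`HeterogeneityStats`, so downstream code (rescaling, reporting, the
CLI) can treat all methods uniformly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from scipy import stats

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal-effect estimate.

    ``beta`` is the effect of a 1 SD higher exposure on the outcome, in
    whatever units ``unit_label`` declares (SD outcome by default; grams after
    rescaling).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    unit_label: str = "SD outcome per SD exposure"

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"standard error must be positive and finite, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        n_snps: int,
        unit_label: str = "SD outcome per SD exposure",
    ) -> "MrEstimate":
        """Build an estimate with a normal 95% CI and two-sided normal p-value."""
        beta = float(beta)
        se = float(se)
        p = 2.0 * stats.norm.sf(abs(beta) / se)
        return cls(
            method=method,
            beta=beta,
            se=se,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pvalue=float(p),
            n_snps=int(n_snps),
            unit_label=unit_label,
        )

    def scaled(self, factor: float, unit_label: str) -> "MrEstimate":
        """Return the estimate with beta/SE/CI multiplied by ``factor``.

        The p-value is scale invariant and carried over unchanged.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return dataclasses.replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            unit_label=unit_label,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q heterogeneity summary across per-SNP Wald ratios.

    ``i2_percent`` is the share of between-SNP variation attributable to
    heterogeneity rather than sampling error, clipped at zero when Q <= df.
    """

    Q: float
    df: int
    i2_percent: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ValueError("Q must be non-negative")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not (0.0 <= self.i2_percent <= 100.0):
            raise ValueError("I2 must lie in [0, 100]")

    @classmethod
    def from_q(cls, Q: float, df: int) -> "HeterogeneityStats":
        Q = float(Q)
        df = int(df)
        i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
        return cls(Q=Q, df=df, i2_percent=i2, pvalue=float(stats.chi2.sf(Q, df)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
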