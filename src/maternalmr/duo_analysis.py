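"""Individual-level mother-child analyses.

When both maternal and fetal genotypes are observed, the maternal genetic
effect on an offspring outcome can be estimated directly by regressing the
outcome on maternal dosage *conditional on* the child's dosage (plus
covariates), removing confounding by the transmitted alleles.  This module
implements that conditional regression, weighted genetic scores, score vs
covariate validity checks, and fixed-effect pooling of per-cohort estimates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimates import MrEstimate
from .wlm import wlm_combine


class CollinearDosagesError(ValueError):
    """Maternal and child dosage vectors are (near-)identical."""


class AlignmentError(ValueError):
    """SNP identifiers of dosages and weights do not line up."""


class DegenerateCovariateError(ValueError):
    """Covariate has no variance."""


@dataclass
class DuoTable:
    """Genotypes and phenotypes for mother-child pairs.

    ``maternal`` and ``child`` are n_pairs x n_snps dosage matrices in [0, 2]
    on the same SNP ordering and allele orientation.  ``outcome`` is the
    offspring phenotype (e.g. birthweight).  ``exposure`` and ``mediator``
    are optional maternal phenotype vectors, present in synthetic populations
    so that exposure/mediator GWAS can be run on the same table.
    """

    snp_ids: list[str]
    maternal: np.ndarray
    child: np.ndarray
    outcome: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    pair_ids: Optional[list[str]] = None
    exposure: Optional[np.ndarray] = None
    mediator: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, float)
        self.child = np.asarray(self.child, float)
        self.outcome = np.asarray(self.outcome, float)
        n, p = self.maternal.shape
        if self.child.shape != (n, p):
            raise ValueError("maternal and child dosage blocks must have equal shape")
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length must match the dosage columns")
        if self.outcome.shape != (n,):
            raise ValueError("outcome length must match the number of pairs")
        for block in (self.maternal, self.child):
            if block.size and (np.nanmin(block) < 0 or np.nanmax(block) > 2):
                raise ValueError("dosages must lie in [0, 2]")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates must have one row per pair")

    @property
    def n_pairs(self) -> int:
        return self.maternal.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_pairs
        data = {"pair_id": self.pair_ids or [f"pair{i}" for i in range(n)]}
        for j, s in enumerate(self.snp_ids):
            data[f"m_{s}"] = self.maternal[:, j]
        for j, s in enumerate(self.snp_ids):
            data[f"c_{s}"] = self.child[:, j]
        data["outcome"] = self.outcome
        if self.exposure is not None:
            data["exposure"] = self.exposure
        if self.mediator is not None:
            data["mediator"] = self.mediator
        df = pd.DataFrame(data)
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, covariate_columns: Sequence[str] = ()) -> "DuoTable":
        df = pd.read_csv(path, sep="\t")
        m_cols = [c for c in df.columns if c.startswith("m_")]
        snp_ids = [c[2:] for c in m_cols]
        c_cols = [f"c_{s}" for s in snp_ids]
        missing = [c for c in c_cols if c not in df.columns]
        if missing:
            raise ValueError(f"child dosage columns missing: {missing}")
        return cls(
            snp_ids=snp_ids,
            maternal=df[m_cols].to_numpy(float),
            child=df[c_cols].to_numpy(float),
            outcome=df["outcome"].to_numpy(float),
            covariates=df[list(covariate_columns)] if covariate_columns else None,
            pair_ids=df["pair_id"].astype(str).tolist() if "pair_id" in df.columns else None,
            exposure=df["exposure"].to_numpy(float) if "exposure" in df.columns else None,
            mediator=df["mediator"].to_numpy(float) if "mediator" in df.columns else None,
        )


@dataclass(frozen=True)
class ScoreWeights:
    """Per-allele weights (exposure units) aligned to the exposure-increasing allele."""

    snp_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.weights):
            raise ValueError("snp_ids and weights must have equal length")


def conditional_maternal_effect(
    duos: DuoTable,
    snp_index: int,
    use_covariates: bool = True,
    min_pairs: int = 30,
) -> tuple[float, float]:
    """Maternal per-allele effect on the outcome, adjusted for fetal genotype.

    OLS of outcome on [intercept, maternal dosage, child dosage, covariates],
    complete-case on the analysed SNP.  Returns (beta, se) for the maternal
    dosage coefficient.
    """
    gm = duos.maternal[:, snp_index]
    gc = duos.child[:, snp_index]
    y = duos.outcome
    keep = np.isfinite(gm) & np.isfinite(gc) & np.isfinite(y)
    if use_covariates and duos.covariates is not None:
        keep &= np.all(np.isfinite(duos.covariates.to_numpy(float)), axis=1)
    gm, gc, y = gm[keep], gc[keep], y[keep]
    if len(y) < min_pairs:
        raise ValueError(f"need at least {min_pairs} complete pairs, got {len(y)}")
    if np.var(gm) == 0 or np.var(gc) == 0:
        raise ValueError("no variance in dosages at this SNP")
    r = np.corrcoef(gm, gc)[0, 1]
    if abs(r) > 0.999:
        raise CollinearDosagesError(
            f"maternal and child dosages are collinear (r={r:.4f}) at SNP index {snp_index}"
        )
    cols = [gm, gc]
    if use_covariates and duos.covariates is not None:
        cols.append(duos.covariates.to_numpy(float)[keep])
    X = sm.add_constant(np.column_stack(cols))
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


def genetic_score(dosages, weights: ScoreWeights) -> np.ndarray:
    """Weighted allele score per individual: sum_j weight_j * dosage_j.

    ``dosages`` is a DataFrame with one column per SNP id, or a (matrix,
    snp_ids) pair via DuoTable slicing.  Columns are aligned to the weights
    by SNP id; any mismatch is an error, never a silent reorder.
    """
    if isinstance(dosages, pd.DataFrame):
        missing = [s for s in weights.snp_ids if s not in dosages.columns]
        if missing:
            raise AlignmentError(f"dosage columns missing for SNPs: {missing}")
        mat = dosages[list(weights.snp_ids)].to_numpy(float)
    else:
        mat, ids = dosages
        if list(ids) != list(weights.snp_ids):
            raise AlignmentError("SNP id ordering differs between dosages and weights")
        mat = np.asarray(mat, float)
    return mat @ np.asarray(weights.weights, float)


def maternal_score(duos: DuoTable, weights: ScoreWeights) -> np.ndarray:
    """Convenience: genetic score on the maternal dosage block of a DuoTable."""
    return genetic_score((duos.maternal, duos.snp_ids), weights)


def score_covariate_check(score: np.ndarray, covariate: np.ndarray) -> tuple[float, float, float]:
    """Association of a covariate with the genetic score (instrument validity check).

    Continuous covariates: OLS of covariate on score.  Binary covariates
    (values in {0,1}): logistic regression, returning the log-odds slope.
    Returns (beta, se, p).
    """
    score = np.asarray(score, float)
    covariate = np.asarray(covariate, float)
    if score.shape != covariate.shape:
        raise ValueError("score and covariate must have matching lengths")
    if np.var(covariate) == 0:
        raise DegenerateCovariateError("covariate is constant")
    X = sm.add_constant(score)
    values = np.unique(covariate)
    if set(values).issubset({0.0, 1.0}):
        res = sm.Logit(covariate, X).fit(disp=0)
    else:
        res = sm.OLS(covariate, X).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def pool_cohorts(
    per_cohort: Sequence[tuple[float, float]],
    unit_label: str = "SD outcome per SD exposure",
) -> MrEstimate:
    """Fixed-effect inverse-variance meta-analysis of per-cohort (beta, se)."""
    beta, se = wlm_combine(per_cohort)
    return MrEstimate.from_beta_se(
        "pooled_wald_fixed", beta, se, n_snps=len(list(per_cohort)), unit_label=unit_label
    )
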