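"""Synthetic mother-child populations with known causal ground truth.

The generator emulates the statistical structure the analysis assumes:

* biallelic SNPs in Hardy-Weinberg proportions; each child receives one
  allele drawn uniformly from its mother's two plus one paternal allele from
  the population frequency, giving the mother-child dosage correlation of 0.5
  that the maternal/fetal decomposition exploits;
* a maternal exposure (SD units) built from a weighted genetic score plus
  normal noise, with a configurable heritable fraction;
* a scalar mediator (the "fasting glucose" role) downstream of the exposure,
  optionally with its own direct genetic effects;
* an offspring outcome (SD units) receiving the maternal causal effect —
  split between a direct path and the mediator path — plus optional fetal
  direct effects, optional horizontal pleiotropy acting through maternal
  (or fetal) genotype, and noise.

Two-sample summary datasets are built from two non-overlapping populations,
and the outcome population is further split so the own-birthweight and
offspring-birthweight GWAS come from disjoint halves (zero sampling
covariance between the two marginal betas, matching the decomposition's
independence default).

All randomness flows through numpy Generators seeded from ``(seed, stream)``
pairs, so datasets are bit-reproducible and the exposure and outcome samples
use independent streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .duo_analysis import DuoTable
from .summary_io import COMPLEMENT, InstrumentSet, SnpAssociation

# ordered non-palindromic allele pairs (strand-resolvable)
_SAFE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if b not in (a, COMPLEMENT[a])]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class SimConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PleiotropySpec:
    """Horizontal pleiotropy injected into the outcome model.

    ``magnitude`` is the per-allele pleiotropic effect on the outcome in SD
    units.  Directional pleiotropy adds +magnitude for every affected SNP;
    balanced pleiotropy adds +/-magnitude with random signs.  ``via_fetal``
    routes the effect through the child's genotype instead of the mother's.
    """

    mode: str = "none"
    n_pleiotropic: int = 0
    magnitude: float = 0.0
    via_fetal: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise SimConfigError(f"unknown pleiotropy mode {self.mode!r}")
        if self.mode != "none" and self.n_pleiotropic < 1:
            raise SimConfigError("n_pleiotropic must be >= 1 when pleiotropy is on")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a synthetic mother-child study."""

    seed: int
    n_snps: int = 14
    n_individuals: int = 20_000
    allele_freqs: Optional[tuple[float, ...]] = None
    snp_exposure_betas: Optional[tuple[float, ...]] = None
    exposure_h2_target: float = 0.02
    theta_maternal: float = -0.2
    mediation_fraction: float = 0.5
    beta_fetal_direct: Optional[tuple[float, ...]] = None
    snp_mediator_betas: Optional[tuple[float, ...]] = None
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    palindromic_fraction: float = 0.0
    mediator_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if self.n_snps < 1 or self.n_individuals < 2:
            raise SimConfigError("n_snps >= 1 and n_individuals >= 2 required")
        if not (0.0 < self.mediation_fraction <= 1.0):
            raise SimConfigError("mediation_fraction must lie in (0, 1]")
        if not (0.0 < self.exposure_h2_target < 1.0):
            raise SimConfigError("exposure_h2_target must lie in (0, 1)")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, float)
            if len(f) != self.n_snps or np.any(f <= 0.05) or np.any(f >= 0.95):
                raise SimConfigError("allele_freqs must be n_snps values in (0.05, 0.95)")
        for name in ("snp_exposure_betas", "beta_fetal_direct", "snp_mediator_betas"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_snps:
                raise SimConfigError(f"{name} must have n_snps entries")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise SimConfigError("palindromic_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Realised ground truth stored alongside every generated dataset."""

    seed: int
    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    other_alleles: tuple[str, ...]
    allele_freqs: tuple[float, ...]
    snp_exposure_betas: tuple[float, ...]  # per-allele, SD-exposure scale
    exposure_h2: float
    theta_maternal: float
    mediation_fraction: float
    beta_fetal_direct: tuple[float, ...]
    snp_mediator_betas: tuple[float, ...]
    pleiotropic_effects: tuple[float, ...]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class TwoSampleDataset:
    """Summary statistics from two independent synthetic populations."""

    instruments: InstrumentSet
    outcome_own: list[SnpAssociation]
    outcome_offspring: list[SnpAssociation]
    mediator_associations: list[SnpAssociation]
    truth: SimTruth


def _materialise(config: SimConfig) -> SimTruth:
    """Resolve the per-SNP parameters a config leaves to be drawn, reproducibly."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_snps
    snp_ids = tuple(f"rs{i + 1:04d}" for i in range(n))

    if config.allele_freqs is not None:
        freqs = np.asarray(config.allele_freqs, float)
    else:
        freqs = rng.uniform(0.10, 0.90, n)

    n_pal = int(round(config.palindromic_fraction * n))
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist()) if n_pal else set()
    pairs = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _SAFE_PAIRS
        pairs.append(pool[int(rng.integers(len(pool)))])
    eff, oth = zip(*pairs)

    var_per_allele = 2.0 * freqs * (1.0 - freqs)
    if config.snp_exposure_betas is not None:
        betas = np.asarray(config.snp_exposure_betas, float)
        h2 = float(np.sum(var_per_allele * betas**2))
        if h2 >= 1.0:
            raise SimConfigError(
                f"genetic score variance {h2:.3f} exceeds the unit exposure variance"
            )
        if h2 <= 0.0:
            raise SimConfigError("genetic score has zero variance")
    else:
        # heavy-right-tailed effect-size shapes with random signs, rescaled so
        # the score explains exactly exposure_h2_target of the exposure
        shapes = 0.3 + rng.exponential(1.0, n)
        signs = rng.choice([-1.0, 1.0], n)
        raw = shapes * signs
        raw_var = float(np.sum(var_per_allele * raw**2))
        betas = raw * np.sqrt(config.exposure_h2_target / raw_var)
        h2 = config.exposure_h2_target

    fetal = (
        np.asarray(config.beta_fetal_direct, float)
        if config.beta_fetal_direct is not None
        else np.zeros(n)
    )
    med = (
        np.asarray(config.snp_mediator_betas, float)
        if config.snp_mediator_betas is not None
        else np.zeros(n)
    )

    pleio = np.zeros(n)
    spec = config.pleiotropy
    if spec.mode != "none":
        if spec.n_pleiotropic > n:
            raise SimConfigError("n_pleiotropic exceeds n_snps")
        idx = rng.choice(n, size=spec.n_pleiotropic, replace=False)
        if spec.mode == "directional":
            # directional means "positive on the exposure-increasing allele":
            # align each pleiotropic effect with the sign of the SNP's
            # exposure beta, since downstream analysis orients to that allele
            pleio[idx] = spec.magnitude * np.sign(betas[idx])
        else:
            pleio[idx] = spec.magnitude * rng.choice([-1.0, 1.0], spec.n_pleiotropic)

    return SimTruth(
        seed=config.seed,
        snp_ids=snp_ids,
        effect_alleles=tuple(eff),
        other_alleles=tuple(oth),
        allele_freqs=tuple(float(f) for f in freqs),
        snp_exposure_betas=tuple(float(b) for b in betas),
        exposure_h2=float(h2),
        theta_maternal=config.theta_maternal,
        mediation_fraction=config.mediation_fraction,
        beta_fetal_direct=tuple(float(b) for b in fetal),
        snp_mediator_betas=tuple(float(b) for b in med),
        pleiotropic_effects=tuple(float(a) for a in pleio),
    )


def simulate_duos(
    config: SimConfig,
    stream: int = 1,
    truth: Optional[SimTruth] = None,
) -> tuple[DuoTable, SimTruth]:
    """Generate one population of mother-child pairs under the config.

    ``stream`` selects an independent random substream of the config seed,
    so several non-overlapping populations can be drawn from one config.
    """
    if truth is None:
        truth = _materialise(config)
    rng = np.random.default_rng([config.seed, stream])
    n, p = config.n_individuals, config.n_snps
    freqs = np.asarray(truth.allele_freqs)
    betas = np.asarray(truth.snp_exposure_betas)
    fetal = np.asarray(truth.beta_fetal_direct)
    gamma = np.asarray(truth.snp_mediator_betas)
    pleio = np.asarray(truth.pleiotropic_effects)

    # Hardy-Weinberg maternal genotypes as two Bernoulli alleles; the child
    # receives one allele uniformly from the mother plus one paternal allele
    # from the population frequency (uniform-threshold draws: much faster
    # than rng.binomial with array p, same distribution)
    g_mother = (
        (rng.random((n, p)) < freqs).astype(float) + (rng.random((n, p)) < freqs)
    )
    transmitted = (rng.random((n, p)) < g_mother / 2.0).astype(float)
    paternal = rng.random((n, p)) < freqs
    g_child = transmitted + paternal

    h2 = truth.exposure_h2
    score = g_mother @ betas
    exposure = score + rng.normal(0.0, np.sqrt(1.0 - h2), n)

    mediator = exposure + g_mother @ gamma + rng.normal(0.0, config.mediator_noise_sd, n)

    theta, mf = config.theta_maternal, config.mediation_fraction
    pleio_dosage = g_child if config.pleiotropy.via_fetal else g_mother
    systematic = (
        theta * ((1.0 - mf) * exposure + mf * mediator)
        + g_child @ fetal
        + pleio_dosage @ pleio
    )
    resid_var = max(0.05, 1.0 - min(float(np.var(systematic)), 0.95))
    outcome = systematic + rng.normal(0.0, np.sqrt(resid_var), n)

    duos = DuoTable(
        snp_ids=list(truth.snp_ids),
        maternal=g_mother,
        child=g_child,
        outcome=outcome,
        exposure=exposure,
        mediator=mediator,
    )
    return duos, truth


def gwas_from_duos(
    duos: DuoTable,
    trait: str,
    truth: Optional[SimTruth] = None,
) -> list[SnpAssociation]:
    """Per-SNP simple-regression GWAS of one trait carried by a duo table.

    ``exposure``, ``mediator`` and ``offspring_outcome`` are maternal-side
    analyses (trait regressed on maternal dosage); ``own_outcome`` regresses
    the child's phenotype on the child's own dosage.  Monomorphic SNPs are
    dropped.  Allele labels and frequencies come from ``truth`` when given,
    else placeholder A/G labels are used.
    """
    traits = {
        "exposure": ("maternal", "exposure"),
        "mediator": ("maternal", "mediator"),
        "offspring_outcome": ("maternal", "outcome"),
        "own_outcome": ("child", "outcome"),
    }
    if trait not in traits:
        raise ValueError(f"unknown trait {trait!r}; expected one of {sorted(traits)}")
    block_name, attr = traits[trait]
    y = getattr(duos, attr)
    if y is None:
        raise ValueError(f"duo table carries no {attr!r} phenotype")
    G = duos.maternal if block_name == "maternal" else duos.child
    y = np.asarray(y, float)
    n = len(y)

    g_mean = G.mean(axis=0)
    g_c = G - g_mean
    sxx = np.sum(g_c**2, axis=0)
    y_c = y - y.mean()
    syy = float(np.sum(y_c**2))

    poly = sxx > 0  # monomorphic SNPs excluded
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = g_c.T @ y_c
        beta = np.where(poly, sxy / np.where(poly, sxx, 1.0), np.nan)
        rss = np.maximum(syy - beta * sxy, 0.0)
        # perfect fits (e.g. a constant trait) get a numerically-zero SE floor
        se = np.maximum(np.sqrt(rss / (n - 2) / np.where(poly, sxx, 1.0)), 1e-12)
        pvals = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)

    out: list[SnpAssociation] = []
    for j, snp in enumerate(duos.snp_ids):
        if not poly[j]:
            continue
        out.append(
            SnpAssociation(
                snp_id=snp,
                effect_allele=truth.effect_alleles[j] if truth else "A",
                other_allele=truth.other_alleles[j] if truth else "G",
                beta=float(beta[j]),
                se=float(se[j]),
                eaf=float(np.clip(g_mean[j] / 2.0, 1e-6, 1 - 1e-6)),
                pvalue=float(pvals[j]),
                n=n,
            )
        )
    return out


def _scramble_orientation(
    associations: Sequence[SnpAssociation], rng: np.random.Generator
) -> list[SnpAssociation]:
    """Randomly swap allele labels (negating beta) to exercise harmonisation."""
    out = []
    for a in associations:
        if rng.random() < 0.5:
            out.append(
                dataclasses.replace(
                    a,
                    effect_allele=a.other_allele,
                    other_allele=a.effect_allele,
                    beta=-a.beta,
                    eaf=None if a.eaf is None else 1.0 - a.eaf,
                )
            )
        else:
            out.append(a)
    return out


def make_two_sample_dataset(
    config: SimConfig,
    split_outcome_sample: bool = True,
    scramble_outcome_alleles: bool = True,
    n_exposure_individuals: Optional[int] = None,
) -> TwoSampleDataset:
    """Two-sample summary dataset: exposure GWAS and outcome GWAS, independent samples.

    Population 1 provides the SNP-exposure (and SNP-mediator) associations;
    population 2 provides the own-birthweight and offspring-birthweight
    associations.  With ``split_outcome_sample`` the outcome population is
    halved so the two outcome GWAS share no individuals and the own/offspring
    sampling covariance is exactly zero.  Outcome allele orientations are
    randomly scrambled by default so the harmonisation step is always
    exercised end to end.  ``n_exposure_individuals`` lets the exposure GWAS
    sample be larger than the outcome sample, as in real studies where the
    exposure discovery GWAS dwarfs the birthweight sample.
    """
    truth = _materialise(config)
    cfg1 = config
    if n_exposure_individuals is not None:
        cfg1 = dataclasses.replace(config, n_individuals=n_exposure_individuals)
    pop1, _ = simulate_duos(cfg1, stream=1, truth=truth)
    pop2, _ = simulate_duos(config, stream=2, truth=truth)

    exposure_assocs = gwas_from_duos(pop1, "exposure", truth=truth)
    mediator_assocs = gwas_from_duos(pop1, "mediator", truth=truth)

    if split_outcome_sample:
        half = pop2.n_pairs // 2
        own_duos = DuoTable(
            snp_ids=pop2.snp_ids,
            maternal=pop2.maternal[:half],
            child=pop2.child[:half],
            outcome=pop2.outcome[:half],
        )
        off_duos = DuoTable(
            snp_ids=pop2.snp_ids,
            maternal=pop2.maternal[half:],
            child=pop2.child[half:],
            outcome=pop2.outcome[half:],
        )
    else:
        own_duos = off_duos = pop2
    outcome_own = gwas_from_duos(own_duos, "own_outcome", truth=truth)
    outcome_off = gwas_from_duos(off_duos, "offspring_outcome", truth=truth)

    if scramble_outcome_alleles:
        rng = np.random.default_rng([config.seed, 3])
        outcome_own = _scramble_orientation(outcome_own, rng)
        outcome_off = _scramble_orientation(outcome_off, rng)

    instruments = InstrumentSet(
        exposure_name="synthetic_maternal_exposure",
        unit_label="SD exposure",
        sd_in_natural_units=1.0,
        snps=exposure_assocs,
    )
    return TwoSampleDataset(
        instruments=instruments,
        outcome_own=outcome_own,
        outcome_offspring=outcome_off,
        mediator_associations=mediator_assocs,
        truth=truth,
    )
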