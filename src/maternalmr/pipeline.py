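"""Config-driven orchestration: read -> harmonise -> WLM -> estimators -> report.

`run_pipeline` executes the full two-sample MR analysis described by a
:class:`RunConfig`: exposure instruments are read and harmonised against the
outcome associations (either pre-computed maternal-effect betas, or an
own/offspring birthweight pair that is first decomposed into maternal
effects), the estimator suite and sensitivity analyses are run, and all
estimates are rescaled from SD-outcome units to natural units (grams of
birthweight by default).  Partial failures are recorded per stage in the
report rather than silently dropped, and identical config + inputs yield
byte-identical numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimates import HeterogeneityStats, MrEstimate
from .mr_core import (
    RadialRow,
    cochran_q,
    ivw_pool,
    leave_one_out,
    mr_egger,
    mvmr,
    radial_mr,
    wald_ratios,
    weighted_median,
)
from .summary_io import (
    HarmonisedRecord,
    InstrumentSet,
    SnpAssociation,
    harmonise,
    harmonised_to_frame,
    read_summary_table,
    rescale_estimate,
)
from .wlm import DuoGwasPair, wlm_decompose

logger = logging.getLogger("maternalmr")

DEFAULT_METHODS = (
    "ivw",
    "ivw_mre",
    "egger",
    "weighted_median",
    "heterogeneity",
    "leave_one_out",
    "radial",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    exposure_path: str
    outcome_path: str
    outcome_mode: str = "maternal"  # "maternal" betas ready, or "wlm_pair"
    exposure_columns: dict = field(default_factory=dict)
    exposure_name: str = "exposure"
    exposure_unit_label: str = "SD"
    exposure_sd_natural: float = 1.0
    methods: tuple = DEFAULT_METHODS
    radial_alpha: float = 0.05
    n_boot: int = 1000
    palindromic_eaf_window: float = 0.08
    outcome_sd_grams: float = 484.0
    mvmr_exposure_paths: tuple = ()
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("methods list must be non-empty")
        if self.outcome_mode not in ("maternal", "wlm_pair"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        self.methods = tuple(self.methods)
        self.mvmr_exposure_paths = tuple(self.mvmr_exposure_paths)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["mvmr_exposure_paths"] = list(self.mvmr_exposure_paths)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured result bundle of one pipeline run."""

    estimates: list[MrEstimate] = field(default_factory=list)       # natural units
    estimates_sd: list[MrEstimate] = field(default_factory=list)    # SD-outcome units
    heterogeneity: Optional[HeterogeneityStats] = None
    leave_one_out: list[tuple[str, MrEstimate]] = field(default_factory=list)
    radial_estimate: Optional[MrEstimate] = None
    radial_rows: list[RadialRow] = field(default_factory=list)
    harmonised: list[HarmonisedRecord] = field(default_factory=list)
    audit: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimates": [e.to_dict() for e in self.estimates],
            "estimates_sd": [e.to_dict() for e in self.estimates_sd],
            "heterogeneity": self.heterogeneity.to_dict() if self.heterogeneity else None,
            "leave_one_out": [
                {"excluded_snp": s, **e.to_dict()} for s, e in self.leave_one_out
            ],
            "radial_estimate": self.radial_estimate.to_dict() if self.radial_estimate else None,
            "radial_rows": [dataclasses.asdict(r) for r in self.radial_rows],
            "harmonised": [dataclasses.asdict(r) for r in self.harmonised],
            "audit": self.audit,
            "failures": self.failures,
            "provenance": self.provenance,
        }


def read_wlm_pair_table(path) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Read a TSV of own/offspring birthweight betas sharing one allele pair per SNP.

    Columns: snp, effect_allele, other_allele, [eaf], beta_own, se_own,
    beta_off, se_off.  Returns (own, offspring) association lists.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"snp", "effect_allele", "other_allele", "beta_own", "se_own", "beta_off", "se_off"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wlm pair table missing columns: {sorted(missing)}")
    own, off = [], []
    for _, row in df.iterrows():
        common = dict(
            snp_id=str(row["snp"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=float(row["eaf"]) if "eaf" in df.columns and pd.notna(row["eaf"]) else None,
        )
        own.append(SnpAssociation(beta=float(row["beta_own"]), se=float(row["se_own"]), **common))
        off.append(SnpAssociation(beta=float(row["beta_off"]), se=float(row["se_off"]), **common))
    return own, off


def maternal_records_from_pair(
    exposure: InstrumentSet,
    own: list[SnpAssociation],
    offspring: list[SnpAssociation],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonisedRecord]:
    """Harmonise own and offspring tables to the exposure, then WLM-decompose.

    Returns harmonised records whose beta_y/se_y are the decomposed *maternal*
    genetic effects on the outcome; records excluded in either harmonisation
    stay excluded (with the first available reason).
    """
    rec_own = harmonise(exposure, own, palindromic_eaf_window)
    rec_off = harmonise(exposure, offspring, palindromic_eaf_window)
    out: list[HarmonisedRecord] = []
    for r_own, r_off in zip(rec_own, rec_off):
        assert r_own.snp_id == r_off.snp_id
        rec = dataclasses.replace(r_off)
        if r_own.excluded or r_off.excluded:
            rec.excluded_reason = r_own.excluded_reason or r_off.excluded_reason
            out.append(rec)
            continue
        eff = wlm_decompose(
            DuoGwasPair(
                snp_id=rec.snp_id,
                beta_own=r_own.beta_y,
                se_own=r_own.se_y,
                beta_off=r_off.beta_y,
                se_off=r_off.se_y,
            )
        )
        rec.beta_y = eff.beta_maternal
        rec.se_y = eff.se_maternal
        out.append(rec)
    return out


def _audit(records: list[HarmonisedRecord]) -> dict:
    reasons: dict[str, int] = {}
    for r in records:
        if r.excluded:
            reasons[r.excluded_reason] = reasons.get(r.excluded_reason, 0) + 1
    n_excluded = sum(reasons.values())
    return {
        "n_input": len(records),
        "n_analysed": len(records) - n_excluded,
        "n_excluded": n_excluded,
        "exclusion_reasons": reasons,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``."""
    report = RunReport()
    report.provenance = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
    }

    exposure = read_summary_table(
        config.exposure_path,
        column_map=config.exposure_columns,
        exposure_name=config.exposure_name,
        unit_label=config.exposure_unit_label,
        sd_in_natural_units=config.exposure_sd_natural,
    )
    logger.info("read %d exposure SNPs (%d rows rejected)", len(exposure), len(exposure.rejected))

    if config.outcome_mode == "wlm_pair":
        own, off = read_wlm_pair_table(config.outcome_path)
        records = maternal_records_from_pair(
            exposure, own, off, config.palindromic_eaf_window
        )
    else:
        outcome = read_summary_table(config.outcome_path)
        records = harmonise(exposure, outcome.snps, config.palindromic_eaf_window)
    report.harmonised = records
    report.audit = _audit(records)
    report.audit["exposure_rows_rejected"] = len(exposure.rejected)
    logger.info("harmonisation: %s", report.audit)

    unit_sd = "SD birthweight per SD exposure"
    note = f"1 SD exposure = {config.exposure_sd_natural} {config.exposure_unit_label}"
    ratios = wald_ratios(records)

    def record(est: MrEstimate) -> None:
        report.estimates_sd.append(est)
        report.estimates.append(
            rescale_estimate(est, config.outcome_sd_grams, exposure_sd_note=note)
        )

    for method in config.methods:
        try:
            if method == "ivw":
                record(ivw_pool(ratios, model="fixed", unit_label=unit_sd))
            elif method == "ivw_mre":
                record(ivw_pool(ratios, model="multiplicative_random", unit_label=unit_sd))
            elif method == "egger":
                slope, intercept = mr_egger(records, unit_label=unit_sd)
                record(slope)
                record(intercept)
            elif method == "weighted_median":
                record(
                    weighted_median(
                        records, n_boot=config.n_boot, seed=config.seed, unit_label=unit_sd
                    )
                )
            elif method == "heterogeneity":
                report.heterogeneity = cochran_q(ratios)
            elif method == "leave_one_out":
                report.leave_one_out = leave_one_out(records, unit_label=unit_sd)
            elif method == "radial":
                est, rows = radial_mr(
                    records, alpha=config.radial_alpha, model="ivw", unit_label=unit_sd
                )
                report.radial_estimate = rescale_estimate(
                    est, config.outcome_sd_grams, exposure_sd_note=note
                )
                report.radial_rows = rows
            elif method == "mvmr":
                _run_mvmr(config, exposure, records, report, unit_sd, note)
            else:
                report.failures[method] = f"unknown method {method!r}"
        except (ValueError, ZeroDivisionError) as exc:
            report.failures[method] = f"{type(exc).__name__}: {exc}"
            logger.warning("stage %s failed: %s", method, exc)
    return report


def _run_mvmr(config, exposure, records, report, unit_sd, note) -> None:
    if not config.mvmr_exposure_paths:
        report.failures["mvmr"] = "no mvmr_exposure_paths configured"
        return
    kept = [r for r in records if not r.excluded]
    kept_ids = [r.snp_id for r in kept]
    columns = [np.array([r.beta_x for r in kept])]
    names = [config.exposure_name]
    for path in config.mvmr_exposure_paths:
        extra = read_summary_table(path)
        extra_rec = {
            r.snp_id: r
            for r in harmonise(exposure, extra.snps, config.palindromic_eaf_window)
            if not r.excluded
        }
        columns.append(
            np.array([extra_rec[i].beta_y if i in extra_rec else np.nan for i in kept_ids])
        )
        names.append(Path(path).stem)
    X = np.column_stack(columns)
    ok = np.all(np.isfinite(X), axis=1)
    beta_y = np.array([r.beta_y for r in kept])[ok]
    se_y = np.array([r.se_y for r in kept])[ok]
    for est in mvmr(beta_y, se_y, X[ok], exposure_names=names, unit_label=unit_sd):
        report.estimates_sd.append(est)
        report.estimates.append(
            rescale_estimate(est, config.outcome_sd_grams, exposure_sd_note=note)
        )


def _estimates_frame(estimates: list[MrEstimate]) -> pd.DataFrame:
    cols = ["method", "beta", "se", "ci_low", "ci_high", "pvalue", "n_snps", "unit_label"]
    return pd.DataFrame([e.to_dict() for e in estimates], columns=cols)


def write_report(report: RunReport, out_dir, formats=("tsv", "json")) -> dict[str, Path]:
    """Write the report as tidy TSV tables and/or a single JSON bundle.

    Column order is fixed, so repeated runs of the same config produce
    byte-identical files.  Sections that could not be computed are written
    with their recorded failure reason instead of being omitted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "tsv" in formats:
        p = out_dir / "estimates.tsv"
        _estimates_frame(report.estimates).to_csv(p, sep="\t", index=False)
        written["estimates"] = p

        p = out_dir / "heterogeneity.tsv"
        if report.heterogeneity is not None:
            pd.DataFrame([report.heterogeneity.to_dict()]).to_csv(p, sep="\t", index=False)
        else:
            pd.DataFrame(
                [{"skipped_reason": report.failures.get("heterogeneity", "not requested")}]
            ).to_csv(p, sep="\t", index=False)
        written["heterogeneity"] = p

        p = out_dir / "leave_one_out.tsv"
        if report.leave_one_out:
            df = pd.DataFrame(
                [{"excluded_snp": s, **e.to_dict()} for s, e in report.leave_one_out]
            )
        else:
            df = pd.DataFrame(
                [{"skipped_reason": report.failures.get("leave_one_out", "not requested")}]
            )
        df.to_csv(p, sep="\t", index=False)
        written["leave_one_out"] = p

        p = out_dir / "radial.tsv"
        if report.radial_rows:
            pd.DataFrame([dataclasses.asdict(r) for r in report.radial_rows]).to_csv(
                p, sep="\t", index=False
            )
        else:
            pd.DataFrame(
                [{"skipped_reason": report.failures.get("radial", "not requested")}]
            ).to_csv(p, sep="\t", index=False)
        written["radial"] = p

        p = out_dir / "harmonisation.tsv"
        harmonised_to_frame(report.harmonised).to_csv(p, sep="\t", index=False)
        written["harmonisation"] = p

    if "json" in formats:
        p = out_dir / "report.json"
        with open(p, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        written["json"] = p

    log_path = out_dir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"config digest: {report.provenance.get('config_digest')}\n")
        fh.write(f"seed: {report.provenance.get('seed')}\n")
        fh.write(f"audit: {json.dumps(report.audit)}\n")
        fh.write(f"failures: {json.dumps(report.failures)}\n")
    written["log"] = log_path
    return written


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
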