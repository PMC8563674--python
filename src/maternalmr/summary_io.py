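"""Reading, writing and harmonising GWAS summary statistics.

Two-sample MR combines SNP-exposure and SNP-outcome association tables that
were estimated in different samples, typically with arbitrary and possibly
conflicting allele orientations.  This module reads such tables, aligns the
outcome associations onto the exposure table's alleles, orients every record
to the exposure-increasing allele (so all instrument betas are non-negative),
and converts pooled estimates between SD units and natural units
(e.g. grams of birthweight).

Strand-ambiguous (palindromic A/T or G/C) variants cannot be aligned from
allele labels alone; they are resolved by allele-frequency agreement when the
frequencies are informative and excluded otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .estimates import MrEstimate

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: default logical-name -> file-column mapping (GWAS-catalog style headers)
DEFAULT_COLUMN_MAP = {
    "snp": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "p",
    "n": "n",
}

REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se")


class SummaryFormatError(ValueError):
    """The input table does not have the promised shape."""


class DuplicateSnpError(SummaryFormatError):
    """The same snp_id occurs more than once."""


class EmptyOverlapError(ValueError):
    """Exposure and outcome tables share no SNPs."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's effect-allele-oriented association with one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pvalue: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        reason = self.invalid_reason()
        if reason is not None:
            raise ValueError(f"{self.snp_id}: {reason}")

    def invalid_reason(self) -> Optional[str]:
        """Return a human-readable reason this record is invalid, or None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid alleles (biallelic single-base SNPs only)"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not self.se > 0:
            return "nonpositive SE"
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            return "EAF outside (0,1)"
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            return "p-value outside (0,1]"
        if self.n is not None and not self.n > 0:
            return "nonpositive sample size"
        return None

    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass
class InstrumentSet:
    """An ordered set of instrument SNPs for one exposure."""

    exposure_name: str
    unit_label: str
    sd_in_natural_units: float
    snps: list[SnpAssociation]
    #: (row index, snp id or '?', reason) for rows rejected while reading
    rejected: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sd_in_natural_units > 0:
            raise ValueError("sd_in_natural_units must be positive")
        ids = [s.snp_id for s in self.snps]
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            raise DuplicateSnpError(f"duplicate snp_id(s): {', '.join(dups)}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def __len__(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.snps])


@dataclass
class HarmonisedRecord:
    """A SNP's exposure and outcome associations on a common orientation.

    After harmonisation the effect allele is the exposure-increasing allele,
    so ``beta_x >= 0`` for every retained record.  Excluded records keep their
    identity and carry a non-empty ``excluded_reason``.
    """

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    effect_allele: str = ""
    other_allele: str = ""
    eaf_x: Optional[float] = None
    eaf_y: Optional[float] = None
    flipped: bool = False
    strand_complemented: bool = False
    excluded_reason: Optional[str] = None

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


def _map_columns(df: pd.DataFrame, column_map: Mapping[str, str]) -> pd.DataFrame:
    for logical in REQUIRED_COLUMNS:
        col = column_map.get(logical, DEFAULT_COLUMN_MAP[logical])
        if col not in df.columns:
            raise SummaryFormatError(
                f"required column {col!r} (for {logical!r}) missing; found {list(df.columns)}"
            )
    out = {}
    for logical, default in DEFAULT_COLUMN_MAP.items():
        col = column_map.get(logical, default)
        if col in df.columns:
            out[logical] = df[col]
    return pd.DataFrame(out)


def read_summary_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    exposure_name: str = "exposure",
    unit_label: str = "SD",
    sd_in_natural_units: float = 1.0,
) -> InstrumentSet:
    """Read a tab- or comma-separated association table into an InstrumentSet.

    Row order is preserved.  Rows that violate the record invariants (bad
    alleles, nonpositive SE, out-of-range EAF ...) are rejected, not errors:
    they are listed in ``InstrumentSet.rejected`` with a per-row reason.
    Duplicate snp_ids and missing mapped columns are hard errors.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=None, engine="python", dtype={0: str})
    df = _map_columns(raw, column_map)

    snps: list[SnpAssociation] = []
    rejected: list[tuple[int, str, str]] = []
    for i, row in df.iterrows():
        kwargs = dict(
            snp_id=str(row["snp"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            beta=float(row["beta"]),
            se=float(row["se"]),
        )
        for opt, key in (("eaf", "eaf"), ("p", "pvalue"), ("n", "n")):
            if opt in df.columns and pd.notna(row[opt]):
                kwargs[key] = float(row[opt])
        try:
            snps.append(SnpAssociation(**kwargs))
        except ValueError as exc:
            reason = str(exc).split(": ", 1)[-1]
            rejected.append((int(i), kwargs["snp_id"], reason))

    ids = [s.snp_id for s in snps]
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise DuplicateSnpError(f"duplicate snp_id(s): {', '.join(dups)}")
    return InstrumentSet(
        exposure_name=exposure_name,
        unit_label=unit_label,
        sd_in_natural_units=sd_in_natural_units,
        snps=snps,
        rejected=rejected,
    )


def write_summary_table(associations: Iterable[SnpAssociation], path) -> None:
    df = pd.DataFrame([dataclasses.asdict(a) for a in associations])
    df = df.rename(columns={"snp_id": "snp", "pvalue": "p"})
    df.to_csv(path, sep="\t", index=False)


def _complemented(assoc: SnpAssociation) -> tuple[str, str]:
    return COMPLEMENT[assoc.effect_allele], COMPLEMENT[assoc.other_allele]


def harmonise(
    exposure: InstrumentSet,
    outcome: Sequence[SnpAssociation],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonisedRecord]:
    """Align outcome associations to the exposure table's alleles.

    For each exposure SNP, the outcome record is matched by snp_id and its
    alleles reconciled: identical alleles are kept as-is; swapped alleles
    negate the outcome beta and reflect its EAF; alleles matching only after
    strand complementation are complemented first; anything else is excluded
    with reason ``"allele mismatch"``.  Palindromic variants are resolved by
    EAF agreement, or excluded (``"palindromic-ambiguous"``) when either EAF
    is missing or within ``palindromic_eaf_window`` of 0.5.  Finally every
    matched record is oriented to the exposure-increasing allele by negating
    both betas (and relabelling alleles) where the exposure beta is negative.

    One record per exposure SNP is always returned (matched + excluded
    conserves the input count).
    """
    if not 0.0 <= palindromic_eaf_window <= 0.5:
        raise ValueError("palindromic_eaf_window must lie in [0, 0.5]")
    by_id = {a.snp_id: a for a in outcome}
    if not set(exposure.snp_ids) & set(by_id):
        raise EmptyOverlapError("exposure and outcome tables share no SNPs")

    records: list[HarmonisedRecord] = []
    for exp in exposure.snps:
        rec = HarmonisedRecord(
            snp_id=exp.snp_id,
            beta_x=exp.beta,
            se_x=exp.se,
            beta_y=float("nan"),
            se_y=float("nan"),
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            eaf_x=exp.eaf,
        )
        out = by_id.get(exp.snp_id)
        if out is None:
            rec.excluded_reason = "missing in outcome"
            records.append(rec)
            continue

        exp_pair = (exp.effect_allele, exp.other_allele)
        if exp.is_palindromic():
            out_set = frozenset((out.effect_allele, out.other_allele))
            if out_set != frozenset(exp_pair):
                rec.excluded_reason = "allele mismatch"
                records.append(rec)
                continue
            ambiguous = (
                exp.eaf is None
                or out.eaf is None
                or abs(exp.eaf - 0.5) < palindromic_eaf_window
                or abs(out.eaf - 0.5) < palindromic_eaf_window
            )
            if ambiguous:
                rec.excluded_reason = "palindromic-ambiguous"
                records.append(rec)
                continue
            # frequencies on the same side of 0.5 => same orientation
            flip = (exp.eaf > 0.5) != (out.eaf > 0.5)
            rec.beta_y = -out.beta if flip else out.beta
            rec.se_y = out.se
            rec.eaf_y = 1.0 - out.eaf if flip else out.eaf
            rec.flipped = flip
        else:
            out_pair = (out.effect_allele, out.other_allele)
            comp_pair = _complemented(out)
            if out_pair == exp_pair:
                flip, comp = False, False
            elif out_pair == exp_pair[::-1]:
                flip, comp = True, False
            elif comp_pair == exp_pair:
                flip, comp = False, True
            elif comp_pair == exp_pair[::-1]:
                flip, comp = True, True
            else:
                rec.excluded_reason = "allele mismatch"
                records.append(rec)
                continue
            rec.beta_y = -out.beta if flip else out.beta
            rec.se_y = out.se
            if out.eaf is not None:
                rec.eaf_y = 1.0 - out.eaf if flip else out.eaf
            rec.flipped = flip
            rec.strand_complemented = comp

        # orient to the exposure-increasing allele
        if rec.beta_x < 0:
            rec.beta_x = -rec.beta_x
            rec.beta_y = -rec.beta_y
            rec.effect_allele, rec.other_allele = rec.other_allele, rec.effect_allele
            if rec.eaf_x is not None:
                rec.eaf_x = 1.0 - rec.eaf_x
            if rec.eaf_y is not None:
                rec.eaf_y = 1.0 - rec.eaf_y
        records.append(rec)

    assert len(records) == len(exposure.snps)
    return records


def harmonised_to_frame(records: Sequence[HarmonisedRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_harmonised_table(records: Sequence[HarmonisedRecord], path) -> None:
    harmonised_to_frame(records).to_csv(path, sep="\t", index=False)


def rescale_estimate(
    estimate: MrEstimate,
    outcome_sd: float,
    exposure_sd_note: str = "",
) -> MrEstimate:
    """Convert an estimate from SD-outcome units to natural outcome units.

    ``outcome_sd`` is the natural-unit size of one outcome SD (484 g for
    birthweight).  Beta, SE and CI scale linearly; the p-value is unchanged.
    """
    if outcome_sd <= 0:
        raise ValueError("outcome_sd must be positive")
    label = "natural outcome units per SD exposure"
    if exposure_sd_note:
        label = f"{label} ({exposure_sd_note})"
    return estimate.scaled(outcome_sd, label)
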