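import numpy as np
import pytest

from maternalmr.summary_io import HarmonisedRecord, InstrumentSet, SnpAssociation


@pytest.fixture
def simple_instruments() -> InstrumentSet:
    """Three well-behaved non-palindromic instrument SNPs."""
    return InstrumentSet(
        exposure_name="adiposity",
        unit_label="SD body fat %",
        sd_in_natural_units=6.5,
        snps=[
            SnpAssociation("rs1", "A", "G", beta=0.05, se=0.004, eaf=0.30),
            SnpAssociation("rs2", "C", "T", beta=0.03, se=0.005, eaf=0.62),
            SnpAssociation("rs3", "G", "A", beta=-0.04, se=0.006, eaf=0.45),
        ],
    )


def make_records(bx, by, sy, sx=None, ids=None) -> list[HarmonisedRecord]:
    """Harmonised-record factory for estimator tests."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    ids = ids or [f"rs{j}" for j in range(len(bx))]
    return [
        HarmonisedRecord(
            snp_id=ids[j], beta_x=float(bx[j]), se_x=float(sx[j]),
            beta_y=float(by[j]), se_y=float(sy[j]),
        )
        for j in range(len(bx))
    ]


@pytest.fixture
def record_factory():
    return make_records
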