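"""Degree of X-inactivation skewing from HUMARA peak heights.

The HUMARA assay digests genomic DNA with methylation-sensitive enzymes
(HpaII/HhaI) before PCR across the polymorphic CAG repeat of the
androgen receptor gene.  Digestion destroys the unmethylated (active-X)
allele, so the surviving digested signal reflects the methylated,
inactive-X allele of each chromosome.  The undigested reaction measures
both alleles and corrects allele-specific PCR amplification bias:

    r = (h1 / h2) / (u1 / u2)          corrected inactive-X ratio
    f = r / (1 + r)                    fraction of cells with allele 1 inactive
    active fraction of allele 1 = 1 - f
    DS = |active_fraction - 0.5| * 100 in [0, 50]

DS = 0 means random X inactivation (50:50), DS = 50 completely skewed.
A digested peak of exactly zero is the limit of the formula (r = 0 or
infinity, DS = 50); both digested peaks zero is an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .matrix import FormatError, ValidationError

__all__ = ["HumaraPeaks", "SkewResult", "degree_of_skewing",
           "read_peak_table", "write_peak_table", "skew_table"]


@dataclass(frozen=True)
class HumaraPeaks:
    """Peak heights for one sample: digested (h1, h2), undigested (u1, u2)."""

    sample_id: str
    digested: tuple[float, float]
    undigested: tuple[float, float]

    def __post_init__(self) -> None:
        h1, h2 = self.digested
        u1, u2 = self.undigested
        if min(h1, h2, u1, u2) < 0:
            raise ValidationError(f"{self.sample_id}: negative peak height")
        if u1 == 0 or u2 == 0:
            raise ValidationError(
                f"{self.sample_id}: undigested peaks must be positive "
                "(both alleles amplify without digestion)"
            )
        if h1 == 0 and h2 == 0:
            raise ValidationError(f"{self.sample_id}: both digested peaks zero")


@dataclass(frozen=True)
class SkewResult:
    sample_id: str
    active_fraction: float  # fraction of cells with allele 1 active
    ds: float  # degree of skewing, percent in [0, 50]


def degree_of_skewing(p: HumaraPeaks) -> SkewResult:
    """Degree of XCI skewing (percent of the preferentially active allele
    above 50, in [0, 50]) from one sample's corrected peak ratio."""
    h1, h2 = p.digested
    u1, u2 = p.undigested
    if h1 == 0:
        f = 0.0
    elif h2 == 0:
        f = 1.0
    else:
        r = (h1 / h2) / (u1 / u2)
        f = r / (1.0 + r)
    active = 1.0 - f
    ds = abs(active - 0.5) * 100.0
    return SkewResult(p.sample_id, active, ds)


_COLUMNS = ("sample_id", "d1", "d2", "u1", "u2")


def read_peak_table(path, dialect: str = "tsv") -> list[HumaraPeaks]:
    """Read a peak-height table (columns sample_id, d1, d2, u1, u2)."""
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peak table missing columns: {missing}")
    return [
        HumaraPeaks(str(r.sample_id), (float(r.d1), float(r.d2)),
                    (float(r.u1), float(r.u2)))
        for r in df.itertuples()
    ]


def write_peak_table(peaks: list[HumaraPeaks], path, dialect: str = "tsv") -> Path:
    sep = "\t" if dialect == "tsv" else ","
    df = pd.DataFrame(
        [(p.sample_id, *p.digested, *p.undigested) for p in peaks],
        columns=list(_COLUMNS),
    )
    path = Path(path)
    df.to_csv(path, sep=sep, index=False)
    return path


def skew_table(peaks: list[HumaraPeaks]) -> pd.DataFrame:
    """Degree of skewing for a list of samples as a tidy table."""
    rows = [degree_of_skewing(p) for p in peaks]
    return pd.DataFrame(
        [(r.sample_id, r.active_fraction, r.ds) for r in rows],
        columns=["sample_id", "active_fraction", "ds"],
    )
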