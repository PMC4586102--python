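"""Tabular containers and readers/writers for methylation artifacts.

The central object is :class:`BetaMatrix`, a probes x samples grid of
methylation beta values (fraction methylated, in [0, 1]).  Probe
annotations, sample sheets and detection p-value matrices are thin,
validated wrappers around :class:`pandas.DataFrame`.

Conventions
-----------
* Missing cells are encoded as the literal token ``NA`` on disk, NaN in
  memory.
* Row and column order is preserved exactly on read and write; only BED
  output is sorted (by chromosome, then start), because interval
  consumers expect sorted input.
* Annotation positions are 1-based; BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "BetaMatrix",
    "DetectionPMatrix",
    "ProbeAnnotation",
    "SampleSheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_detection_p",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_sem_bed",
]

_SEPS = {"tsv": "\t", "csv": ","}


class ValidationError(ValueError):
    """A value or identifier violates a container invariant."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")


@dataclass
class _UnitGrid:
    """Shared contract for probe x sample grids with values in [0, 1]."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"value {vals[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    def equals(self, other: "_UnitGrid") -> bool:
        return self.data.equals(other.data)


@dataclass
class BetaMatrix(_UnitGrid):
    """Probes x samples grid of methylation beta values in [0, 1]."""


@dataclass
class DetectionPMatrix(_UnitGrid):
    """Per-probe, per-sample detection p-values (same shape contract)."""


_CHROMS = {str(c) for c in range(1, 23)} | {"X", "Y"}


@dataclass
class ProbeAnnotation:
    """Genomic mapping of probes: chromosome, 1-based position, gene symbol
    and platform membership (subset of {27K, 450K}).

    ``gene`` may be empty (intergenic probe) or hold several symbols
    separated by ``;`` — a handful of array probes map inside more than one
    gene.  Probe ids are opaque strings; real manifests are not uniform
    enough for stricter checks.
    """

    data: pd.DataFrame

    REQUIRED = ("probe_id", "chromosome", "position", "gene", "platforms")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        _check_unique(df["probe_id"], "probe")
        df = df.copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str).str.removeprefix("chr")
        bad_chrom = ~df["chromosome"].isin(_CHROMS)
        if bad_chrom.any():
            raise ValidationError(
                f"unknown chromosomes: {sorted(df.loc[bad_chrom, 'chromosome'].unique())}"
            )
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            bad = df.loc[df["position"] < 1, "probe_id"].tolist()
            raise ValidationError(f"positions must be >= 1 (probes {bad[:10]})")
        df["gene"] = df["gene"].fillna("").astype(str)
        df["platforms"] = df["platforms"].fillna("").astype(str)
        ok = df["platforms"].map(
            lambda p: set(filter(None, p.split(";"))) <= {"27K", "450K"}
        )
        if not ok.all():
            bad = df.loc[~ok, "probe_id"].tolist()
            raise ValidationError(f"platforms must be subset of 27K;450K (probes {bad[:10]})")
        self.data = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data["probe_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("probe_id")

    def covers(self, probes: Iterable[str]) -> list[str]:
        """Return the probes from `probes` absent from this annotation."""
        have = set(self.data["probe_id"])
        return [p for p in probes if p not in have]

    def gene_map(self) -> pd.DataFrame:
        """Long (probe_id, gene) table, one row per probe-gene link.

        Probes with an empty gene field are omitted; multi-gene probes
        contribute one row per symbol.
        """
        rows = []
        for pid, gene in zip(self.data["probe_id"], self.data["gene"]):
            for g in filter(None, gene.split(";")):
                rows.append((pid, g))
        return pd.DataFrame(rows, columns=["probe_id", "gene"])


@dataclass
class SampleSheet:
    """Per-sample phenotype and technical metadata.

    Columns: sample_id, age (years), sex (F/M), bmi (kg/m^2, may be
    missing), platform (27K/450K), bs_control_intensity (bisulfite
    conversion control, arbitrary units, may be missing), ds_xci (degree
    of X-inactivation skewing in [0, 50] percent, may be missing),
    replicate_of (sample id of the original for technical duplicates,
    empty otherwise).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "age", "sex", "platform")
    OPTIONAL = ("bmi", "bs_control_intensity", "ds_xci", "replicate_of")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        for c in self.OPTIONAL:
            if c not in df.columns:
                df[c] = "" if c == "replicate_of" else np.nan
        _check_unique(df["sample_id"], "sample")
        df["sample_id"] = df["sample_id"].astype(str)
        df["age"] = df["age"].astype(float)
        if (df["age"] < 0).any():
            raise ValidationError("negative ages in sample sheet")
        if not df["sex"].isin(["F", "M"]).all():
            raise ValidationError("sex must be F or M")
        if not df["platform"].isin(["27K", "450K"]).all():
            raise ValidationError("platform must be 27K or 450K")
        for c in ("bmi", "bs_control_intensity", "ds_xci"):
            df[c] = pd.to_numeric(df[c], errors="raise")
        bmi_bad = df["bmi"].notna() & (df["bmi"] <= 0)
        if bmi_bad.any():
            raise ValidationError("bmi must be positive when present")
        ds = df["ds_xci"]
        if ((ds < 0) | (ds > 50)).any():
            raise ValidationError("ds_xci must lie in [0, 50]")
        df["replicate_of"] = df["replicate_of"].fillna("").astype(str)
        known = set(df["sample_id"])
        orphans = df.loc[
            (df["replicate_of"] != "") & ~df["replicate_of"].isin(known), "sample_id"
        ].tolist()
        if orphans:
            raise ValidationError(
                f"replicate_of refers to unknown samples for: {orphans[:10]}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")

    def duplicate_pairs(self) -> list[tuple[str, str]]:
        """(original, replicate) pairs declared via replicate_of."""
        df = self.data
        reps = df[df["replicate_of"] != ""]
        return [(row.replicate_of, row.sample_id) for row in reps.itertuples()]


# ---------------------------------------------------------------------------
# readers / writers


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected tsv or csv") from None


def _read_grid(path, dialect: str, cls):
    sep = _sep(dialect)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=False
        )
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size and df.columns.str.startswith("Unnamed").any():
        raise FormatError(f"{path}: blank sample ids in header")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in sample {col!r}: {exc}") from exc
    return cls(df)


def read_beta_matrix(path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta matrix: first column probe ids, header row sample ids,
    cells numeric in [0, 1] or the missing token ``NA``."""
    return _read_grid(path, dialect, BetaMatrix)


def read_detection_p(path, dialect: str = "tsv") -> DetectionPMatrix:
    """Read a detection p-value matrix (same layout as a beta matrix)."""
    return _read_grid(path, dialect, DetectionPMatrix)


def write_beta_matrix(m: BetaMatrix, path, dialect: str = "tsv") -> Path:
    """Write a beta matrix as TSV/CSV, missing as ``NA``, order preserved."""
    path = Path(path)
    m.data.to_csv(path, sep=_sep(dialect), na_rep="NA", index_label="probe_id")
    return path


def read_probe_annotation(path, dialect: str = "tsv") -> ProbeAnnotation:
    df = pd.read_csv(path, sep=_sep(dialect), na_values=["NA"], keep_default_na=False,
                     dtype={"chromosome": str})
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path, dialect: str = "tsv") -> Path:
    path = Path(path)
    annot.data.to_csv(path, sep=_sep(dialect), na_rep="NA", index=False)
    return path


def read_sample_sheet(path, dialect: str = "tsv") -> SampleSheet:
    df = pd.read_csv(path, sep=_sep(dialect), na_values=["NA"], keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, dialect: str = "tsv") -> Path:
    path = Path(path)
    sheet.data.to_csv(path, sep=_sep(dialect), na_rep="NA", index=False)
    return path


_CHROM_ORDER = {str(c): c for c in range(1, 23)} | {"X": 23, "Y": 24}


def write_sem_bed(calls, annot: ProbeAnnotation, path) -> Path:
    """Write epimutation calls as a BED-like file.

    One line per call: chrom, 0-based start (= annotated position - 1),
    end (= position), name ``probe|sample|direction``; sorted by
    chromosome then start.  ``calls`` is anything with probe_id,
    sample_id and direction columns (a call table or a
    :class:`~semscan.detect.SEMCallSet`).
    """
    table = getattr(calls, "calls", calls)
    path = Path(path)
    if len(table) == 0:
        path.write_text("")
        return path
    ann = annot.indexed()
    missing = sorted(set(table["probe_id"]) - set(ann.index))
    if missing:
        raise ValidationError(f"probes absent from annotation: {missing[:10]}")
    rows = pd.DataFrame(
        {
            "chrom": ann.loc[table["probe_id"], "chromosome"].to_numpy(),
            "start": ann.loc[table["probe_id"], "position"].to_numpy() - 1,
            "end": ann.loc[table["probe_id"], "position"].to_numpy(),
            "name": [
                f"{p}|{s}|{d}"
                for p, s, d in zip(
                    table["probe_id"], table["sample_id"], table["direction"]
                )
            ],
        }
    )
    rows["_key"] = rows["chrom"].map(_CHROM_ORDER)
    rows = rows.sort_values(["_key", "start", "name"], kind="mergesort")
    rows.drop(columns="_key").to_csv(path, sep="\t", header=False, index=False)
    return path
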