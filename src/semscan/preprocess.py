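"""Sample QC, probe filtering, quantile normalisation, platform pooling.

The pipeline mirrors standard array-methylation practice: drop samples
with failed bisulfite conversion or aberrant global profiles, drop
unreliable probes and the sex chromosomes, quantile-normalise across
samples, then restrict to the probes shared by the 27K and 450K
platforms so both halves of a mixed cohort live in one matrix.

Filter order is fixed (bisulfite control, then PCA screen; missing
betas, then detection p, then sex chromosomes) so QC reports are
deterministic and each removal carries a single reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (
    BetaMatrix,
    DetectionPMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

__all__ = [
    "QCReport",
    "filter_samples",
    "filter_probes",
    "quantile_normalize",
    "background_correct",
    "pool_platforms",
]

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Record of what a QC step removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_probes: list[tuple[str, str]] = field(default_factory=list)
    n_probes_retained: int = 0
    n_samples_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", s, r) for s, r in self.removed_samples] + [
            ("probe", p, r) for p, r in self.removed_probes
        ]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])


def filter_samples(
    m: BetaMatrix,
    sheet: SampleSheet,
    bs_threshold: float = 4000.0,
    pca_sd: float = 4.0,
) -> tuple[BetaMatrix, QCReport]:
    """Drop failed-conversion and globally aberrant samples.

    Samples with bisulfite-control intensity strictly below
    ``bs_threshold`` are removed first (samples without a recorded
    intensity are kept).  The survivors are screened by PCA on the
    probe-standardised matrix: a sample whose score on PC1 or PC2 lies
    more than ``pca_sd`` standard deviations from that component's mean
    is removed as having an aberrant methylation profile.
    """
    info = sheet.indexed()
    missing = [s for s in m.sample_ids if s not in info.index]
    if missing:
        raise ValidationError(f"sample sheet does not cover: {missing[:10]}")

    report = QCReport()
    keep = []
    for s in m.sample_ids:
        bs = info.at[s, "bs_control_intensity"]
        if pd.notna(bs) and bs < bs_threshold:
            report.removed_samples.append((s, "bs_control"))
        else:
            keep.append(s)

    if len(keep) < 3:
        raise ValidationError(
            f"only {len(keep)} samples survive the bisulfite screen; "
            "PCA requires at least 3"
        )

    sub = m.data[keep]
    flagged = _pca_outliers(sub, pca_sd)
    for s in flagged:
        report.removed_samples.append((s, "pca_outlier"))
    keep = [s for s in keep if s not in flagged]

    out = BetaMatrix(m.data[keep])
    report.n_samples_retained = len(keep)
    report.n_probes_retained = out.shape[0]
    return out, report


def _pca_outliers(df: pd.DataFrame, pca_sd: float) -> set[str]:
    # complete, non-constant probes carry the PCA; scores via SVD
    X = df.to_numpy(dtype=float).T  # samples x probes
    ok = ~np.isnan(X).any(axis=0)
    X = X[:, ok]
    sd = X.std(axis=0, ddof=1)
    nz = sd > 0
    X = X[:, nz]
    if X.shape[1] == 0:
        return set()
    X = (X - X.mean(axis=0)) / sd[nz]
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :2] * S[:2]
    flagged: set[str] = set()
    for k in range(min(2, scores.shape[1])):
        col = scores[:, k]
        s = col.std(ddof=1)
        if s == 0:
            continue
        dev = np.abs(col - col.mean())
        flagged |= {df.columns[i] for i in np.flatnonzero(dev > pca_sd * s)}
    return flagged


def filter_probes(
    m: BetaMatrix,
    annot: ProbeAnnotation,
    detp: DetectionPMatrix | None = None,
    detp_alpha: float = 0.05,
    call_rate: float = 0.95,
) -> tuple[BetaMatrix, QCReport]:
    """Remove unreliable probes and the sex chromosomes.

    In order: probes with any missing beta; probes detected (p <
    ``detp_alpha``) in fewer than ``call_rate`` of samples; probes on
    chromosomes X or Y.  Each probe is reported with the first reason
    that applies.  When no detection p-value matrix is given the
    detection filter is skipped with a warning (27K exports often lack
    one).
    """
    missing = annot.covers(m.probe_ids)
    if missing:
        raise ValidationError(f"annotation does not cover probes: {missing[:10]}")
    if detp is not None:
        if detp.shape != m.shape or detp.probe_ids != m.probe_ids or \
                detp.sample_ids != m.sample_ids:
            raise ValidationError("detection p matrix shape/ids do not match beta matrix")
    else:
        logger.warning("no detection p-value matrix supplied; skipping detection filter")

    report = QCReport()
    reasons: dict[str, str] = {}

    has_missing = m.data.isna().any(axis=1)
    for p in m.data.index[has_missing]:
        reasons.setdefault(p, "missing_beta")

    if detp is not None:
        frac = (detp.data < detp_alpha).mean(axis=1)
        for p in detp.data.index[frac < call_rate]:
            reasons.setdefault(p, "detection_p")

    chrom = annot.indexed()["chromosome"]
    for p in m.probe_ids:
        if chrom.at[p] in ("X", "Y"):
            reasons.setdefault(p, "sex_chromosome")

    keep = [p for p in m.probe_ids if p not in reasons]
    report.removed_probes = [(p, reasons[p]) for p in m.probe_ids if p in reasons]
    out = BetaMatrix(m.data.loc[keep])
    report.n_probes_retained = len(keep)
    report.n_samples_retained = out.shape[1]
    return out, report


def quantile_normalize(m: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the common distribution of mean order
    statistics.

    After normalisation each sample's sorted values equal the
    across-sample mean of order statistics; ties within a sample receive
    the mean of the reference values over their rank span, so tied
    inputs stay tied.
    """
    if not m.is_complete():
        raise ValidationError(
            "quantile_normalize requires a complete matrix; run filter_probes first"
        )
    X = m.values
    if X.shape[1] == 0 or X.shape[0] == 0:
        return BetaMatrix(m.data.copy())
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = _map_to_reference(X[:, j], ref)
    return BetaMatrix(pd.DataFrame(out, index=m.probe_ids, columns=m.sample_ids))


def _map_to_reference(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    # run starts of equal values; each run gets the mean reference value
    starts = np.flatnonzero(np.r_[True, np.diff(sv) != 0])
    counts = np.diff(np.r_[starts, sv.size])
    run_means = np.add.reduceat(ref, starts) / counts
    mapped_sorted = np.repeat(run_means, counts)
    out = np.empty_like(v)
    out[order] = mapped_sorted
    return out


def background_correct(m: BetaMatrix) -> BetaMatrix:
    """Identity placeholder: true background correction operates on raw
    fluorescence intensities, which a beta-value matrix no longer
    carries.  Kept in the pipeline so intensity-level implementations
    can slot in."""
    return BetaMatrix(m.data.copy())


def pool_platforms(m27: BetaMatrix, m450: BetaMatrix) -> BetaMatrix:
    """Restrict both matrices to their shared probes and concatenate
    samples; probe order follows the 450K matrix."""
    overlap = set(m27.sample_ids) & set(m450.sample_ids)
    if overlap:
        raise ValidationError(f"overlapping sample ids: {sorted(overlap)[:10]}")
    shared = set(m27.probe_ids) & set(m450.probe_ids)
    if not shared:
        raise ValidationError("no probes in common between the two platforms")
    order = [p for p in m450.probe_ids if p in shared]
    pooled = pd.concat([m450.data.loc[order], m27.data.loc[order]], axis=1)
    return BetaMatrix(pooled)
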