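"""Stochastic epigenetic mutation (SEM) calling.

A SEM is a per-probe, per-subject methylation value lying beyond the
extreme Tukey fences of the population distribution at that CpG:

    lower = Q1 - k * IQR,    upper = Q3 + k * IQR,    k = 3 by default.

A value strictly below the lower fence is a *hypo* call, strictly above
the upper fence a *hyper* call; a value equal to a fence is not called
("exceeding" means strict).  Per-subject burden is the total call count,
analysed on the ln(n + 1) scale so zero-burden subjects (children)
remain usable in regressions.

Two quartile conventions are supported:

``linear``
    linear interpolation of order statistics at position p * (n - 1)
    (the numpy default; what most quantile routines compute).
``tukey``
    Tukey hinges at depth (floor((n + 1) / 2) + 1) / 2 from each end
    (what a classic box-and-whisker plot draws).

The model-style entry point is :class:`SEMScan`; `SEMScan(beta).fit()`
returns a :class:`SEMScanResults` holding the call set, per-probe fence
statistics and per-sample burden, with enrichment, concordance, BED
export and plotting hanging off it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BetaMatrix, ProbeAnnotation, ValidationError, write_sem_bed

__all__ = [
    "ProbeOutlierStats",
    "SEMCallSet",
    "probe_fences",
    "call_sems",
    "count_sems",
    "duplicate_concordance",
    "SEMScan",
    "SEMScanResults",
]

QUANTILE_METHODS = ("linear", "tukey")


@dataclass(frozen=True)
class ProbeOutlierStats:
    """Quartiles and extreme fences for one probe's beta distribution."""

    probe_id: str
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


def _quartiles(sorted_vals: np.ndarray, method: str) -> tuple[float, float]:
    n = sorted_vals.size
    if method == "linear":
        q1, q3 = np.quantile(sorted_vals, [0.25, 0.75], method="linear")
        return float(q1), float(q3)
    if method == "tukey":
        depth = (math.floor((n + 1) / 2) + 1) / 2
        lo = math.floor(depth) - 1  # 0-based
        hi = math.ceil(depth) - 1
        q1 = (sorted_vals[lo] + sorted_vals[hi]) / 2
        q3 = (sorted_vals[n - 1 - lo] + sorted_vals[n - 1 - hi]) / 2
        return float(q1), float(q3)
    raise ValueError(f"unknown quantile method {method!r}; expected one of {QUANTILE_METHODS}")


def probe_fences(
    values, k: float = 3.0, probe_id: str = "", method: str = "linear"
) -> ProbeOutlierStats:
    """Quartiles, IQR and the k-fold extreme fences for one probe."""
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValidationError("probe_fences requires complete values")
    if v.size < 4:
        raise ValidationError(f"need >= 4 values for stable quartiles, got {v.size}")
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")
    q1, q3 = _quartiles(np.sort(v), method)
    iqr = q3 - q1
    return ProbeOutlierStats(probe_id, q1, q3, iqr, q1 - k * iqr, q3 + k * iqr)


@dataclass
class SEMCallSet:
    """Sparse epimutation calls plus per-probe fence statistics.

    ``calls``: DataFrame (probe_id, sample_id, direction in {hyper, hypo}),
    at most one row per (probe, sample).
    ``stats``: DataFrame indexed by probe_id with q1, q3, iqr,
    lower_fence, upper_fence — one row for every probe of the scanned
    matrix, so the probe universe travels with the calls.
    ``samples``: the scanned sample ids (zero-call samples included).
    """

    calls: pd.DataFrame
    stats: pd.DataFrame
    samples: list[str]
    k: float = 3.0

    def __len__(self) -> int:
        return len(self.calls)

    def for_sample(self, sample_id: str) -> set[str]:
        c = self.calls
        return set(c.loc[c["sample_id"] == sample_id, "probe_id"])

    @property
    def probe_universe(self) -> list[str]:
        return list(self.stats.index)


def call_sems(m: BetaMatrix, k: float = 3.0, method: str = "linear") -> SEMCallSet:
    """Call SEMs on a complete beta matrix.

    For every probe the fences are computed over all samples; samples
    strictly beyond a fence are called (hyper above, hypo below).
    """
    if not m.is_complete():
        raise ValidationError(
            "call_sems requires a complete matrix; filter or impute missing betas first"
        )
    X = m.values
    n_probes, n_samples = X.shape
    if n_samples < 4:
        raise ValidationError(f"need >= 4 samples, got {n_samples}")
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")

    S = np.sort(X, axis=1)
    if method == "linear":
        q1 = np.quantile(X, 0.25, axis=1, method="linear")
        q3 = np.quantile(X, 0.75, axis=1, method="linear")
    elif method == "tukey":
        n = n_samples
        depth = (math.floor((n + 1) / 2) + 1) / 2
        lo, hi = math.floor(depth) - 1, math.ceil(depth) - 1
        q1 = (S[:, lo] + S[:, hi]) / 2
        q3 = (S[:, n - 1 - lo] + S[:, n - 1 - hi]) / 2
    else:
        raise ValueError(f"unknown quantile method {method!r}")
    iqr = q3 - q1
    lower = q1 - k * iqr
    upper = q3 + k * iqr

    hyper = X > upper[:, None]
    hypo = X < lower[:, None]
    probes = np.asarray(m.probe_ids)
    samples = np.asarray(m.sample_ids)
    pi, si = np.nonzero(hyper | hypo)
    direction = np.where(hyper[pi, si], "hyper", "hypo")
    calls = pd.DataFrame(
        {"probe_id": probes[pi], "sample_id": samples[si], "direction": direction}
    )
    stats = pd.DataFrame(
        {"q1": q1, "q3": q3, "iqr": iqr, "lower_fence": lower, "upper_fence": upper},
        index=pd.Index(probes, name="probe_id"),
    )
    return SEMCallSet(calls=calls, stats=stats, samples=list(samples), k=k)


def count_sems(calls: SEMCallSet, samples) -> pd.DataFrame:
    """Per-subject epimutation burden: n_sem, n_hyper, n_hypo and
    log_sem = ln(n_sem + 1)."""
    samples = list(samples)
    seen = set(calls.calls["sample_id"])
    unknown = seen - set(samples)
    if unknown:
        raise ValidationError(f"calls contain samples not listed: {sorted(unknown)[:10]}")
    tab = (
        calls.calls.groupby(["sample_id", "direction"]).size().unstack(fill_value=0)
        if len(calls.calls)
        else pd.DataFrame(columns=["hyper", "hypo"])
    )
    for col in ("hyper", "hypo"):
        if col not in tab.columns:
            tab[col] = 0
    out = pd.DataFrame({"sample_id": samples})
    out["n_hyper"] = [int(tab["hyper"].get(s, 0)) for s in samples]
    out["n_hypo"] = [int(tab["hypo"].get(s, 0)) for s in samples]
    out["n_sem"] = out["n_hyper"] + out["n_hypo"]
    out["log_sem"] = np.log1p(out["n_sem"])
    return out


def duplicate_concordance(calls: SEMCallSet, pairs) -> pd.DataFrame:
    """Concordance of epimutation profiles for technical duplicate pairs.

    For each pair the two samples' binary epimutation indicator vectors
    over the full probe universe are correlated (Pearson / phi).  A pair
    with identical non-empty call sets scores 1.0; a pair where both
    members have no calls is reported as missing.
    """
    universe = calls.probe_universe
    idx = {p: i for i, p in enumerate(universe)}
    known = set(calls.samples)
    rows = []
    for a, b in pairs:
        unknown = {a, b} - known
        if unknown:
            raise ValidationError(f"unknown sample ids in pairs: {sorted(unknown)}")
        va = np.zeros(len(universe))
        vb = np.zeros(len(universe))
        sa, sb = calls.for_sample(a), calls.for_sample(b)
        bad = (sa | sb) - idx.keys()
        if bad:
            raise ValidationError(f"calls outside probe universe: {sorted(bad)[:5]}")
        for p in sa:
            va[idx[p]] = 1.0
        for p in sb:
            vb[idx[p]] = 1.0
        if not sa and not sb:
            r = np.nan
        elif sa == sb:
            r = 1.0
        elif va.std() == 0 or vb.std() == 0:
            r = np.nan  # one profile constant over the universe
        else:
            r = float(np.corrcoef(va, vb)[0, 1])
        rows.append((a, b, r))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "concordance"])


# ---------------------------------------------------------------------------
# model-style interface


class SEMScan:
    """Epimutation-scan model for a beta-value matrix.

    Parameters
    ----------
    beta : BetaMatrix or DataFrame
        Complete probes x samples matrix of beta values.
    k : float
        Fence multiplier (3 = extreme outliers).
    quantile_method : str
        ``linear`` or ``tukey`` (see module docstring).
    """

    def __init__(self, beta, k: float = 3.0, quantile_method: str = "linear"):
        if not isinstance(beta, BetaMatrix):
            beta = BetaMatrix(beta)
        if quantile_method not in QUANTILE_METHODS:
            raise ValueError(f"quantile_method must be one of {QUANTILE_METHODS}")
        self.beta = beta
        self.k = float(k)
        self.quantile_method = quantile_method

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SEMScan":
        return cls(BetaMatrix(df), **kw)

    def fit(self) -> "SEMScanResults":
        callset = call_sems(self.beta, k=self.k, method=self.quantile_method)
        return SEMScanResults(self, callset)


class SEMScanResults:
    """Fitted epimutation scan: calls, fence statistics and burden."""

    def __init__(self, model: SEMScan, callset: SEMCallSet):
        self.model = model
        self.callset = callset

    @property
    def calls(self) -> pd.DataFrame:
        return self.callset.calls

    @property
    def stats(self) -> pd.DataFrame:
        return self.callset.stats

    def counts(self) -> pd.DataFrame:
        return count_sems(self.callset, self.model.beta.sample_ids)

    def duplicate_concordance(self, pairs) -> pd.DataFrame:
        return duplicate_concordance(self.callset, pairs)

    def gene_enrichment(self, sample_id: str, annot: ProbeAnnotation, **kw):
        from .enrichment import gene_enrichment

        return gene_enrichment(self.callset, sample_id, annot, **kw)

    def to_bed(self, annot: ProbeAnnotation, path):
        return write_sem_bed(self.callset, annot, path)

    def summary(self) -> str:
        c = self.counts()
        lines = [
            "SEM scan summary",
            "================",
            f"probes scanned     : {self.model.beta.shape[0]}",
            f"samples scanned    : {self.model.beta.shape[1]}",
            f"fence multiplier k : {self.model.k:g} ({self.model.quantile_method} quartiles)",
            f"total calls        : {len(self.callset)} "
            f"(hyper {int(c['n_hyper'].sum())}, hypo {int(c['n_hypo'].sum())})",
            f"burden per subject : median {c['n_sem'].median():g}, "
            f"max {c['n_sem'].max()}",
            f"subjects with >= 1 : {int((c['n_sem'] > 0).sum())} / {len(c)}",
        ]
        return "\n".join(lines)

    def plot_probe(self, probe_id: str, ax=None):
        """Box plot of one probe's betas with its extreme fences and any
        called samples highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.model.beta.data.loc[probe_id].to_numpy(dtype=float)
        st = self.stats.loc[probe_id]
        ax.boxplot(v, vert=True, whis=(0, 100))
        ax.axhline(st["lower_fence"], ls="--", color="crimson", label="fences")
        ax.axhline(st["upper_fence"], ls="--", color="crimson")
        called = self.calls[self.calls["probe_id"] == probe_id]
        if len(called):
            beta_row = self.model.beta.data.loc[probe_id]
            ax.scatter(
                np.ones(len(called)),
                beta_row[called["sample_id"]].to_numpy(dtype=float),
                color="crimson",
                zorder=3,
                label="SEM",
            )
        ax.set_ylabel("beta")
        ax.set_title(probe_id)
        ax.legend(loc="best")
        return ax

    def plot_burden(self, sheet=None, ax=None):
        """Burden (log scale) per subject, against age when a sample
        sheet is provided."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.counts()
        if sheet is not None:
            info = sheet.indexed() if hasattr(sheet, "indexed") else sheet
            age = [info.at[s, "age"] for s in c["sample_id"]]
            ax.scatter(age, c["log_sem"])
            ax.set_xlabel("age (years)")
        else:
            ax.plot(sorted(c["log_sem"]), marker="o", ls="")
            ax.set_xlabel("subject (sorted)")
        ax.set_ylabel("ln(SEM + 1)")
        return ax
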