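"""Gene-level over-representation of epimutated probes.

For one subject's call set the question is whether a gene carries more
epimutated probes than chance would place there.  With N_G probes in the
tested universe, N_S of them epimutated in the subject, and a gene
covered by G_I probes of which S_I are epimutated, the number of
epimutated probes falling in the gene under random placement is
hypergeometric, and the over-representation p-value is the inclusive
upper tail P(X >= S_I).  Raw p-values are Bonferroni-corrected by the
number of genes tested.

A probe annotated to several genes counts once per gene in G_I / S_I but
only once in the universe totals N_G / N_S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProbeAnnotation, ValidationError

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "gene_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    g_i: int
    s_i: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def hypergeom_upper_tail(N_G: int, N_S: int, G_I: int, S_I: int) -> float:
    """P(X >= S_I) for X ~ Hypergeometric(N_G, N_S, G_I).

    Upper tail is inclusive; S_I = 0 therefore gives exactly 1.
    Evaluated through the survival function, which works in log space
    internally, so tiny tails keep full relative precision.
    """
    for name, v in (("N_G", N_G), ("N_S", N_S), ("G_I", G_I), ("S_I", S_I)):
        if v < 0 or v != int(v):
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    if N_S > N_G or G_I > N_G:
        raise ValidationError("need N_S <= N_G and G_I <= N_G")
    if S_I > min(G_I, N_S):
        raise ValidationError("S_I cannot exceed min(G_I, N_S)")
    if S_I == 0:
        return 1.0
    return float(stats.hypergeom.sf(S_I - 1, N_G, N_S, G_I))


def gene_enrichment(
    calls,
    sample_id: str,
    annot: ProbeAnnotation,
    alpha: float = 0.05,
    universe=None,
) -> pd.DataFrame:
    """Per-gene hypergeometric over-representation for one subject.

    Parameters
    ----------
    calls : SEMCallSet
        Fitted call set; its probe universe is the default test universe.
    sample_id : str
        Subject to test.
    annot : ProbeAnnotation
        Probe-to-gene mapping.  Probes with an empty gene field count in
        N_G / N_S but belong to no gene.
    alpha : float
        Significance level applied to the Bonferroni-corrected p.
    universe : iterable of probe ids, optional
        Override the probe universe (e.g. the full array manifest
        rather than the post-QC probe set).

    Returns
    -------
    DataFrame with one row per gene having at least one probe in the
    universe, sorted by raw p ascending (ties broken by gene name):
    gene, g_i, s_i, p_raw, p_bonferroni, significant.
    """
    if sample_id not in set(calls.samples):
        raise ValidationError(f"unknown sample {sample_id!r}")
    universe = list(universe) if universe is not None else calls.probe_universe
    uni = set(universe)
    called = calls.for_sample(sample_id) & uni

    gm = annot.gene_map()
    gm = gm[gm["probe_id"].isin(uni)]
    N_G = len(uni)
    N_S = len(called)

    g_sizes = gm.groupby("gene")["probe_id"].nunique()
    hits = gm[gm["probe_id"].isin(called)].groupby("gene")["probe_id"].nunique()

    n_genes = len(g_sizes)
    rows = []
    for gene, g_i in g_sizes.items():
        s_i = int(hits.get(gene, 0))
        p = hypergeom_upper_tail(N_G, N_S, int(g_i), s_i)
        p_bonf = min(1.0, p * n_genes)
        rows.append((gene, int(g_i), s_i, p, p_bonf, p_bonf < alpha))
    out = pd.DataFrame(
        rows, columns=["gene", "g_i", "s_i", "p_raw", "p_bonferroni", "significant"]
    )
    return out.sort_values(["p_raw", "gene"], kind="mergesort").reset_index(drop=True)
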