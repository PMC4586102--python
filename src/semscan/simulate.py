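"""Synthetic mixed-platform methylation cohorts with known ground truth.

The generator emulates the statistical structure the epimutation scan
assumes in an aging cohort: a bimodal per-probe baseline methylation
profile; logit-normal measurement noise (heteroscedastic, shrinking
near 0 and 1); a mild global hypomethylation drift with age and BMI; a
per-subject epimutation burden drawn Poisson with rate lambda0 *
exp(b * age + u), where u is a subject-level lognormal frailty that
keeps the individual age-burden correlation realistic (strong but far
from deterministic); technical duplicate pairs sharing a configurable
fraction of their epimutations; and, in females, X-inactivation skewing
increasing linearly in log-burden with Gaussian noise, clipped to the
[0, 50] percent range — with no direct age effect, so the age-skewing
association is fully mediated by burden.

Planted epimutations are displaced towards the far boundary of the unit
interval by at least the configured effect size and far enough beyond
the eventual population fences to be detectable; everything is
deterministic for a given seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .matrix import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "Truth",
    "generate_cohort",
    "generate_duplicates",
    "plant_imprinting_block",
]

_AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults mirror the target study design: 178 subjects aged 3-106 in
    five age strata of at least 10 subjects, a mixed 27K/450K cohort
    (about 53% on 450K), burden rate lambda0 * exp(b * age), global
    age/BMI hypomethylation, three technical duplicate pairs sharing 99%
    of their epimutations, and burden-driven XCI skewing in
    heterozygous females.  Probe counts are scaled to desk size; the
    shared set stands in for the 25k probes common to both platforms.
    """

    n_subjects: int = 178
    age_range: tuple[float, float] = (3.0, 106.0)
    n_probes_shared: int = 2000
    n_probes_private: int = 500  # per platform
    probes_per_gene: int = 10
    noise_sd_logit: float = 0.15
    sem_rate_intercept: float = 2.0  # lambda0: expected SEMs at age 0
    sem_rate_slope: float = 0.04  # b: per-year log-rate
    sem_frailty_sd: float = 1.0  # SD of the subject-level log-rate frailty
    global_drift: float = -3e-4  # per-year mean beta change
    bmi_effect: float = -2e-3  # per kg/m^2 beta change (BMI centred at 25)
    epimutation_effect_size: float = 0.2  # minimum |delta beta| of a plant
    duplicate_pairs: int = 3
    duplicate_share: float = 0.99
    imprinting_samples: int = 0
    # skewing map: DS = level + slope * (log_sem - center) + noise, clipped
    # to [0, 50]; the defaults centre the map so clipping is rare (a few
    # percent at the age extremes) and the burden-DS relation stays linear
    xci_slope: float = 7.0  # DS percent per unit log-burden
    xci_center: float = 2.8  # log-burden at the reference DS level
    xci_level: float = 25.0  # DS percent at the reference log-burden
    xci_noise: float = 6.0  # SD (DS percent) of the skewing noise
    frac_450k: float = 94 / 178
    frac_female: float = 0.5
    frac_heterozygous: float = 0.7  # informative HUMARA females
    bmi_missing_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValidationError("need at least 4 subjects")
        if not 0 <= self.duplicate_share <= 1:
            raise ValidationError("duplicate_share must lie in [0, 1]")
        for name in ("sem_rate_intercept", "n_probes_shared", "n_probes_private",
                     "duplicate_pairs", "imprinting_samples"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 < self.epimutation_effect_size < 0.5:
            raise ValidationError("epimutation_effect_size must lie in (0, 0.5)")


@dataclass
class Truth:
    """Ground truth planted by the generator."""

    calls: pd.DataFrame  # probe_id, sample_id, direction
    gene_blocks: list[tuple[str, str]] = field(default_factory=list)
    coefficients: dict = field(default_factory=dict)

    def counts(self, samples) -> pd.DataFrame:
        tab = self.calls.groupby("sample_id").size()
        out = pd.DataFrame({"sample_id": list(samples)})
        out["n_sem"] = [int(tab.get(s, 0)) for s in out["sample_id"]]
        out["log_sem"] = np.log1p(out["n_sem"])
        return out


@dataclass
class SyntheticCohort:
    beta: BetaMatrix  # pooled: shared probes x all samples
    beta27: BetaMatrix
    beta450: BetaMatrix
    sheet: SampleSheet
    annot: ProbeAnnotation
    truth: Truth
    config: CohortConfig
    baseline_mu: pd.Series  # per-probe baseline means (generator internal)


def _make_annotation(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_sh, n_pr, gsize = cfg.n_probes_shared, cfg.n_probes_private, cfg.probes_per_gene
    ids = [f"cg{i:08d}" for i in range(n_sh + 2 * n_pr)]
    rows = []
    pos_counter = {}
    for i, pid in enumerate(ids):
        if i < n_sh:
            platforms = "27K;450K"
            chrom = _AUTOSOMES[i % len(_AUTOSOMES)]
            gene = f"GENE{i // gsize + 1:05d}"
        else:
            j = i - n_sh
            platforms = "27K" if j < n_pr else "450K"
            # a slice of private probes sits on chrX to exercise the
            # sex-chromosome filter
            chrom = "X" if j % 20 == 0 else _AUTOSOMES[j % len(_AUTOSOMES)]
            gene = ""
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 1
        rows.append((pid, chrom, 1000 * pos_counter[chrom], gene, platforms))
    return pd.DataFrame(
        rows, columns=["probe_id", "chromosome", "position", "gene", "platforms"]
    )


def _stratified_ages(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """At least 10 subjects per age stratum, remainder uniform."""
    lo, hi = cfg.age_range
    edges = [(max(lo, a), min(hi, b)) for a, b in
             ((0, 20), (20, 40), (40, 60), (60, 80), (80, 106.99))]
    edges = [(a, b) for a, b in edges if a < b]
    per = min(10, cfg.n_subjects // max(1, len(edges)))
    ages = [rng.uniform(a, b, size=per) for a, b in edges]
    n_rest = cfg.n_subjects - per * len(edges)
    if n_rest > 0:
        ages.append(rng.uniform(lo, hi, size=n_rest))
    out = np.concatenate(ages)
    rng.shuffle(out)
    return out


def _baseline_mu(n: int, rng: np.random.Generator) -> np.ndarray:
    # bimodal methylation landscape, as on real arrays
    low = rng.beta(2, 8, size=n)
    high = rng.beta(8, 2, size=n)
    mu = np.where(rng.random(n) < 0.5, low, high)
    return np.clip(mu, 0.03, 0.97)


def _planted_value(mu: float, sigma_beta: float, effect: float,
                   rng: np.random.Generator) -> tuple[float, str]:
    """Displace towards the far boundary, beyond fences and >= effect."""
    d = max(effect, 7.0 * sigma_beta + 0.05) + rng.uniform(0.0, 0.03)
    if mu <= 0.5:
        v, direction = mu + d, "hyper"
    else:
        v, direction = mu - d, "hypo"
    if not 0.005 <= v <= 0.995:
        raise ValidationError(
            f"infeasible epimutation displacement at baseline {mu:.3f} "
            f"(required |delta beta| {d:.3f})"
        )
    return float(v), direction


def generate_cohort(cfg: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Accepts a :class:`CohortConfig` or keyword overrides of its fields.
    Deterministic for a given ``seed``.
    """
    if cfg is None:
        cfg = CohortConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    annot_df = _make_annotation(cfg, rng)
    annot = ProbeAnnotation(annot_df)
    probe_ids = annot_df["probe_id"].to_numpy()
    n_sh = cfg.n_probes_shared
    mu = _baseline_mu(len(probe_ids), rng)
    mu_s = pd.Series(mu, index=probe_ids)

    # subjects ------------------------------------------------------------
    ages = _stratified_ages(cfg, rng)
    n = cfg.n_subjects
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < cfg.frac_female, "F", "M")
    platform = np.where(rng.random(n) < cfg.frac_450k, "450K", "27K")
    # keep both platforms populated whenever possible
    if (platform == "450K").all() and n > 1:
        platform[0] = "27K"
    if (platform == "27K").all() and n > 1:
        platform[0] = "450K"
    bmi = np.clip(rng.normal(25.0, 4.0, size=n), 16.0, None)
    bmi_obs = bmi.copy()
    bmi_obs[rng.random(n) < cfg.bmi_missing_frac] = np.nan
    bs = rng.normal(8000.0, 800.0, size=n).clip(5000.0, None)

    # planted epimutation burden ------------------------------------------
    frailty = np.clip(rng.normal(0.0, cfg.sem_frailty_sd, size=n), -2.0, 2.0)
    lam = cfg.sem_rate_intercept * np.exp(cfg.sem_rate_slope * ages + frailty)
    counts = rng.poisson(lam)
    if (counts > n_sh).any():
        raise ValidationError("planted burden exceeds the shared probe pool")
    call_rows: list[tuple[str, str, str]] = []
    planted_values: dict[tuple[int, int], float] = {}  # (probe idx, sample idx)
    for j, sid in enumerate(sample_ids):
        if counts[j] == 0:
            continue
        chosen = rng.choice(n_sh, size=counts[j], replace=False)
        for pi in chosen:
            sig = cfg.noise_sd_logit * mu[pi] * (1 - mu[pi]) + 0.01
            v, direction = _planted_value(mu[pi], sig, cfg.epimutation_effect_size, rng)
            planted_values[(pi, j)] = v
            call_rows.append((probe_ids[pi], sid, direction))

    # beta matrix ----------------------------------------------------------
    mean = np.clip(
        mu[:, None]
        + cfg.global_drift * ages[None, :]
        + cfg.bmi_effect * (bmi[None, :] - 25.0),
        0.02, 0.98,
    )
    eps = rng.normal(0.0, cfg.noise_sd_logit, size=mean.shape)
    beta_full = np.clip(expit(logit(mean) + eps), 0.001, 0.999)
    for (pi, j), v in planted_values.items():
        beta_full[pi, j] = v

    # XCI skewing: burden-driven, no direct age term -----------------------
    log_sem = np.log1p(counts.astype(float))
    ds = np.clip(
        cfg.xci_level
        + cfg.xci_slope * (log_sem - cfg.xci_center)
        + rng.normal(0.0, cfg.xci_noise, size=n),
        0.0, 50.0,
    )
    informative = (sex == "F") & (rng.random(n) < cfg.frac_heterozygous)
    ds_obs = np.where(informative, ds, np.nan)

    sheet = SampleSheet(pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sex,
            "bmi": bmi_obs,
            "platform": platform,
            "bs_control_intensity": bs,
            "ds_xci": ds_obs,
            "replicate_of": "",
        }
    ))

    full = pd.DataFrame(beta_full, index=probe_ids, columns=sample_ids)
    is27 = platform == "27K"
    probes27 = probe_ids[: n_sh + cfg.n_probes_private]
    probes450 = np.concatenate([probe_ids[:n_sh], probe_ids[n_sh + cfg.n_probes_private:]])
    beta27 = BetaMatrix(full.loc[probes27, np.array(sample_ids)[is27]])
    beta450 = BetaMatrix(full.loc[probes450, np.array(sample_ids)[~is27]])
    pooled = BetaMatrix(full.loc[probe_ids[:n_sh]])

    truth = Truth(
        calls=pd.DataFrame(call_rows, columns=["probe_id", "sample_id", "direction"]),
        coefficients={
            "sem_rate_intercept": cfg.sem_rate_intercept,
            "sem_rate_slope": cfg.sem_rate_slope,
            "sem_frailty_sd": cfg.sem_frailty_sd,
            "global_drift": cfg.global_drift,
            "bmi_effect": cfg.bmi_effect,
            "xci_slope": cfg.xci_slope,
            "xci_center": cfg.xci_center,
        },
    )
    cohort = SyntheticCohort(
        beta=pooled, beta27=beta27, beta450=beta450, sheet=sheet, annot=annot,
        truth=truth, config=cfg, baseline_mu=mu_s,
    )
    for i in range(cfg.imprinting_samples):
        gene = f"GENE{(i % (n_sh // cfg.probes_per_gene)) + 1:05d}"
        cohort = plant_imprinting_block(cohort, gene, sample_ids[i % n])
    return cohort


def generate_duplicates(
    cohort: SyntheticCohort,
    duplicate_pairs: int | None = None,
    duplicate_share: float | None = None,
) -> SyntheticCohort:
    """Append technical replicates of randomly chosen subjects.

    Each replicate re-measures its original with independent noise and
    carries a planted epimutation set sharing ``duplicate_share`` of the
    original's: every original call is retained with that probability,
    and the replicate gains its own calls for the complement, so both
    members have comparable burden but only partial overlap.

    Duplicated subjects are drawn from those carrying at least 10
    planted epimutations (concordance is degenerate for near-empty call
    sets); when too few subjects qualify, the highest-burden remainder
    fills in.
    """
    cfg = cohort.config
    n_pairs = cfg.duplicate_pairs if duplicate_pairs is None else duplicate_pairs
    share = cfg.duplicate_share if duplicate_share is None else duplicate_share
    if n_pairs > cfg.n_subjects:
        raise ValidationError("more duplicate pairs than subjects")
    if n_pairs == 0:
        return cohort
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]).generate_state(1)[0])

    sheet_df = cohort.sheet.data.copy()
    originals = sheet_df[sheet_df["replicate_of"] == ""]["sample_id"].tolist()
    burden = cohort.truth.calls.groupby("sample_id").size()
    ranked = sorted(originals, key=lambda sid: -int(burden.get(sid, 0)))
    eligible = [sid for sid in ranked if int(burden.get(sid, 0)) >= 10]
    if len(eligible) >= n_pairs:
        chosen = rng.choice(eligible, size=n_pairs, replace=False)
    else:
        chosen = np.asarray(ranked[:n_pairs])

    pooled = cohort.beta.data.copy()
    b27 = cohort.beta27.data.copy()
    b450 = cohort.beta450.data.copy()
    mu_all = cohort.baseline_mu
    probe_pos = {p: i for i, p in enumerate(mu_all.index)}
    n_sh = cfg.n_probes_shared

    truth_calls = cohort.truth.calls
    new_rows = []
    new_sheet_rows = []
    for sid in chosen:
        rep_id = f"{sid}_rep"
        info = sheet_df.set_index("sample_id").loc[sid]
        orig_calls = truth_calls[truth_calls["sample_id"] == sid]
        keep = rng.random(len(orig_calls)) < share
        kept = orig_calls[keep]
        n_new = int((~keep).sum())
        used = set(probe_pos[p] for p in orig_calls["probe_id"])
        free = np.setdiff1d(np.arange(n_sh), np.fromiter(used, dtype=int, count=len(used)))
        extra_idx = rng.choice(free, size=min(n_new, free.size), replace=False)

        # fresh measurement noise for the replicate
        bmi_val = info["bmi"] if pd.notna(info["bmi"]) else 25.0
        mean = np.clip(
            mu_all.to_numpy()
            + cfg.global_drift * info["age"]
            + cfg.bmi_effect * (bmi_val - 25.0),
            0.02, 0.98,
        )
        eps = rng.normal(0.0, cfg.noise_sd_logit, size=mean.size)
        col = np.clip(expit(logit(mean) + eps), 0.001, 0.999)

        rep_call_rows = []
        for row in kept.itertuples():
            pi = probe_pos[row.probe_id]
            sig = cfg.noise_sd_logit * mu_all.iloc[pi] * (1 - mu_all.iloc[pi]) + 0.01
            col[pi], d = _planted_value(mu_all.iloc[pi], sig,
                                        cfg.epimutation_effect_size, rng)
            rep_call_rows.append((row.probe_id, rep_id, d))
        for pi in extra_idx:
            sig = cfg.noise_sd_logit * mu_all.iloc[pi] * (1 - mu_all.iloc[pi]) + 0.01
            col[pi], d = _planted_value(mu_all.iloc[pi], sig,
                                        cfg.epimutation_effect_size, rng)
            rep_call_rows.append((mu_all.index[pi], rep_id, d))
        new_rows.extend(rep_call_rows)

        pooled[rep_id] = col[:n_sh]
        if info["platform"] == "27K":
            b27[rep_id] = col[: n_sh + cfg.n_probes_private]
        else:
            idx450 = [probe_pos[p] for p in b450.index]
            b450[rep_id] = col[idx450]
        new_sheet_rows.append(
            {
                "sample_id": rep_id, "age": info["age"], "sex": info["sex"],
                "bmi": info["bmi"], "platform": info["platform"],
                "bs_control_intensity": info["bs_control_intensity"],
                "ds_xci": np.nan, "replicate_of": sid,
            }
        )

    sheet = SampleSheet(pd.concat(
        [sheet_df, pd.DataFrame(new_sheet_rows)], ignore_index=True
    ))
    truth = Truth(
        calls=pd.concat(
            [truth_calls,
             pd.DataFrame(new_rows, columns=["probe_id", "sample_id", "direction"])],
            ignore_index=True,
        ),
        gene_blocks=list(cohort.truth.gene_blocks),
        coefficients=dict(cohort.truth.coefficients),
    )
    return SyntheticCohort(
        beta=BetaMatrix(pooled), beta27=BetaMatrix(b27), beta450=BetaMatrix(b450),
        sheet=sheet, annot=cohort.annot, truth=truth, config=cfg,
        baseline_mu=cohort.baseline_mu,
    )


def plant_imprinting_block(
    cohort: SyntheticCohort, gene: str, sample: str
) -> SyntheticCohort:
    """Displace every probe of ``gene`` beyond fence distance in one
    sample, emulating an imprinting-disorder methylation defect.

    Idempotent on the recorded truth: planting the same (gene, sample)
    twice is a no-op the second time.
    """
    if (gene, sample) in cohort.truth.gene_blocks:
        return cohort
    ann = cohort.annot.data
    probes = [
        p for p, g in zip(ann["probe_id"], ann["gene"])
        if gene in g.split(";") and p in cohort.beta.data.index
    ]
    if len(probes) < 3:
        raise ValidationError(f"gene {gene!r} has fewer than 3 probes (or is unknown)")
    if sample not in cohort.beta.data.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    cfg = cohort.config
    tag = zlib.crc32(f"{gene}|{sample}".encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 13, tag]).generate_state(1)[0]
    )
    pooled = cohort.beta.data.copy()
    already = set(
        cohort.truth.calls[cohort.truth.calls["sample_id"] == sample]["probe_id"]
    )
    rows = []
    for p in probes:
        mu = float(cohort.baseline_mu[p])
        sig = cfg.noise_sd_logit * mu * (1 - mu) + 0.01
        v, d = _planted_value(mu, sig, cfg.epimutation_effect_size, rng)
        pooled.at[p, sample] = v
        if p not in already:
            rows.append((p, sample, d))
    truth = Truth(
        calls=pd.concat(
            [cohort.truth.calls,
             pd.DataFrame(rows, columns=["probe_id", "sample_id", "direction"])],
            ignore_index=True,
        ),
        gene_blocks=cohort.truth.gene_blocks + [(gene, sample)],
        coefficients=dict(cohort.truth.coefficients),
    )
    b27, b450 = cohort.beta27.data.copy(), cohort.beta450.data.copy()
    for tgt in (b27, b450):
        if sample in tgt.columns:
            for p in probes:
                if p in tgt.index:
                    tgt.at[p, sample] = pooled.at[p, sample]
    return SyntheticCohort(
        beta=BetaMatrix(pooled), beta27=BetaMatrix(b27), beta450=BetaMatrix(b450),
        sheet=cohort.sheet, annot=cohort.annot, truth=truth, config=cfg,
        baseline_mu=cohort.baseline_mu,
    )
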