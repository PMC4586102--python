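"""Statistical layer: standardized regression, correlation ratio, path
analysis and multiple imputation with Rubin pooling.

All regressions operate on Z-scored variables, so coefficients are
standardized (comparable across variables and bounded by 1 in absolute
value for orthonormal designs).  The path model is a recursive system of
standardized OLS regressions — one per endogenous variable on its
parents — which for a recursive, just-identified diagram coincides with
the structural-equation estimates.

Missing covariates (typically BMI, and XCI skewing outside the
heterozygous-female subset) are handled either by complete-case
analysis per model, or by chained-equation multiple imputation with
posterior-noise draws, pooled across imputations by Rubin's rules:

    q_bar = mean(q_i),  W = mean(var_i),  B = Var(q_i),
    T = W + (1 + 1/m) * B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrix import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "AGE_RANGE_BINS",
    "AGE_RANGE_LABELS",
    "z_transform",
    "correlation_ratio",
    "standardized_regression",
    "build_cohort_table",
    "age_range_labels",
    "PathModel",
    "PathResults",
    "DEFAULT_PATH_EDGES",
    "impute_missing",
    "rubin_pool",
    "PooledEstimate",
]

AGE_RANGE_BINS = (0, 20, 40, 60, 80, 107)
AGE_RANGE_LABELS = ("0-19", "20-39", "40-59", "60-79", "80-106")

# age -> burden -> skewing diagram; average methylation sits downstream of
# age and burden, and the direct age -> skewing arrow is the one the
# mediation question interrogates
DEFAULT_PATH_EDGES = (
    ("age", "log_sem"),
    ("age", "avg_beta"),
    ("log_sem", "avg_beta"),
    ("age", "ds_xci"),
    ("log_sem", "ds_xci"),
    ("avg_beta", "ds_xci"),
)


def z_transform(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("z_transform needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValidationError("z_transform undefined for constant input")
    return (v - v.mean()) / sd


def correlation_ratio(groups) -> float:
    """Correlation ratio eta = sqrt(SS_between / SS_total) of a continuous
    variable across categorical groups.

    ``groups`` is an iterable of (label, values) pairs; every subject
    contributes one value, groups weighted by their size.
    """
    groups = [(lab, np.asarray(v, dtype=float)) for lab, v in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(v.size == 0 for _, v in groups):
        raise ValidationError("empty group")
    allv = np.concatenate([v for _, v in groups])
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    if ss_total == 0:
        raise ValidationError("correlation ratio undefined: all values identical")
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for _, v in groups))
    return float(np.sqrt(ss_between / ss_total))


def age_range_labels(ages) -> pd.Series:
    """Assign the five study age strata (0-19 ... 80-106)."""
    return pd.cut(
        pd.Series(ages, dtype=float),
        bins=AGE_RANGE_BINS,
        labels=AGE_RANGE_LABELS,
        right=False,
        include_lowest=True,
    )


def build_cohort_table(
    beta: BetaMatrix, counts: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """One row per subject: age, bmi, avg_beta (mean methylation over all
    probes), log_sem, ds_xci, sex, age_range.

    Technical replicates (replicate_of set) are excluded — they are QC
    material, not independent subjects.
    """
    info = sheet.indexed()
    avg = beta.data.mean(axis=0)
    tab = counts.set_index("sample_id").copy()
    keep = [s for s in tab.index if s in info.index and info.at[s, "replicate_of"] == ""]
    tab = tab.loc[keep]
    tab["avg_beta"] = [avg.get(s, np.nan) for s in tab.index]
    for col in ("age", "bmi", "ds_xci", "sex"):
        tab[col] = [info.at[s, col] for s in tab.index]
    tab["age_range"] = age_range_labels(tab["age"]).to_numpy()
    return tab.reset_index()


_COND_LIMIT = 1e8


def standardized_regression(y: str, x, table: pd.DataFrame) -> pd.DataFrame:
    """OLS of Z-scored y on Z-scored predictors, complete cases only.

    Returns one row per predictor: term, beta_std, ci_low, ci_high
    (normal-approximation 95%), p (two-sided).
    """
    x = list(x)
    cols = [y] + x
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"variables absent from table: {missing}")
    sub = table[cols].dropna()
    if len(sub) < len(x) + 2:
        raise ValidationError(
            f"only {len(sub)} complete cases for {y} ~ {x}; need >= {len(x) + 2}"
        )
    Z = np.column_stack([z_transform(sub[c]) for c in cols])
    yv, X = Z[:, 0], Z[:, 1:]
    cond = np.linalg.cond(X)
    if cond > _COND_LIMIT:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValidationError(
            f"collinear design (condition number {cond:.3g}); "
            f"worst pair: {x[i]!r} ~ {x[j]!r}"
        )
    fit = sm.OLS(yv, sm.add_constant(X, has_constant="add")).fit()
    rows = []
    for k, term in enumerate(x, start=1):
        b, se = fit.params[k], fit.bse[k]
        rows.append(
            (term, b, b - 1.959963984540054 * se, b + 1.959963984540054 * se,
             fit.pvalues[k], len(sub))
        )
    return pd.DataFrame(
        rows, columns=["term", "beta_std", "ci_low", "ci_high", "p", "n"]
    )


class PathModel:
    """Recursive path-analysis model over observed, Z-scored variables.

    Parameters
    ----------
    table : DataFrame
        One row per subject, columns holding the model variables.
    edges : iterable of (parent, child)
        Directed acyclic edge set.  Each endogenous variable is
        regressed on its full parent set; edge coefficients are the
        standardized partial regression coefficients.
    """

    def __init__(self, table: pd.DataFrame, edges=DEFAULT_PATH_EDGES):
        self.table = table
        self.edges = [tuple(e) for e in edges]
        self._check_acyclic()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, edges=DEFAULT_PATH_EDGES):
        return cls(table, edges)

    def _check_acyclic(self) -> None:
        children: dict[str, set[str]] = {}
        for a, b in self.edges:
            children.setdefault(a, set()).add(b)
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = 1
            for nxt in children.get(node, ()):
                if state.get(nxt, 0) == 1:
                    raise ValidationError(
                        f"cyclic path specification: {' -> '.join(stack + [node, nxt])}"
                    )
                if state.get(nxt, 0) == 0:
                    visit(nxt, stack + [node])
            state[node] = 2

        for n in list(children):
            if state.get(n, 0) == 0:
                visit(n, [])

    def fit(self, alpha: float = 0.05) -> "PathResults":
        parents: dict[str, list[str]] = {}
        for a, b in self.edges:
            parents.setdefault(b, []).append(a)
        rows = []
        for child, par in parents.items():
            res = standardized_regression(child, par, self.table)
            for r in res.itertuples():
                rows.append(
                    (r.term, child, r.beta_std, r.ci_low, r.ci_high, r.p,
                     r.p < alpha, r.n)
                )
        table = pd.DataFrame(
            rows,
            columns=["from", "to", "beta_std", "ci_low", "ci_high", "p",
                     "significant", "n"],
        )
        # report in the order the edges were specified
        order = {e: i for i, e in enumerate(self.edges)}
        table["_o"] = [order[(a, b)] for a, b in zip(table["from"], table["to"])]
        table = table.sort_values("_o").drop(columns="_o").reset_index(drop=True)
        return PathResults(self, table, alpha)


class PathResults:
    """Fitted path model: one standardized coefficient per edge."""

    def __init__(self, model: PathModel, edges: pd.DataFrame, alpha: float):
        self.model = model
        self.edges = edges
        self.alpha = alpha

    def edge(self, a: str, b: str) -> pd.Series:
        m = self.edges[(self.edges["from"] == a) & (self.edges["to"] == b)]
        if m.empty:
            raise KeyError(f"no edge {a} -> {b}")
        return m.iloc[0]

    def summary(self) -> str:
        lines = [
            "Path analysis (recursive standardized OLS)",
            "==========================================",
            f"{'edge':<24}{'beta_std':>9}{'95% CI':>20}{'p':>12}  sig  n",
        ]
        for _, r in self.edges.iterrows():
            ci = f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]"
            star = "*" if r["significant"] else " "
            lines.append(
                f"{r['from']:>10} -> {r['to']:<10}{r['beta_std']:>+9.3f}"
                f"{ci:>20}{r['p']:>12.3g}   {star}   {r['n']}"
            )
        lines.append(f"significance level: {self.alpha}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Schematic diagram: significant edges solid, others dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        nodes = sorted(set(self.edges["from"]) | set(self.edges["to"]))
        theta = np.linspace(0, 2 * np.pi, len(nodes), endpoint=False)
        pos = {n: (np.cos(t), np.sin(t)) for n, t in zip(nodes, theta)}
        for _, r in self.edges.iterrows():
            a, b = pos[r["from"]], pos[r["to"]]
            ax.annotate(
                "", xy=b, xytext=a,
                arrowprops=dict(
                    arrowstyle="-|>",
                    ls="-" if r["significant"] else "--",
                    color="crimson" if r["significant"] else "grey",
                    shrinkA=22, shrinkB=22,
                ),
            )
            mid = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
            ax.text(*mid, f"{r['beta_std']:+.2f}", ha="center", fontsize=8)
        for n, (xx, yy) in pos.items():
            ax.text(xx, yy, n, ha="center", va="center",
                    bbox=dict(boxstyle="round", fc="white"))
        ax.set_xlim(-1.5, 1.5)
        ax.set_ylim(-1.5, 1.5)
        ax.axis("off")
        return ax


def impute_missing(
    table: pd.DataFrame, m: int = 5, seed: int = 0, columns=None
) -> list[pd.DataFrame]:
    """Chained-equation multiple imputation with posterior-noise draws.

    Numeric columns are imputed jointly by iterated Bayesian-ridge
    regressions, sampling from the posterior predictive at each step so
    the m completed tables carry genuine between-imputation variability.
    Deterministic for a given seed.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    if m < 1:
        raise ValidationError("need at least 1 imputation")
    num = table.select_dtypes(include=[np.number])
    if columns is not None:
        num = num[list(columns)]
    fully_missing = [c for c in num.columns if num[c].isna().all()]
    if fully_missing:
        raise ValidationError(f"variables entirely missing: {fully_missing}")
    n_complete = int(num.dropna().shape[0])
    if num.isna().any().any() and n_complete < 10:
        raise ValidationError(f"only {n_complete} complete cases; need >= 10 to impute")

    if not num.isna().any().any():
        return [table.copy() for _ in range(m)]

    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31 - 1)
    out = []
    for s in seeds:
        imp = IterativeImputer(
            sample_posterior=True, random_state=int(s), max_iter=15
        )
        filled = imp.fit_transform(num.to_numpy())
        t = table.copy()
        t[num.columns] = filled
        out.append(t)
    return out


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules pooled estimate across m imputations."""

    q_bar: float
    W: float  # mean within-imputation variance
    B: float  # between-imputation variance
    T: float  # total variance
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))


def rubin_pool(estimates) -> PooledEstimate:
    """Pool (estimate, variance) pairs from m imputed analyses."""
    est = [(float(q), float(v)) for q, v in estimates]
    m = len(est)
    if m < 2:
        raise ValidationError("Rubin pooling needs at least 2 imputations")
    q = np.array([e[0] for e in est])
    w = np.array([e[1] for e in est])
    q_bar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    return PooledEstimate(q_bar=q_bar, W=W, B=B, T=float(T), m=m)
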