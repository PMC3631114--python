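"""Statistical layer: paired t-test, two-way ANOVA, Tukey-Kramer post-hoc.

The study design crosses two two-level factors — histological type
(plexiform A-M vs Haversian P-L) and pre-treatment (fatigued F vs
control C) — over unbalanced cell sizes, so the ANOVA uses the partial
(Type III) sum-of-squares decomposition under sum-to-zero contrasts, and
the post-hoc comparisons among the four cells use the Tukey-Kramer
harmonic-mean adjustment for unequal n. Significance is assessed at the
5% level, with post-hoc stars at 0.05 / 0.02 / 0.01.

Effects are computed here from first principles (least squares on
explicit contrast-coded design matrices); only the reference
distributions (t, F, studentized range) come from scipy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TwoFactorDataset",
    "PairedTResult",
    "paired_t_test",
    "two_way_anova",
    "tukey_posthoc",
    "significance_stars",
]

#: Post-hoc star thresholds: p < 0.05 -> *, < 0.02 -> **, < 0.01 -> ***
STAR_THRESHOLDS = (0.05, 0.02, 0.01)


def significance_stars(p: float) -> str:
    return "*" * sum(p < thr for thr in STAR_THRESHOLDS)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t_test(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Classical paired t-test on the differences x - y, two-sided.

    Degenerate input (all differences identical, zero variance) is
    rejected rather than returning an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length series with at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        raise ValueError("zero-variance differences: paired t-test undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(t=float(t), df=df, p=float(p))


@dataclass(frozen=True)
class TwoFactorDataset:
    """Observations crossed by two categorical factors.

    ``factor_a`` conventionally holds the histology labels (e.g. "AM",
    "PL") and ``factor_b`` the treatment labels ("F", "C"), but any
    two-factor layout with >= 2 levels each is accepted.
    """

    values: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        a = np.asarray(self.factor_a)
        b = np.asarray(self.factor_b)
        if not (v.size == a.size == b.size) or v.size == 0:
            raise ValueError("values and factor labels must be equal-length, non-empty")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "factor_a", a)
        object.__setattr__(self, "factor_b", b)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value: str, factor_a: str = "histology", factor_b: str = "treatment"
    ) -> "TwoFactorDataset":
        return cls(df[value].to_numpy(), df[factor_a].to_numpy(), df[factor_b].to_numpy())

    @property
    def levels_a(self) -> np.ndarray:
        return np.unique(self.factor_a)

    @property
    def levels_b(self) -> np.ndarray:
        return np.unique(self.factor_b)

    def cell_counts(self) -> pd.DataFrame:
        return (
            pd.DataFrame({"a": self.factor_a, "b": self.factor_b})
            .value_counts()
            .unstack(fill_value=0)
        )

    @property
    def balanced(self) -> bool:
        counts = self.cell_counts().to_numpy()
        return bool((counts == counts.flat[0]).all())

    def check_cells(self, min_per_cell: int = 1) -> None:
        counts = self.cell_counts()
        for a in self.levels_a:
            for b in self.levels_b:
                n = counts.loc[a, b] if (a in counts.index and b in counts.columns) else 0
                if n < min_per_cell:
                    raise ValueError(
                        f"cell ({a!r}, {b!r}) has {n} observations; "
                        f"need >= {min_per_cell} for ANOVA with interaction"
                    )


def _sum_contrast(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: (n, k-1) columns; last level = -1."""
    k = len(levels)
    cols = np.zeros((labels.size, k - 1))
    for j in range(k - 1):
        cols[labels == levels[j], j] = 1.0
        cols[labels == levels[-1], j] = -1.0
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass(frozen=True)
class AnovaTable:
    """Per-effect sums of squares, F statistics and p-values."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, residual
    ss_type: int = 3

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    def __repr__(self) -> str:
        return f"AnovaTable(type {self.ss_type})\n{self.table!r}"


def two_way_anova(data: TwoFactorDataset, ss_type: int = 3) -> AnovaTable:
    """Two-way fixed-effects ANOVA with interaction.

    Type III (partial) sums of squares under sum-to-zero contrasts by
    default — each effect is tested as the increase in residual sum of
    squares when its columns are dropped from the full model — which is
    the appropriate decomposition for the study's unbalanced cells.
    Type II is available for comparison. Requires every cell occupied
    with >= 2 observations.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    data.check_cells(min_per_cell=2)
    y = data.values
    n = y.size
    la, lb = data.levels_a, data.levels_b
    A = _sum_contrast(data.factor_a, la)
    B = _sum_contrast(data.factor_b, lb)
    AB = np.einsum("ni,nj->nij", A, B).reshape(n, -1)
    one = np.ones((n, 1))

    X_full = np.hstack([one, A, B, AB])
    rss_full = _rss(X_full, y)
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid

    if ss_type == 3:
        drops = {
            "factor_a": np.hstack([one, B, AB]),
            "factor_b": np.hstack([one, A, AB]),
            "interaction": np.hstack([one, A, B]),
        }
        ss = {k: _rss(X, y) - rss_full for k, X in drops.items()}
    else:  # Type II: main effects adjusted for each other, not the interaction
        rss_ab = _rss(np.hstack([one, A, B]), y)
        ss = {
            "factor_a": _rss(np.hstack([one, B]), y) - rss_ab,
            "factor_b": _rss(np.hstack([one, A]), y) - rss_ab,
            "interaction": rss_ab - rss_full,
        }

    dfs = {
        "factor_a": len(la) - 1,
        "factor_b": len(lb) - 1,
        "interaction": (len(la) - 1) * (len(lb) - 1),
    }
    rows = []
    for eff in ("factor_a", "factor_b", "interaction"):
        s = max(ss[eff], 0.0)  # guard tiny negative round-off
        f_stat = (s / dfs[eff]) / ms_resid
        rows.append(
            {"effect": eff, "sum_sq": s, "df": dfs[eff],
             "mean_sq": s / dfs[eff], "F": f_stat,
             "p": float(sps.f.sf(f_stat, dfs[eff], df_resid))}
        )
    rows.append(
        {"effect": "residual", "sum_sq": rss_full, "df": df_resid,
         "mean_sq": ms_resid, "F": np.nan, "p": np.nan}
    )
    return AnovaTable(pd.DataFrame(rows).set_index("effect"), ss_type)


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey-Kramer comparisons among the factor-crossing cells."""

    comparisons: pd.DataFrame  # group1, group2, mean_diff, q, p_adj, stars
    mse: float = field(default=np.nan)
    df_resid: int = field(default=0)

    def p_adj(self, group1: str, group2: str) -> float:
        c = self.comparisons
        m = ((c.group1 == group1) & (c.group2 == group2)) | (
            (c.group1 == group2) & (c.group2 == group1)
        )
        if not m.any():
            raise KeyError(f"no comparison between {group1!r} and {group2!r}")
        return float(c.loc[m, "p_adj"].iloc[0])


def tukey_posthoc(data: TwoFactorDataset, group_sep: str = "/") -> TukeyResult:
    """Tukey-Kramer comparisons among the a x b cells of the design.

    Uses the residual mean square of the full cell-means model (identical
    to the two-way model with interaction). For unequal cell sizes the
    standard error of a pair uses the Tukey-Kramer form
    sqrt(MSE/2 * (1/n_i + 1/n_j)); adjusted p-values come from the
    studentized-range distribution with k = number of cells. Symmetric in
    pair order; stars mark p < 0.05 / 0.02 / 0.01.
    """
    data.check_cells(min_per_cell=2)
    cells = [f"{a}{group_sep}{b}" for a in data.levels_a for b in data.levels_b]
    labels = np.array(
        [f"{a}{group_sep}{b}" for a, b in zip(data.factor_a, data.factor_b)]
    )
    y = data.values
    k = len(cells)
    means = {c: y[labels == c].mean() for c in cells}
    ns = {c: int((labels == c).sum()) for c in cells}
    n = y.size
    rss = sum(float(((y[labels == c] - means[c]) ** 2).sum()) for c in cells)
    df_resid = n - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the post-hoc test")
    mse = rss / df_resid

    rows = []
    for g1, g2 in itertools.combinations(cells, 2):
        diff = means[g2] - means[g1]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        p = min(p, 1.0)
        rows.append(
            {"group1": g1, "group2": g2, "mean_diff": diff, "q": q,
             "p_adj": p, "stars": significance_stars(p)}
        )
    return TukeyResult(pd.DataFrame(rows), mse=mse, df_resid=df_resid)
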