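"""Group and community statistics for superoxide measurement tables.

ANOVA/Tukey/t-tests are thin, contract-checked wrappers over statsmodels and
scipy (Type-II sums of squares for the unbalanced species x health design).
Bray-Curtis dissimilarity and ANOSIM are implemented from their definitions:
ANOSIM ranks all pairwise dissimilarities (average ranks on ties) and
computes

    R = (mean_between_rank - mean_within_rank) / (M / 2),   M = n(n-1)/2,

tested by permuting sample labels.  The denominator M/2 = n(n-1)/4 bounds R
to [-1, 1] with R = 1 at perfect separation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "AnosimResult",
    "TTestResult",
    "two_way_anova",
    "tukey_hsd",
    "two_sample_t",
    "relative_abundance",
    "bray_curtis",
    "anosim",
]


# ---------------------------------------------------------------------------
# ANOVA / Tukey / t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F/df/p for two main effects and their interaction."""

    effects: Mapping[str, AnovaEffect]

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factors: tuple[str, str] = ("species", "health"),
) -> AnovaResult:
    """Full-factorial two-way ANOVA with Type-II sums of squares.

    Type II is used because the design is unbalanced (per-cell n varies) and
    the questions are about main effects in the presence of an interaction.
    Every factor-level combination must be observed; an empty cell is refused
    with the offending cell named.
    """
    a, b = factors
    for col in (value, a, b):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    if not np.all(np.isfinite(table[value].to_numpy(dtype=float))):
        raise ValueError("response values must be finite")
    levels_a = table[a].unique()
    levels_b = table[b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least two observed levels")
    counts = table.groupby([a, b], observed=True).size()
    missing = [
        cell
        for cell in itertools.product(levels_a, levels_b)
        if cell not in counts.index
    ]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    data = table.rename(columns={value: "_y", a: "_fa", b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=data).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)
    df_den = int(anova_table.loc["Residual", "df"])
    mapping = {a: "C(_fa)", b: "C(_fb)", "interaction": "C(_fa):C(_fb)"}
    effects = {
        name: AnovaEffect(
            F=float(anova_table.loc[row, "F"]),
            df_num=int(anova_table.loc[row, "df"]),
            df_den=df_den,
            p=float(anova_table.loc[row, "PR(>F)"]),
        )
        for name, row in mapping.items()
    }
    return AnovaResult(effects=effects)


def tukey_hsd(
    table: pd.DataFrame, factor: str, value: str = "value", alpha: float = 0.05
) -> dict[tuple[str, str], float]:
    """Tukey HSD pairwise p-values for one factor (Tukey-Kramer when
    unbalanced).  Requires at least three groups."""
    if factor not in table.columns or value not in table.columns:
        raise ValueError(f"table lacks column {factor!r} or {value!r}")
    groups = table[factor].astype(str)
    if groups.nunique() < 3:
        raise ValueError("Tukey HSD requires at least 3 groups")
    result = pairwise_tukeyhsd(
        table[value].to_numpy(dtype=float), groups.to_numpy(), alpha=alpha
    )
    pairs = list(itertools.combinations(result.groupsunique, 2))
    return {
        (str(g1), str(g2)): float(p) for (g1, g2), p in zip(pairs, result.pvalues)
    }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    variant: str


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "unequal_variance"
) -> TTestResult:
    """Two-sided two-sample t-test, pooled or Welch (unequal variance).

    Degenerate input with zero variance in both samples and equal means
    returns t = 0, p = 1 by convention.
    """
    if variant not in ("pooled", "unequal_variance"):
        raise ValueError("variant must be 'pooled' or 'unequal_variance'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = variant == "pooled"
    df_pooled = float(a.size + b.size - 2)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TTestResult(t=0.0, df=df_pooled, p=1.0, variant=variant)
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = df_pooled if pooled else float(res.df)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue), variant=variant)


# ---------------------------------------------------------------------------
# Bray-Curtis + ANOSIM
# ---------------------------------------------------------------------------


def relative_abundance(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Row-normalize a samples x taxa count matrix to relative abundances."""
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals.ravel() <= 0))
        raise ValueError(f"sample {bad} has zero total abundance")
    return x / totals


def bray_curtis(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa matrix.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); symmetric, zero diagonal,
    entries in [0, 1].  An all-zero sample is refused by name/index because
    its dissimilarity to anything is undefined.
    """
    if isinstance(matrix, pd.DataFrame):
        ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if x.ndim != 2:
        raise ValueError("community matrix must be 2-D (samples x taxa)")
    if np.any(x < 0):
        raise ValueError("community matrix entries must be non-negative")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero sample: {ids[zero_rows[0]]!r}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i + 1 :] - x[i]).sum(axis=1)
        total = (x[i + 1 :] + x[i]).sum(axis=1)
        d[i, i + 1 :] = diff / total
    return d + d.T


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int | None
    mean_between_rank: float
    mean_within_rank: float
    method: str = "permutation"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.R <= 1.0 + 1e-12:
            raise ValueError("R must lie in [-1, 1]")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dissimilarity: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities on a square dissimilarity matrix.

    With ``exact=True`` all distinct label assignments are enumerated
    (feasible for small n) and the p-value is the exact tail fraction
    including the observed assignment; otherwise ``n_permutations`` seeded
    label permutations give p = (#{R_perm >= R_obs} + 1) / (n_perm + 1).
    """
    d = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity must be square")
    if labels.shape != (n,):
        raise ValueError("labels must match the matrix dimension")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    uniques, group_sizes = np.unique(labels, return_counts=True)
    if uniques.size < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if np.any(group_sizes < 2):
        lonely = uniques[group_sizes < 2][0]
        raise ValueError(f"group {lonely!r} has fewer than 2 samples")
    if not exact and n_permutations < 99:
        raise ValueError("use at least 99 permutations")

    iu, ju = np.triu_indices(n, k=1)
    ranks = sps.rankdata(d[iu, ju])  # average ranks on ties
    m = ranks.size  # n(n-1)/2
    denom = m / 2.0  # == n(n-1)/4, bounds R to [-1, 1]

    codes = np.searchsorted(uniques, labels)
    observed = _anosim_r(ranks, codes[iu] == codes[ju], denom)

    if exact:
        seen: set[tuple[int, ...]] = set()
        at_least = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            perm_arr = np.asarray(perm)
            if _anosim_r(ranks, perm_arr[iu] == perm_arr[ju], denom) >= observed - 1e-12:
                at_least += 1
        total = len(seen)
        return AnosimResult(
            R=observed,
            p=at_least / total,
            n_permutations=total,
            seed=None,
            mean_between_rank=float(ranks[~(codes[iu] == codes[ju])].mean()),
            mean_within_rank=float(ranks[codes[iu] == codes[ju]].mean()),
            method="exact",
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _anosim_r(ranks, perm[iu] == perm[ju], denom) >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(
        R=observed,
        p=p,
        n_permutations=n_permutations,
        seed=seed,
        mean_between_rank=float(ranks[~(codes[iu] == codes[ju])].mean()),
        mean_within_rank=float(ranks[codes[iu] == codes[ju]].mean()),
        method="permutation",
    )
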