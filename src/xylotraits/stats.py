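"""Group statistics: one-way ANOVA, Tukey HSD with compact letters, Pearson
correlations and ordinary least-squares regression.

Mirrors the usual reporting style of treatment-comparison tables in plant
science: per-group mean ± standard error, an ANOVA p value per trait, and
compact letter display (CLD) codes where groups sharing a letter do not
differ significantly under Tukey's HSD at the chosen alpha.  Unbalanced
groups are handled by the Tukey–Kramer adjustment (delegated to scipy).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "RegressionFit",
    "TukeyResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "pearson_matrix",
    "fit_regression",
    "group_summary",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class TukeyResult:
    """Pairwise Tukey HSD decisions plus compact letters.

    ``pvalues`` is a symmetric DataFrame indexed by group; ``significant``
    the corresponding boolean decision matrix at ``alpha``; ``letters`` maps
    group → letter string such that two groups share at least one letter iff
    their pairwise difference is non-significant.
    """

    groups: list[str]
    means: pd.Series
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    letters: dict[str, str]
    alpha: float


@dataclass
class GroupSummary:
    """Per-group mean/SE/n with ANOVA and Tukey letters for one trait."""

    table: pd.DataFrame  # index group; columns mean, se, n, letters
    anova_f: float
    anova_p: float
    alpha: float


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in groups]
    for g, s in zip(groups, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        if np.any(~np.isfinite(s)):
            raise ValueError(f"group {g!r} contains non-finite values")
    return groups, samples


def one_way_anova(values, labels) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    Degenerate groupings (fewer than two groups, or any group with n < 2)
    raise ``ValueError``.  With zero within-group variance and identical
    means F is 0 by convention.
    """
    _, samples = _split_groups(values, labels)
    allv = np.concatenate(samples)
    if np.allclose(allv, allv[0]):
        return 0.0, 1.0
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(values, labels, alpha: float = 0.05) -> TukeyResult:
    """Tukey's HSD over all group pairs plus a compact letter display.

    Uses the studentized-range distribution (Tukey–Kramer for unequal group
    sizes).  Letters are assigned by insert-and-absorb so that any two groups
    share ≥ 1 letter iff their pairwise test is non-significant.
    """
    groups, samples = _split_groups(values, labels)
    res = sps.tukey_hsd(*samples)
    k = len(groups)
    pmat = pd.DataFrame(np.asarray(res.pvalue, dtype=float), index=groups, columns=groups)
    sig = (pmat < alpha) & ~np.eye(k, dtype=bool)
    sig = pd.DataFrame(sig.values if isinstance(sig, pd.DataFrame) else sig, index=groups, columns=groups)
    means = pd.Series([s.mean() for s in samples], index=groups, dtype=float)
    letters = compact_letter_display(sig, means)
    return TukeyResult(groups=groups, means=means, pvalues=pmat, significant=sig, letters=letters, alpha=alpha)


def compact_letter_display(significant: pd.DataFrame, means: pd.Series) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` is a symmetric boolean matrix (True = groups differ).
    Letters are ordered so that 'a' goes to the group with the largest mean.
    Guarantees: two groups share a letter iff their pairwise difference is
    non-significant.
    """
    order = list(means.sort_values(ascending=False).index)
    sig = significant.loc[order, order].to_numpy()
    k = len(order)
    # columns = candidate letter sets, start with one set containing everyone
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                a, b = col - {j}, col - {i}
                # absorb: only keep sets not contained in an existing one
                for new in (a, b):
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # drop columns that are subsets of others (absorption may leave some)
    columns = [c for c in columns if not any(c < other for other in columns)]
    # stable ordering: by first (highest-mean) member
    columns.sort(key=lambda c: (min(c), -len(c)))
    alphabet = string.ascii_lowercase
    if len(columns) > len(alphabet):
        raise RuntimeError("more letter groups than letters available")
    letters = {g: "" for g in order}
    for li, col in enumerate(columns):
        for idx in sorted(col):
            letters[order[idx]] += alphabet[li]
    return letters


def pearson_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p over the numeric columns of ``df``.

    Pairwise-complete observations; pairs with < 3 complete cases or a
    constant column get NaN (reported missing, never zero).
    """
    cols = df.select_dtypes(include=[np.number]).columns
    r = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    p = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            x, y = df[ci], df[cj]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            xv, yv = x[ok].to_numpy(float), y[ok].to_numpy(float)
            if np.std(xv) == 0 or np.std(yv) == 0:
                if ci == cj and np.std(xv) > 0:
                    r.loc[ci, cj] = 1.0
                continue
            rv, pv = sps.pearsonr(xv, yv)
            r.loc[ci, cj] = r.loc[cj, ci] = float(rv)
            p.loc[ci, cj] = p.loc[cj, ci] = float(pv)
    return r, p


def fit_regression(x, y) -> RegressionFit:
    """Ordinary least squares y on x; r² is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def group_summary(values, labels, alpha: float = 0.05) -> GroupSummary:
    """Mean ± SE per group with ANOVA F/p and Tukey compact letters."""
    groups, samples = _split_groups(values, labels)
    f, p = one_way_anova(values, labels)
    tk = tukey_hsd(values, labels, alpha=alpha)
    rows = []
    for g, s in zip(groups, samples):
        rows.append(
            {
                "group": g,
                "mean": float(s.mean()),
                "se": float(s.std(ddof=1) / np.sqrt(s.size)),
                "n": int(s.size),
                "letters": tk.letters[g],
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return GroupSummary(table=table, anova_f=f, anova_p=p, alpha=alpha)
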