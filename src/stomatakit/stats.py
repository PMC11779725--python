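"""Hybrid-vs-parent statistics for stomatal trait tables.

Pearson correlation matrices with t-distribution p-values, one-way
ANOVA with Tukey HSD and a compact letter display (CLD), z-score PCA on
the trait correlation matrix with variance contributions, and heterosis
rates comparing an F1 hybrid against its parental inbred lines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scistats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import TRAIT_COLUMNS, TraitTable

__all__ = ["CorrMatrix", "CLDResult", "PCAResult", "HeterosisResult",
           "pearson_matrix", "anova_cld", "pca_traits", "heterosis_rates"]


def _as_trait_frame(table: TraitTable | pd.DataFrame, columns: list[str] | None) -> pd.DataFrame:
    df = table.df if isinstance(table, TraitTable) else table
    if columns is None:
        columns = [c for c in TRAIT_COLUMNS if c in df.columns] or list(df.select_dtypes("number").columns)
    return df[columns].astype(float)


@dataclass(frozen=True)
class CorrMatrix:
    """Pairwise Pearson r and two-sided p-values over trait columns."""

    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    undefined: dict[tuple[str, str], str] = field(default_factory=dict)


def pearson_matrix(table: TraitTable | pd.DataFrame, columns: list[str] | None = None) -> CorrMatrix:
    """Pearson correlation matrix with per-pair complete-case handling.

    p-values come from the t statistic r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  Pairs involving a zero-variance trait are
    reported as missing with a reason instead of a spurious value.
    """
    data = _as_trait_frame(table, columns)
    cols = list(data.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    undefined: dict[tuple[str, str], str] = {}
    for i, j in itertools.combinations(range(k), 2):
        sub = data.iloc[:, [i, j]].dropna()
        n = len(sub)
        if n < 3:
            undefined[(cols[i], cols[j])] = f"only {n} complete cases"
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            p.iloc[i, j] = p.iloc[j, i] = np.nan
            continue
        x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            undefined[(cols[i], cols[j])] = "zero variance"
            r.iloc[i, j] = r.iloc[j, i] = np.nan
            p.iloc[i, j] = p.iloc[j, i] = np.nan
            continue
        xm, ym = x - x.mean(), y - y.mean()
        rij = float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))
        rij = max(-1.0, min(1.0, rij))
        if abs(rij) == 1.0:
            pij = 0.0
        else:
            t = rij * np.sqrt((n - 2) / (1 - rij * rij))
            pij = float(2 * _scistats.t.sf(abs(t), n - 2))
        r.iloc[i, j] = r.iloc[j, i] = rij
        p.iloc[i, j] = p.iloc[j, i] = pij
    return CorrMatrix(cols, r, p, undefined)


# ---------------------------------------------------------------------------
# one-way ANOVA with compact letter display


@dataclass(frozen=True)
class CLDResult:
    """Group means with significance letters: groups sharing a letter are
    not significantly different at the chosen alpha."""

    groups: list[str]          #: ordered by descending mean
    means: dict[str, float]
    letters: dict[str, str]
    f_statistic: float
    p_value: float
    alpha: float
    tukey: pd.DataFrame | None = None


def _insert_absorb_letters(ordered: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Start from one column holding every group; for each significantly
    different pair occupying a common column, split that column in two,
    removing one member from each copy; finally absorb columns that are
    subsets of another.  Letters are assigned a, b, ... in the order of
    the highest-mean member of each column.
    """
    columns: list[set] = [set(ordered)]
    for pair in sorted(significant, key=sorted):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {b})
            columns.append(col - {a})
        # absorb: drop empties, duplicates, and strict subsets
        uniq: list[set] = []
        for c in columns:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < d for d in uniq)]
    rank = {g: i for i, g in enumerate(ordered)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in ordered}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in ordered}


def anova_cld(values, groups, alpha: float = 0.05) -> CLDResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons at ``alpha``,
    summarized as a compact letter display.

    Groups are ordered by descending mean; the top group gets letter
    "a".  Two groups share a letter iff their Tukey comparison is not
    significant.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    names = list(pd.unique(groups))
    if len(names) < 1:
        raise ValueError("no groups")
    samples = {g: values[groups == g] for g in names}
    for g, v in samples.items():
        if len(v) < 1:
            raise ValueError(f"group {g!r} is empty")
    means = {str(g): float(v.mean()) for g, v in samples.items()}
    ordered = [str(g) for g in sorted(names, key=lambda g: -means[str(g)])]
    if len(names) == 1:
        return CLDResult(ordered, means, {ordered[0]: "a"}, float("nan"), float("nan"), alpha)
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("every group needs >= 2 observations for ANOVA/Tukey")
    f_stat, p_val = _scistats.f_oneway(*[samples[g] for g in names])
    tk = pairwise_tukeyhsd(values, groups.astype(str), alpha=alpha)
    tkdf = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    significant = {
        frozenset((str(a), str(b)))
        for a, b, rej in zip(tkdf["group1"], tkdf["group2"], tkdf["reject"])
        if bool(rej)
    }
    letters = _insert_absorb_letters(ordered, significant)
    return CLDResult(ordered, means, letters, float(f_stat), float(p_val), alpha, tkdf)


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA of z-scored traits."""

    traits: list[str]
    eigenvalues: np.ndarray             #: nonincreasing; sums to n_traits
    loadings: np.ndarray                #: columns = components
    contributions: np.ndarray           #: percent variance per component
    cumulative: np.ndarray
    scores: np.ndarray                  #: rows x components


def pca_traits(table: TraitTable | pd.DataFrame, columns: list[str] | None = None) -> PCAResult:
    """PCA on z-scored traits via the correlation-matrix eigendecomposition.

    z-scores use the sample SD (ddof=1); zero-variance traits are
    dropped with a warning.  The sign of each component is fixed so its
    largest-magnitude loading is positive; eigenvalue ties break toward
    lexicographic loading order.  Contributions are eigenvalues as a
    percentage of their total and sum to 100.
    """
    data = _as_trait_frame(table, columns).dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows for PCA")
    sd = data.std(ddof=1)
    keep = [c for c in data.columns if sd[c] > 0]
    dropped = [c for c in data.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping zero-variance trait(s): {', '.join(dropped)}", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need at least 2 traits with nonzero variance")
    Z = (data[keep] - data[keep].mean()) / data[keep].std(ddof=1)
    C = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(-evals, kind="stable")
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    contributions = 100.0 * evals / evals.sum()
    scores = Z.to_numpy() @ evecs
    return PCAResult(keep, evals, evecs, contributions, np.cumsum(contributions), scores)


# ---------------------------------------------------------------------------
# heterosis


@dataclass(frozen=True)
class HeterosisResult:
    """Heterosis rates of an F1 hybrid trait mean against its parents.

    ``mid_parent_rate`` compares F1 with the parental mean;
    ``over_high_parent_rate`` and ``over_low_parent_rate`` compare with
    the better and worse parent ("super parental" heterosis in either
    direction can be read off whichever convention is wanted).
    """

    trait: str
    f1: float
    p1: float
    p2: float
    mid_parent_rate: float
    over_high_parent_rate: float
    over_low_parent_rate: float


def heterosis_rates(f1: float, p1: float, p2: float, trait: str = "") -> HeterosisResult:
    """Compute mid-parent and over-high/low-parent heterosis rates.

    mid = (F1 - MP)/MP with MP = (P1+P2)/2; over_high uses max(P1, P2),
    over_low uses min(P1, P2).  All three are scale-invariant.  Parent
    means must be positive (rates are relative changes).
    """
    if p1 <= 0 or p2 <= 0:
        raise ValueError("parent means must be positive")
    mp = (p1 + p2) / 2
    hi, lo = max(p1, p2), min(p1, p2)
    return HeterosisResult(
        trait=trait, f1=f1, p1=p1, p2=p2,
        mid_parent_rate=(f1 - mp) / mp,
        over_high_parent_rate=(f1 - hi) / hi,
        over_low_parent_rate=(f1 - lo) / lo,
    )
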