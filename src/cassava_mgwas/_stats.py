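"""Shared small statistics: Pearson tests, pairwise Welch + BH, letter display."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided t-based P on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan, np.nan
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def pairwise_welch(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise Welch t-tests with BH adjustment.

    Groups with fewer than 2 observations must be excluded by the caller.
    """
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if np.array_equal(a, b):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"group1": names[i], "group2": names[j], "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows, columns=["group1", "group2", "t", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    else:
        df["p_adj"] = []
    return df


def compact_letters(
    names: list[str], pairs: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Greedy compact-letter display from a pairwise significance table.

    Two groups share a letter iff they are not significantly different
    (adjusted P >= alpha). Letters are assigned by greedily growing cliques of
    mutually non-different groups in input order.
    """
    differ = set()
    for _, row in pairs.iterrows():
        if row["p_adj"] < alpha:
            differ.add(frozenset((row["group1"], row["group2"])))

    def same(a: str, b: str) -> bool:
        return frozenset((a, b)) not in differ

    cliques: list[list[str]] = []
    for g in names:
        placed = False
        for c in cliques:
            if all(same(g, h) for h in c):
                c.append(g)
                placed = True
        if not placed:
            cliques.append([g])
    # drop cliques fully contained in another
    keep = []
    for i, c in enumerate(cliques):
        if not any(i != j and set(c) <= set(d) for j, d in enumerate(cliques)):
            keep.append(c)
    letters = {g: "" for g in names}
    for letter, c in zip("abcdefghijklmnopqrstuvwxyz", keep):
        for g in c:
            letters[g] += letter
    return letters


def group_contrast_table(
    groups: dict[str, np.ndarray], alpha: float = 0.05, min_n: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group descriptives + pairwise Welch/BH tests with compact letters.

    Groups with n < min_n are reported descriptively but excluded from tests.
    Returns (summary, pairwise) frames.
    """
    tested = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= min_n}
    pairs = pairwise_welch(tested)
    letters = compact_letters(list(tested), pairs, alpha) if len(tested) > 1 else {
        k: "a" for k in tested
    }
    rows = []
    for name, v in groups.items():
        v = np.asarray(v, float)
        rows.append(
            {
                "group": name,
                "n": len(v),
                "mean": float(np.mean(v)) if len(v) else np.nan,
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                "letters": letters.get(name, ""),
                "tested": name in tested,
            }
        )
    return pd.DataFrame(rows), pairs
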