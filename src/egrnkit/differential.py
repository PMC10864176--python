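"""Differential expression/accessibility testing and consensus marker calling.

Implements group-vs-rest Wilcoxon rank-sum markers with min.pct/log-fold
filters, one-way ANOVA markers, Welch t-test differentially accessible
regions (DARs) with the strict p < 1e-3 / log2FC >= 1 / top-5000 filter, a
top-N consensus across marker tables from different methods, and one-sided
Fisher set enrichment with BH adjustment.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_qvalues

__all__ = [
    "wilcoxon_markers",
    "anova_markers",
    "consensus_top200",
    "dar_ttest",
    "fisher_enrichment",
    "rank_marker_table",
]

_EPS = 1e-9


def _as_groups(labels, columns) -> dict:
    labels = pd.Series(labels)
    missing = columns.difference(labels.index)
    if len(missing):
        raise ValueError(f"nuclei without labels: {list(missing[:5])}")
    lab = labels.loc[columns]
    return {g: np.where((lab == g).to_numpy())[0] for g in sorted(lab.unique(), key=str)}


def _log2fc_expm1(norm1: np.ndarray, norm2: np.ndarray) -> np.ndarray:
    """log2 fold change of group means on the expm1 (linear) scale."""
    m1 = np.expm1(norm1).mean(axis=1)
    m2 = np.expm1(norm2).mean(axis=1)
    return np.log2((m1 + _EPS) / (m2 + _EPS))


def rank_marker_table(table: pd.DataFrame) -> pd.DataFrame:
    """Total rank per group: p ascending, |log2FC| descending, feature id."""
    t = table.copy()
    t["_abs_lfc"] = t.log2fc.abs()
    t = t.sort_values(["group", "p", "_abs_lfc", "feature"],
                      ascending=[True, True, False, True], kind="stable")
    t["rank"] = t.groupby("group").cumcount() + 1
    return t.drop(columns="_abs_lfc").reset_index(drop=True)


def wilcoxon_markers(norm_counts: pd.DataFrame, labels, min_pct: float = 0.1,
                     logfc_min: float = 0.25, method: str = "asymptotic") -> pd.DataFrame:
    """Group-vs-rest Wilcoxon rank-sum markers on normalized (log1p) values.

    Features are tested only if expressed in >= ``min_pct`` of nuclei on at
    least one side and log2FC >= ``logfc_min`` (fold change of expm1-scale
    means). ``method`` is 'asymptotic' (normal approximation with tie
    correction) or 'exact' (small groups, no ties). Groups with < 2 nuclei
    are skipped with a warning.
    """
    groups = _as_groups(labels, norm_counts.columns)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    x = norm_counts.to_numpy(dtype=float)
    rows = []
    for g, idx in groups.items():
        rest = np.setdiff1d(np.arange(x.shape[1]), idx)
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has < 2 nuclei; skipped")
            continue
        x1, x2 = x[:, idx], x[:, rest]
        pct1 = (x1 > 0).mean(axis=1)
        pct2 = (x2 > 0).mean(axis=1)
        lfc = _log2fc_expm1(x1, x2)
        keep = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (lfc >= logfc_min)
        if not keep.any():
            continue
        res = stats.mannwhitneyu(x1[keep], x2[keep], axis=1,
                                 alternative="two-sided", method=method)
        sub = pd.DataFrame(
            {
                "feature": norm_counts.index[keep],
                "group": g,
                "log2fc": lfc[keep],
                "pct_group": pct1[keep],
                "pct_rest": pct2[keep],
                "p": np.atleast_1d(res.pvalue),
            }
        )
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["feature", "group", "log2fc", "pct_group", "pct_rest", "p", "q", "rank"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["q"] = bh_qvalues(out.p.to_numpy())
    return rank_marker_table(out)


def anova_markers(norm_counts: pd.DataFrame, labels, fc_min: float = 0.5,
                  p_max: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA markers across all groups.

    A feature is reported for a group when the across-group F-test has
    p < ``p_max`` and the group-vs-rest |log2FC| exceeds ``fc_min``. Features
    with zero variance within every group are flagged (p = NaN), not errors.
    """
    groups = _as_groups(labels, norm_counts.columns)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    x = norm_counts.to_numpy(dtype=float)
    samples = [x[:, idx] for idx in groups.values()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs yield NaN F, flagged below
        f, p = stats.f_oneway(*samples, axis=1)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    rows = []
    for g, idx in groups.items():
        rest = np.setdiff1d(np.arange(x.shape[1]), idx)
        lfc = _log2fc_expm1(x[:, idx], x[:, rest])
        keep = (p < p_max) & (np.abs(lfc) > fc_min)
        flagged = ~np.isfinite(p)
        sub = pd.DataFrame(
            {
                "feature": norm_counts.index,
                "group": g,
                "log2fc": lfc,
                "pct_group": (x[:, idx] > 0).mean(axis=1),
                "pct_rest": (x[:, rest] > 0).mean(axis=1),
                "p": p,
                "degenerate": flagged,
            }
        )
        rows.append(sub[keep | flagged])
    out = pd.concat(rows, ignore_index=True)
    out["q"] = bh_qvalues(np.nan_to_num(out.p.to_numpy(), nan=1.0))
    return rank_marker_table(out.fillna({"p": 1.0}))


def consensus_top200(tables: list[pd.DataFrame], top_n: int = 200,
                     group: str | None = None) -> set:
    """Features shared by the top ``top_n`` of every ranked marker table.

    Tables come from different testing methods over the same feature
    universe; each is truncated under its own rank order (shorter tables are
    used whole, with a warning). Optionally restricted to one group label.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 marker tables for a consensus")
    tops = []
    for t in tables:
        sub = t[t.group == group] if group is not None else t
        sub = sub.sort_values("rank", kind="stable") if "rank" in sub.columns else sub
        if len(sub) < top_n:
            warnings.warn(f"marker table has only {len(sub)} rows (< top_n={top_n})")
        tops.append(set(sub.feature.head(top_n)))
    return set.intersection(*tops)


def dar_ttest(peak_counts: pd.DataFrame, labels, p_max: float = 1e-3,
              log2fc_min: float = 1.0, top_k: int = 5000) -> dict:
    """Differentially accessible regions per group (group vs rest, Welch t).

    Operates on the raw peak count matrix. Keeps peaks with p < ``p_max``
    and log2FC >= ``log2fc_min`` (raw-mean fold change), ranked by p
    ascending then |log2FC| descending then id, truncated to ``top_k``.
    Returns {group: DataFrame}.
    """
    groups = _as_groups(labels, peak_counts.columns)
    x = peak_counts.to_numpy(dtype=float)
    out = {}
    for g, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has < 2 nuclei; skipped for DARs")
            continue
        rest = np.setdiff1d(np.arange(x.shape[1]), idx)
        x1, x2 = x[:, idx], x[:, rest]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
        p = np.nan_to_num(np.atleast_1d(res.pvalue), nan=1.0)
        lfc = np.log2((x1.mean(axis=1) + _EPS) / (x2.mean(axis=1) + _EPS))
        tab = pd.DataFrame(
            {"feature": peak_counts.index, "group": g, "log2fc": lfc, "p": p}
        )
        tab = tab[(tab.p < p_max) & (tab.log2fc >= log2fc_min)]
        tab = rank_marker_table(tab).head(top_k)
        out[g] = tab.reset_index(drop=True)
    return out


def fisher_enrichment(query: set, term_sets: dict, universe: set) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper tail) enrichment per term + BH.

    ``query`` and every term set must be subsets of ``universe``. Returns a
    table with overlap counts, odds ratio, p and BH q, sorted by p.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n_q = len(query)
    rows = []
    for term, members in term_sets.items():
        members = set(members) & universe
        k = len(query & members)
        n_t = len(members)
        # hypergeometric upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, m, n_t, n_q))
        a, b = k, n_q - k
        c, d = n_t - k, m - n_t - (n_q - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((term, k, n_t, n_q, m, odds, p))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "term_size", "query_size", "universe", "odds_ratio", "p"]
    )
    out["q"] = bh_qvalues(out.p.to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
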