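"""Peak-to-gene link calling.

Candidate peaks are those whose midpoint falls in a symmetric window around a
gene's TSS (default total width 500 kb, i.e. half-width 250 kb). For every
candidate (gene, peak) pair, Pearson correlation between imputed expression
and peak accessibility is computed across paired ATAC nuclei; links are
accepted at r >= 0.45 and Benjamini-Hochberg FDR <= 1e-4 (positive r only by
default, configurable).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_qvalues

__all__ = ["candidate_pairs", "pearson_links", "filter_links", "link_gene_summary"]

logger = logging.getLogger(__name__)

R_MIN_DEFAULT = 0.45
Q_MAX_DEFAULT = 1e-4
HALF_WIDTH_DEFAULT = 250_000


def candidate_pairs(genes: pd.DataFrame, peaks: pd.DataFrame,
                    half_width: int = HALF_WIDTH_DEFAULT) -> pd.DataFrame:
    """All (gene, peak) pairs with peak midpoint in [TSS - hw, TSS + hw).

    ``genes`` needs gene_id/chrom/tss columns; ``peaks`` needs
    peak_id/chrom/start/end. Midpoint is floor((start + end) / 2). Returns a
    DataFrame with gene_id, peak_id and the signed distance midpoint - TSS.
    """
    rows = []
    mids_all = (peaks.start.to_numpy() + peaks.end.to_numpy()) // 2
    for chrom, gsub in genes.groupby("chrom"):
        pmask = (peaks.chrom == chrom).to_numpy()
        if not pmask.any():
            continue
        order = np.argsort(mids_all[pmask], kind="stable")
        mids = mids_all[pmask][order]
        pids = peaks.peak_id.to_numpy()[pmask][order]
        lo = np.searchsorted(mids, gsub.tss.to_numpy() - half_width, side="left")
        hi = np.searchsorted(mids, gsub.tss.to_numpy() + half_width, side="left")
        for g, t, a, b in zip(gsub.gene_id, gsub.tss, lo, hi):
            for j in range(a, b):
                rows.append((g, pids[j], int(mids[j] - t)))
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "distance"])


def pearson_links(imputed: pd.DataFrame, atac: pd.DataFrame,
                  pairs: pd.DataFrame) -> pd.DataFrame:
    """Sample Pearson r and two-sided p for each candidate pair.

    ``imputed`` is gene x nucleus, ``atac`` peak x nucleus, over the same
    nucleus columns (order may differ; aligned by name). p comes from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 df. Pairs with a constant gene or peak
    vector are dropped with a logged reason.
    """
    common = imputed.columns.intersection(atac.columns)
    n = len(common)
    if n < 3:
        raise ValueError(f"need >= 3 shared nuclei for correlation, have {n}")
    genes = pairs.gene_id.unique()
    peaks = pairs.peak_id.unique()
    x = imputed.loc[genes, common].to_numpy(dtype=float)
    y = atac.loc[peaks, common].to_numpy(dtype=float)

    def standardize(m):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        z = np.zeros_like(m)
        z[ok] = (m[ok] - mu[ok]) / sd[ok]
        return z, ok

    zx, okx = standardize(x)
    zy, oky = standardize(y)
    gene_pos = pd.Index(genes).get_indexer(pairs.gene_id)
    peak_pos = pd.Index(peaks).get_indexer(pairs.peak_id)
    r = np.einsum("ij,ij->i", zx[gene_pos], zy[peak_pos]) / n
    r = np.clip(r, -1.0, 1.0)
    keep = okx[gene_pos] & oky[peak_pos]
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d candidate pairs with a constant gene or peak vector", dropped)
    out = pairs.loc[keep].copy().reset_index(drop=True)
    r = r[keep]
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    out["r"] = r
    out["p"] = p
    out["n"] = n
    return out


def filter_links(table: pd.DataFrame, r_min: float = R_MIN_DEFAULT,
                 q_max: float = Q_MAX_DEFAULT, signed: bool = True) -> pd.DataFrame:
    """BH-adjust p over all tested pairs and flag accepted links.

    With ``signed=True`` (default) only positive correlations can be accepted
    (r >= r_min); ``signed=False`` accepts |r| >= r_min. Returns the full
    table with q and accepted columns.
    """
    out = table.copy()
    out["q"] = bh_qvalues(out.p.to_numpy())
    strength = out.r if signed else out.r.abs()
    out["accepted"] = (strength >= r_min) & (out.q <= q_max)
    return out


def link_gene_summary(accepted: pd.DataFrame) -> tuple[pd.Series, float]:
    """Linked-region count per gene (genes with >= 1 accepted link) and the mean.

    The mean regions-per-gene is the statistic reported alongside the total
    number of raw peak-to-gene links.
    """
    sub = accepted[accepted.accepted] if "accepted" in accepted.columns else accepted
    if len(sub) == 0:
        return pd.Series(dtype=int, name="n_links"), float("nan")
    counts = sub.groupby("gene_id").size().rename("n_links")
    return counts, float(counts.mean())
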