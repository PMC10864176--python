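"""Small shared numerics: depth normalization, BH adjustment, seeded streams."""
from __future__ import annotations

import numpy as np
from scipy import sparse
from statsmodels.stats.multitest import multipletests


def depth_normalize_log1p(counts, target_sum: float = 1e4) -> np.ndarray:
    """log1p(counts-per-target_sum) column-wise (columns are nuclei).

    Accepts dense arrays or scipy sparse matrices shaped feature x nucleus;
    returns a dense float array. Zero-depth columns stay all-zero.
    """
    if sparse.issparse(counts):
        counts = counts.toarray()
    x = np.asarray(counts, dtype=float)
    depth = x.sum(axis=0)
    scale = np.divide(target_sum, depth, out=np.zeros_like(depth), where=depth > 0)
    return np.log1p(x * scale[None, :])


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def child_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic sub-stream of a root seed, stable across processes."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))
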