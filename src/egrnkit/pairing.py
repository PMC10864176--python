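"""Cross-modality nucleus pairing and expression imputation.

ATAC nuclei are matched to their nearest RNA nucleus in a shared latent space
(e.g. an iNMF or other joint factorization, supplied as input), and the RNA
expression matrix is copied column-wise onto the ATAC nuclei — no smoothing.
A seeded KNN label-confusion check quantifies how well the two modalities are
aligned in that space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._utils import child_rng

__all__ = [
    "LatentEmbedding",
    "NucleusPairing",
    "pair_nuclei",
    "impute_expression",
    "knn_match_confusion",
]


@dataclass
class LatentEmbedding:
    ids: list
    coords: np.ndarray  # nucleus x dim
    modality: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or len(self.ids) != self.coords.shape[0]:
            raise ValueError("coords must be (n_nuclei, dim) matching ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("nucleus ids must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("latent coordinates must be finite")


@dataclass
class NucleusPairing:
    """ATAC nucleus -> RNA nucleus map; many-to-one is allowed."""

    mapping: pd.Series  # index: atac id, value: rna id
    distance: pd.Series


def _nearest(atac_coords: np.ndarray, rna_coords: np.ndarray, chunk: int = 512):
    """Exact nearest neighbor; ties resolve to the lowest RNA index (argmin)."""
    idx = np.empty(len(atac_coords), dtype=int)
    dist = np.empty(len(atac_coords))
    for s in range(0, len(atac_coords), chunk):
        d = cdist(atac_coords[s : s + chunk], rna_coords)
        idx[s : s + chunk] = np.argmin(d, axis=1)
        dist[s : s + chunk] = d[np.arange(d.shape[0]), idx[s : s + chunk]]
    return idx, dist


def pair_nuclei(atac: LatentEmbedding, rna: LatentEmbedding) -> NucleusPairing:
    """Map every ATAC nucleus to the Euclidean-nearest RNA nucleus."""
    if atac.coords.shape[1] != rna.coords.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: atac {atac.coords.shape[1]} vs rna {rna.coords.shape[1]}"
        )
    if len(rna.ids) == 0:
        raise ValueError("rna embedding is empty")
    idx, dist = _nearest(atac.coords, rna.coords)
    rna_ids = np.asarray(rna.ids, dtype=object)
    return NucleusPairing(
        mapping=pd.Series(rna_ids[idx], index=pd.Index(atac.ids, name="atac_id"), name="rna_id"),
        distance=pd.Series(dist, index=pd.Index(atac.ids, name="atac_id"), name="distance"),
    )


def impute_expression(expression: pd.DataFrame, pairing: NucleusPairing) -> pd.DataFrame:
    """Gene x ATAC-nucleus matrix: each column copied from the paired RNA column."""
    missing = pd.Index(pairing.mapping.unique()).difference(expression.columns)
    if len(missing):
        raise KeyError(f"paired RNA nuclei missing from expression matrix: {list(missing[:5])}")
    out = expression.loc[:, pairing.mapping.to_numpy()]
    out.columns = pairing.mapping.index
    return out


def knn_match_confusion(atac: LatentEmbedding, rna: LatentEmbedding,
                        labels_atac: pd.Series | dict, labels_rna: pd.Series | dict,
                        n_sample: int = 50, seed: int = 0):
    """Sample ATAC nuclei, find each one's nearest RNA nucleus, tally labels.

    Returns ``(confusion, match_rate)``: a label x label count table (rows =
    sampled ATAC labels, columns = matched RNA labels) and the fraction of
    sampled nuclei whose matched RNA nucleus carries the identical label.
    """
    labels_atac = pd.Series(labels_atac)
    labels_rna = pd.Series(labels_rna)
    if not set(atac.ids) <= set(labels_atac.index):
        raise ValueError("labels_atac does not cover all ATAC nuclei")
    if not set(rna.ids) <= set(labels_rna.index):
        raise ValueError("labels_rna does not cover all RNA nuclei")
    if n_sample > len(atac.ids):
        raise ValueError(f"n_sample={n_sample} exceeds {len(atac.ids)} available nuclei")
    rng = child_rng(seed, 6)
    pick = np.sort(rng.choice(len(atac.ids), size=n_sample, replace=False))
    sub = LatentEmbedding([atac.ids[i] for i in pick], atac.coords[pick], atac.modality)
    pairing = pair_nuclei(sub, rna)
    la = labels_atac.loc[pairing.mapping.index].to_numpy()
    lr = labels_rna.loc[pairing.mapping.to_numpy()].to_numpy()
    confusion = pd.crosstab(
        pd.Series(la, name="atac_label"), pd.Series(lr, name="rna_label")
    )
    match_rate = float((la == lr).mean())
    return confusion, match_rate
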