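"""Readers and writers for the on-disk formats.

Conventions: Matrix Market counts are feature x nucleus with 1-based indices
on disk and 0-based in memory (scipy handles the shift); BED is 0-based
half-open; all tables are TSV. The fixture layout written by
:func:`write_fixture` is byte-deterministic for a fixed (config, seed).
"""
from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import GroundTruth, PairedMultiome, SimConfig

__all__ = [
    "read_counts",
    "write_counts",
    "read_bed",
    "write_bed",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "write_fixture",
    "read_fixture",
]


def write_counts(directory, matrix, features, barcodes) -> None:
    """Write a feature x nucleus sparse matrix as matrix.mtx + two TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = sparse.coo_matrix(matrix)
    spio.mmwrite(str(directory / "matrix.mtx"), m, field="integer")
    pd.Series(list(features)).to_csv(directory / "features.tsv", sep="\t",
                                     index=False, header=False)
    pd.Series(list(barcodes)).to_csv(directory / "barcodes.tsv", sep="\t",
                                     index=False, header=False)


def read_counts(directory):
    """Read matrix.mtx + features.tsv + barcodes.tsv; returns (csr, features, barcodes)."""
    directory = Path(directory)
    m = spio.mmread(str(directory / "matrix.mtx")).tocsr()
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if m.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix shape {m.shape} does not match {len(features)} features x "
            f"{len(barcodes)} barcodes"
        )
    return m, features, barcodes


def write_bed(path, intervals: pd.DataFrame) -> None:
    """BED3+name(+strand); 0-based half-open coordinates."""
    cols = ["chrom", "start", "end"]
    out = intervals[cols].copy()
    if "id" in intervals.columns:
        out["name"] = intervals["id"]
    elif "peak_id" in intervals.columns:
        out["name"] = intervals["peak_id"]
    if "strand" in intervals.columns:
        out["score"] = 0
        out["strand"] = intervals["strand"]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ with per-line validation; malformed records name the line."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["id"] = parts[3]
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    return pd.DataFrame(rows)


def write_tsv_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------


def write_fixture(pm: PairedMultiome, truth: GroundTruth, config: SimConfig,
                  directory, overwrite: bool = False) -> None:
    """Write the full synthetic dataset + ground truth as a text fixture.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set. Identical (config, seed) produce byte-identical
    files.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is not empty (use overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    for modality in ("rna", "atac"):
        adata: ad.AnnData = getattr(pm, modality)
        write_counts(directory / modality, adata.X.T, adata.var_names, adata.obs_names)
        obs = adata.obs.copy()
        obs.to_csv(directory / f"{modality}_labels.tsv", sep="\t")
        latent = pd.DataFrame(
            adata.obsm["X_latent"], index=adata.obs_names,
            columns=[f"dim{i}" for i in range(adata.obsm["X_latent"].shape[1])],
        )
        write_tsv_matrix(directory / f"{modality}_latent.tsv", latent)

    write_bed(directory / "peaks.bed", pm.peaks.rename(columns={"peak_id": "id"}))
    pm.peaks.to_csv(directory / "peaks.tsv", sep="\t", index=False)
    pm.genes[["chrom", "tss", "strand", "gene_id", "start", "end", "role"]].to_csv(
        directory / "genes.tsv", sep="\t", index=False
    )
    pm.motif_hits.to_csv(directory / "motif_hits.tsv", sep="\t", index=False,
                         float_format="%.10g")
    if pm.motif_annotation is not None:
        pm.motif_annotation.to_csv(directory / "motif_annotation.tsv", sep="\t", index=False)

    truth.program_table.to_csv(directory / "truth_programs.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_links), columns=["peak_id", "gene_id"]).to_csv(
        directory / "truth_links.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.motif_truth.items()), columns=["motif_id", "tf_gene"]
    ).to_csv(directory / "truth_motifs.tsv", sep="\t", index=False)
    truth.cluster_table.to_csv(directory / "truth_clusters.tsv", sep="\t", index=False)

    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"format": "egrnkit-fixture-v1", "config": config.to_dict()}, fh)


def read_fixture(directory):
    """Load a fixture written by :func:`write_fixture`.

    Returns ``(PairedMultiome, GroundTruth, SimConfig)``.
    """
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = SimConfig(**manifest["config"])

    adatas = {}
    for modality in ("rna", "atac"):
        m, features, barcodes = read_counts(directory / modality)
        obs = pd.read_csv(directory / f"{modality}_labels.tsv", sep="\t", index_col=0)
        latent = read_tsv_matrix(directory / f"{modality}_latent.tsv")
        adata = ad.AnnData(
            X=m.T.tocsr(),
            obs=obs.loc[barcodes],
            var=pd.DataFrame(index=pd.Index(features)),
        )
        adata.obsm["X_latent"] = latent.loc[barcodes].to_numpy()
        adatas[modality] = adata

    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    peaks = pd.read_csv(directory / "peaks.tsv", sep="\t")
    motif_hits = pd.read_csv(directory / "motif_hits.tsv", sep="\t")
    annot_path = directory / "motif_annotation.tsv"
    motif_annotation = pd.read_csv(annot_path, sep="\t") if annot_path.exists() else None
    adatas["rna"].var = genes.set_index("gene_id").loc[adatas["rna"].var_names]
    adatas["atac"].var = peaks.set_index("peak_id").loc[adatas["atac"].var_names]
    pm = PairedMultiome(adatas["rna"], adatas["atac"], genes, peaks, motif_hits,
                        motif_annotation)

    programs = pd.read_csv(directory / "truth_programs.tsv", sep="\t")
    links = pd.read_csv(directory / "truth_links.tsv", sep="\t")
    motifs = pd.read_csv(directory / "truth_motifs.tsv", sep="\t")
    clusters = pd.read_csv(directory / "truth_clusters.tsv", sep="\t")
    truth = GroundTruth(
        planted_links=set(map(tuple, links.to_numpy())),
        planted_programs={
            (r.tf_gene, r.enhancer_peak, r.target_gene) for r in programs.itertuples()
        },
        motif_truth=dict(zip(motifs.motif_id, motifs.tf_gene)),
        tf_home_cluster=dict(
            programs.drop_duplicates("tf_gene")[["tf_gene", "home_cluster"]].to_numpy()
        ),
        program_table=programs,
        cluster_table=clusters,
        decoy_motifs=[f"decoy_motif_{i:03d}" for i in range(config.decoy_motifs)],
    )
    return pm, truth, config
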