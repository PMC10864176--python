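"""Synthetic paired snRNA-seq / snATAC-seq generator with planted ground truth.

The generator emulates the structure of a single-nucleus multiome experiment on
a differentiating tissue: nuclei sit on a bifurcating low-dimensional
trajectory (a progenitor root splitting into two mature branches), RNA counts
are negative-binomial and ATAC counts Poisson, both driven by the same latent
process so a shared embedding exists across modalities, and a configurable
number of TF programs are planted: each TF drives the accessibility of
enhancer peaks placed near its target genes' TSSs and the expression of those
targets, with motif hits planted in the enhancer peaks. Every planted object
is recorded in a :class:`GroundTruth` so downstream recovery can be scored.

Everything is a deterministic function of ``(SimConfig, seed)``; per-operation
substreams are derived from the root seed so operations can be re-run
independently.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from ._utils import child_rng

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PairedMultiome",
    "TrajectoryLatent",
    "Programs",
    "simulate_trajectory_latent",
    "plant_regulatory_program",
    "simulate_counts",
    "simulate_multiome",
    "simulate_fragments",
]


class PlacementError(RuntimeError):
    """Genomic feature placement is infeasible for the given configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired multiome dataset.

    Counts and depths are deliberately desk-scale; genomic coordinates are
    0-based half-open on a single synthetic chromosome.
    """

    n_rna_nuclei: int = 400
    n_atac_nuclei: int = 400
    n_genes: int = 300
    n_peaks: int = 1200
    n_tf_programs: int = 3
    targets_per_tf: int = 8
    enhancers_per_target: int = 2
    n_clusters: int = 6
    bifurcating: bool = True
    latent_dim: int = 10
    noise_sd: float = 0.1
    rna_depth_mean: float = 5000.0
    atac_depth_mean: float = 1500.0
    nb_dispersion: float = 2.0
    poisson_rna: bool = False
    chrom_length: int = 200_000_000
    window_half_width: int = 250_000
    decoy_motifs: int = 50
    program_effect: float = 16.0
    enhancer_base_floor: float = 1.0
    decoy_inside_fraction: float = 0.5
    root_fraction: float = 0.35
    path_length: float = 6.0
    branch_angle_deg: float = 60.0
    peak_width: int = 500
    gene_length: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_rna_nuclei": self.n_rna_nuclei,
            "n_atac_nuclei": self.n_atac_nuclei,
            "n_genes": self.n_genes,
            "n_peaks": self.n_peaks,
            "n_tf_programs": self.n_tf_programs,
            "targets_per_tf": self.targets_per_tf,
            "enhancers_per_target": self.enhancers_per_target,
            "n_clusters": self.n_clusters,
            "latent_dim": self.latent_dim,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2 (trajectory lives in a plane)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.window_half_width <= 0:
            raise ValueError("window_half_width must be positive")
        if not 0 < self.root_fraction < 1:
            raise ValueError("root_fraction must be in (0, 1)")
        n_program_genes = self.n_tf_programs * (1 + self.targets_per_tf)
        if n_program_genes > self.n_genes:
            raise ValueError(
                f"need {n_program_genes} genes for the TF programs, have {self.n_genes}"
            )
        n_enh = self.n_tf_programs * self.targets_per_tf * self.enhancers_per_target
        if n_enh > self.n_peaks:
            raise ValueError(f"need {n_enh} enhancer peaks, have {self.n_peaks}")
        if self.bifurcating and self.n_clusters < 3:
            raise ValueError("a bifurcating trajectory needs >= 3 clusters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# trajectory latent space
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryLatent:
    """Latent coordinates plus per-nucleus trajectory truth for both modalities."""

    rna_coords: np.ndarray
    atac_coords: np.ndarray
    rna_obs: pd.DataFrame  # index nucleus id; true_pseudotime, true_branch, true_cluster
    atac_obs: pd.DataFrame
    cluster_table: pd.DataFrame  # cluster, branch, t_lo, t_hi
    config: SimConfig


def _path_point(t: np.ndarray, branch: np.ndarray, config: SimConfig) -> np.ndarray:
    """Noise-free latent position for arc-length fraction t on a given branch."""
    d = config.latent_dim
    s = np.asarray(t, dtype=float) * config.path_length
    l_root = config.root_fraction * config.path_length
    theta = np.deg2rad(config.branch_angle_deg)
    out = np.zeros((len(s), d))
    on_root = s <= l_root
    out[on_root, 0] = s[on_root]
    past = ~on_root
    if past.any():
        extra = s[past] - l_root
        if config.bifurcating:
            sign = np.where(np.asarray(branch)[past] == "B", -1.0, 1.0)
        else:
            sign = np.zeros(past.sum())
            theta = 0.0
        out[past, 0] = l_root + extra * np.cos(theta)
        out[past, 1] = sign * extra * np.sin(theta)
    return out


def cluster_scheme(config: SimConfig) -> pd.DataFrame:
    """Deterministic partition of the trajectory into labeled clusters.

    Root clusters tile [0, root_fraction); each branch gets its own tiles of
    [root_fraction, 1]. Cluster names are c0, c1, ... ordered root, branch A,
    branch B.
    """
    k = config.n_clusters
    if config.bifurcating:
        n_root = max(1, min(k - 2, int(round(k * config.root_fraction))))
        n_branch = k - n_root
        n_a = (n_branch + 1) // 2
        n_b = n_branch - n_a
    else:
        n_root, n_a, n_b = k, 0, 0
    rows = []
    edges = np.linspace(0.0, config.root_fraction if config.bifurcating else 1.0, n_root + 1)
    for i in range(n_root):
        rows.append(("root", edges[i], edges[i + 1]))
    for name, n_c in (("A", n_a), ("B", n_b)):
        edges = np.linspace(config.root_fraction, 1.0, n_c + 1)
        for i in range(n_c):
            rows.append((name, edges[i], edges[i + 1]))
    df = pd.DataFrame(rows, columns=["branch", "t_lo", "t_hi"])
    df.insert(0, "cluster", [f"c{i}" for i in range(len(df))])
    return df


def _assign_clusters(t: np.ndarray, branch: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    labels = np.empty(len(t), dtype=object)
    for row in table.itertuples():
        if row.branch == "root":
            mask = (t >= row.t_lo) & (t < row.t_hi)
        else:
            mask = (branch == row.branch) & (t >= row.t_lo) & (t <= row.t_hi)
        labels[mask] = row.cluster
    # numerical edge: t exactly at root_fraction boundary
    unassigned = labels == None  # noqa: E711
    if unassigned.any():
        last_root = table[table.branch == "root"].iloc[-1].cluster
        labels[unassigned] = last_root
    return labels.astype(str)


def _simulate_one_modality(config: SimConfig, n: int, prefix: str, rng: np.random.Generator,
                           table: pd.DataFrame):
    t = rng.uniform(0.0, 1.0, size=n)
    if config.bifurcating:
        branch = np.where(
            t <= config.root_fraction, "root", np.where(rng.random(n) < 0.5, "A", "B")
        ).astype(object)
    else:
        branch = np.array(["A"] * n, dtype=object)
        branch[t <= config.root_fraction] = "A"
    coords = _path_point(t, branch, config)
    coords = coords + rng.normal(0.0, config.noise_sd, size=coords.shape)
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    obs = pd.DataFrame(
        {
            "true_pseudotime": t,
            "true_branch": branch.astype(str),
            "true_cluster": _assign_clusters(t, branch, table),
        },
        index=pd.Index(ids, name="nucleus_id"),
    )
    return coords, obs


def simulate_trajectory_latent(config: SimConfig) -> TrajectoryLatent:
    """Draw latent coordinates for both modalities from one trajectory process.

    Pseudotime is arc-length position along root+branch normalized to [0, 1];
    isotropic Gaussian noise of sd ``noise_sd`` is added in all latent
    dimensions. RNA and ATAC nuclei are independent draws from the same
    process, so nearest-neighbor pairing across modalities is meaningful.
    """
    config.validate()
    table = cluster_scheme(config)
    rng_rna = child_rng(config.seed, 1)
    rng_atac = child_rng(config.seed, 2)
    rna_coords, rna_obs = _simulate_one_modality(config, config.n_rna_nuclei, "rna_", rng_rna, table)
    atac_coords, atac_obs = _simulate_one_modality(
        config, config.n_atac_nuclei, "atac_", rng_atac, table
    )
    return TrajectoryLatent(rna_coords, atac_coords, rna_obs, atac_obs, table, config)


# ---------------------------------------------------------------------------
# genomic placement and program planting
# ---------------------------------------------------------------------------


@dataclass
class Programs:
    """Planted TF programs plus the genomic placement of all genes and peaks."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss, role
    peaks: pd.DataFrame  # peak_id, chrom, start, end, kind, tf, target_gene
    program_table: pd.DataFrame  # tf_gene, motif_id, enhancer_peak, target_gene, home_cluster
    motif_hits: pd.DataFrame  # peak_id, motif_id, score
    motif_annotation: pd.DataFrame  # motif_id -> tf_gene, planted + decoys
    motif_truth: dict  # motif_id -> tf gene id (planted motifs only)
    tf_home_cluster: dict  # tf gene id -> cluster label
    config: SimConfig


def _home_cluster_order(table: pd.DataFrame) -> list:
    """Terminal (most mature) branch clusters first, interleaving branches."""
    branches = [b for b in ("A", "B") if (table.branch == b).any()]
    per_branch = {
        b: list(table[table.branch == b].sort_values("t_hi", ascending=False).cluster)
        for b in branches
    }
    order: list = []
    i = 0
    while any(per_branch.values()):
        b = branches[i % len(branches)]
        if per_branch[b]:
            order.append(per_branch[b].pop(0))
        i += 1
        if i > 10 * len(table):
            break
    order += list(table[table.branch == "root"].sort_values("t_hi", ascending=False).cluster)
    return order


def plant_regulatory_program(config: SimConfig) -> Programs:
    """Place genes and peaks on one synthetic chromosome and plant TF programs.

    Genes are spaced so that linkage windows of neighboring genes do not both
    capture a planted enhancer: the spacing must exceed 2.2x the window
    half-width, otherwise a :class:`PlacementError` is raised. Each TF program
    gets ``targets_per_tf`` target genes with ``enhancers_per_target``
    enhancer peaks whose midpoints fall within 80% of the window half-width of
    the target's TSS; enhancer peaks carry a strong hit of the TF's motif.
    Decoy peaks are placed both inside and outside gene windows and carry no
    program. Coordinates are 0-based half-open.
    """
    config.validate()
    rng = child_rng(config.seed, 3)
    w = config.window_half_width
    spacing = config.chrom_length // (config.n_genes + 1)
    if spacing < int(2.2 * w):
        raise PlacementError(
            f"gene spacing {spacing} bp cannot separate {config.n_genes} linkage windows "
            f"of half-width {w} bp on a {config.chrom_length} bp chromosome"
        )

    # --- genes -------------------------------------------------------------
    jitter = rng.integers(-spacing // 50, spacing // 50 + 1, size=config.n_genes)
    tss = spacing * (np.arange(config.n_genes) + 1) + jitter
    strand = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    start = np.where(strand == "+", tss, tss - config.gene_length + 1)
    end = np.where(strand == "+", tss + config.gene_length, tss + 1)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "start": start.astype(int),
            "end": end.astype(int),
            "strand": strand,
            "tss": tss.astype(int),
            "role": "background",
        }
    )

    n_tf = config.n_tf_programs
    n_targets = n_tf * config.targets_per_tf
    # spread program genes over the chromosome deterministically
    order = rng.permutation(config.n_genes)
    tf_idx = order[:n_tf]
    target_idx = order[n_tf : n_tf + n_targets]
    genes.loc[tf_idx, "role"] = "tf"
    genes.loc[target_idx, "role"] = "target"
    tf_genes = [gene_ids[i] for i in tf_idx]

    table = cluster_scheme(config)
    home_order = _home_cluster_order(table)
    tf_home = {tf: home_order[i % len(home_order)] for i, tf in enumerate(tf_genes)}

    # --- enhancer peaks ----------------------------------------------------
    pw = config.peak_width
    max_off = int(0.8 * w) - pw
    peak_rows = []
    program_rows = []
    k = 0
    for p, tf in enumerate(tf_genes):
        motif = f"motif_{tf}"
        for j in range(config.targets_per_tf):
            target_i = target_idx[p * config.targets_per_tf + j]
            target = gene_ids[target_i]
            t_tss = int(tss[target_i])
            for _ in range(config.enhancers_per_target):
                for _attempt in range(100):
                    off = int(rng.integers(-max_off, max_off + 1))
                    mid = t_tss + off
                    s = mid - pw // 2
                    if 0 <= s and s + pw <= config.chrom_length:
                        break
                else:  # pragma: no cover - chromosome too small
                    raise PlacementError(f"could not place enhancer near {target}")
                pid = f"peak{k:05d}"
                k += 1
                peak_rows.append((pid, "chr1", s, s + pw, "enhancer", tf, target))
                program_rows.append((tf, motif, pid, target, tf_home[tf]))

    # --- decoy peaks -------------------------------------------------------
    n_decoys = config.n_peaks - k
    n_inside = int(round(config.decoy_inside_fraction * n_decoys))
    gene_pick = rng.integers(0, config.n_genes, size=n_inside)
    offs = rng.integers(-max_off, max_off + 1, size=n_inside)
    for gi, off in zip(gene_pick, offs):
        mid = int(tss[gi]) + int(off)
        s = max(0, mid - pw // 2)
        pid = f"peak{k:05d}"
        k += 1
        peak_rows.append((pid, "chr1", s, s + pw, "decoy_inside", "", ""))
    # outside: midpoints in the gaps between consecutive gene windows
    n_outside = n_decoys - n_inside
    gi = rng.integers(0, config.n_genes - 1, size=n_outside)
    gap_lo = tss[gi] + w + pw
    gap_hi = tss[gi + 1] - w - pw
    u = rng.random(n_outside)
    mids = (gap_lo + u * np.maximum(gap_hi - gap_lo, 1)).astype(int)
    for mid in mids:
        s = int(mid) - pw // 2
        pid = f"peak{k:05d}"
        k += 1
        peak_rows.append((pid, "chr1", s, s + pw, "decoy_outside", "", ""))

    peaks = pd.DataFrame(
        peak_rows, columns=["peak_id", "chrom", "start", "end", "kind", "tf", "target_gene"]
    )
    program_table = pd.DataFrame(
        program_rows,
        columns=["tf_gene", "motif_id", "enhancer_peak", "target_gene", "home_cluster"],
    )

    # --- motif hits ----------------------------------------------------------
    motif_truth = {f"motif_{tf}": tf for tf in tf_genes}
    hit_rows = []
    all_motifs = list(motif_truth) + [f"decoy_motif_{i:03d}" for i in range(config.decoy_motifs)]
    peak_id_arr = peaks.peak_id.to_numpy()
    for motif in all_motifs:
        n_bg = max(1, int(0.05 * config.n_peaks))
        bg = rng.choice(config.n_peaks, size=n_bg, replace=False)
        scores = rng.uniform(0.5, 5.0, size=n_bg)
        hit_rows.extend(zip(peak_id_arr[bg], [motif] * n_bg, scores))
    planted = program_table[["enhancer_peak", "motif_id"]].drop_duplicates()
    strong = rng.uniform(8.0, 12.0, size=len(planted))
    hit_rows.extend(zip(planted.enhancer_peak, planted.motif_id, strong))
    motif_hits = (
        pd.DataFrame(hit_rows, columns=["peak_id", "motif_id", "score"])
        .groupby(["peak_id", "motif_id"], as_index=False)
        .score.max()
    )

    # motif -> TF gene annotation (the standard motif-database input): decoy
    # motifs are assigned distinct background genes, so they compete in the
    # NES/correlation ranking like any real motif would
    bg_pool = [gene_ids[i] for i in order[n_tf + n_targets :]]
    decoy_assign = [
        (f"decoy_motif_{i:03d}", bg_pool[i % len(bg_pool)]) for i in range(config.decoy_motifs)
    ]
    motif_annotation = pd.DataFrame(
        sorted(motif_truth.items()) + decoy_assign, columns=["motif_id", "tf_gene"]
    )

    return Programs(
        genes, peaks, program_table, motif_hits, motif_annotation, motif_truth, tf_home, config
    )


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


@dataclass
class PairedMultiome:
    """Paired single-nucleus RNA and ATAC count data with annotation.

    ``rna`` and ``atac`` follow the anndata convention (obs = nuclei,
    var = features); latent coordinates live in ``obsm['X_latent']``.
    """

    rna: ad.AnnData
    atac: ad.AnnData
    genes: pd.DataFrame
    peaks: pd.DataFrame
    motif_hits: pd.DataFrame
    motif_annotation: pd.DataFrame = None

    def counts(self, modality: str) -> pd.DataFrame:
        """Dense feature x nucleus counts DataFrame for one modality."""
        adata = getattr(self, modality)
        x = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
        return pd.DataFrame(x.T, index=adata.var_names, columns=adata.obs_names)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery scoring."""

    planted_links: set  # {(peak_id, gene_id)}
    planted_programs: set  # {(tf_gene, enhancer_peak, target_gene)}
    motif_truth: dict
    tf_home_cluster: dict
    program_table: pd.DataFrame
    cluster_table: pd.DataFrame
    decoy_motifs: list = field(default_factory=list)


def tf_activity(t: np.ndarray, branch: np.ndarray, home_branch: str,
                t_lo: float, t_hi: float, root_fraction: float) -> np.ndarray:
    """Smooth per-nucleus activity of a TF whose home cluster is a t-interval.

    A Gaussian bump centered on the home cluster's pseudotime range; nuclei on
    the other branch are evaluated at their pseudotime reflected through the
    branch point, so activity decays as they diverge and the program stays
    branch-specific while remaining a smooth function of the latent state.
    """
    t = np.asarray(t, dtype=float)
    branch = np.asarray(branch)
    m = 0.5 * (t_lo + t_hi)
    s = max(0.5 * (t_hi - t_lo), 1e-6)
    t_eff = t.copy()
    if home_branch != "root":
        other = (branch != home_branch) & (branch != "root")
        t_eff[other] = 2.0 * root_fraction - t_eff[other]
    return np.exp(-0.5 * ((t_eff - m) / s) ** 2)


def _activity_matrix(obs: pd.DataFrame, programs: Programs) -> pd.DataFrame:
    config = programs.config
    clusters = cluster_scheme(config).set_index("cluster")
    acts = {}
    for tf, home in programs.tf_home_cluster.items():
        row = clusters.loc[home]
        acts[tf] = tf_activity(
            obs.true_pseudotime.to_numpy(),
            obs.true_branch.to_numpy(),
            row.branch,
            row.t_lo,
            row.t_hi,
            config.root_fraction,
        )
    return pd.DataFrame(acts, index=obs.index)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_counts(latent: TrajectoryLatent, programs: Programs,
                    config: SimConfig | None = None) -> tuple[PairedMultiome, GroundTruth]:
    """Draw RNA (negative binomial) and ATAC (Poisson) counts from the latent.

    Baseline RNA rates are softplus(loadings @ latent); TF activity scales the
    TF gene's and its targets' rates and its enhancers' accessibility rates
    multiplicatively by ``1 + program_effect * activity``. Decoy peaks have
    nucleus-independent rates, so their accessibility is independent of every
    TF's expression by construction. Rates are globally scaled so the mean
    per-nucleus depth matches the configured depths.
    """
    config = config or latent.config
    rng = child_rng(config.seed, 4)

    act_rna = _activity_matrix(latent.rna_obs, programs)
    act_atac = _activity_matrix(latent.atac_obs, programs)

    # --- RNA ---------------------------------------------------------------
    g, d = config.n_genes, config.latent_dim
    loadings = rng.normal(0.0, 0.35, size=(g, d))
    mu = _softplus(loadings @ latent.rna_coords.T + 1.0)  # genes x nuclei
    gene_index = pd.Index(programs.genes.gene_id)
    # program genes get a flat baseline: their only trajectory dependence is
    # the planted TF activity, so the planted effect cannot be cancelled by a
    # random loading pointing away from the TF's home branch
    program_rows = gene_index.get_indexer(
        programs.genes.loc[programs.genes.role.isin(["tf", "target"]), "gene_id"]
    )
    mu[program_rows] = _softplus(1.0)
    for row in programs.program_table[["tf_gene", "target_gene"]].drop_duplicates().itertuples():
        a = act_rna[row.tf_gene].to_numpy()
        mu[gene_index.get_loc(row.target_gene)] = (
            mu[gene_index.get_loc(row.target_gene)] * (1.0 + config.program_effect * a)
        )
    for tf in programs.tf_home_cluster:
        mu[gene_index.get_loc(tf)] *= 1.0 + config.program_effect * act_rna[tf].to_numpy()
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite RNA rate encountered")
    mu *= config.rna_depth_mean * mu.shape[1] / mu.sum()
    if config.poisson_rna:
        rna_counts = rng.poisson(mu)
    else:
        theta = config.nb_dispersion
        rna_counts = rng.poisson(rng.gamma(theta, mu / theta))

    # --- ATAC --------------------------------------------------------------
    p = config.n_peaks
    peak_base = rng.lognormal(0.0, 0.5, size=p)
    peak_index = pd.Index(programs.peaks.peak_id)
    # planted enhancers are genuine accessible elements: floor their baseline
    # so the low tail of the lognormal cannot silence a planted program
    enh_rows = peak_index.get_indexer(programs.program_table.enhancer_peak.unique())
    peak_base[enh_rows] = np.maximum(peak_base[enh_rows], config.enhancer_base_floor)
    rho = np.repeat(peak_base[:, None], config.n_atac_nuclei, axis=1)
    for row in programs.program_table.itertuples():
        a = act_atac[row.tf_gene].to_numpy()
        rho[peak_index.get_loc(row.enhancer_peak)] = (
            rho[peak_index.get_loc(row.enhancer_peak)] * (1.0 + config.program_effect * a)
        )
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite ATAC rate encountered")
    rho *= config.atac_depth_mean * rho.shape[1] / rho.sum()
    atac_counts = rng.poisson(rho)

    # --- assemble ----------------------------------------------------------
    var_rna = programs.genes.set_index("gene_id")
    var_atac = programs.peaks.set_index("peak_id")
    # note: targets of the same TF may repeat, but rates were applied in place

    rna = ad.AnnData(
        X=sparse.csr_matrix(rna_counts.T.astype(np.int64)),
        obs=latent.rna_obs.copy(),
        var=var_rna,
    )
    rna.obsm["X_latent"] = latent.rna_coords
    atac = ad.AnnData(
        X=sparse.csr_matrix(atac_counts.T.astype(np.int64)),
        obs=latent.atac_obs.copy(),
        var=var_atac,
    )
    atac.obsm["X_latent"] = latent.atac_coords

    pm = PairedMultiome(
        rna, atac, programs.genes, programs.peaks, programs.motif_hits,
        programs.motif_annotation,
    )
    truth = GroundTruth(
        planted_links={
            (r.enhancer_peak, r.target_gene) for r in programs.program_table.itertuples()
        },
        planted_programs={
            (r.tf_gene, r.enhancer_peak, r.target_gene)
            for r in programs.program_table.itertuples()
        },
        motif_truth=dict(programs.motif_truth),
        tf_home_cluster=dict(programs.tf_home_cluster),
        program_table=programs.program_table.copy(),
        cluster_table=latent.cluster_table.copy(),
        decoy_motifs=[f"decoy_motif_{i:03d}" for i in range(config.decoy_motifs)],
    )
    return pm, truth


def simulate_multiome(config: SimConfig) -> tuple[PairedMultiome, GroundTruth]:
    """End-to-end generation: trajectory, programs, counts."""
    latent = simulate_trajectory_latent(config)
    programs = plant_regulatory_program(config)
    return simulate_counts(latent, programs, config)


def simulate_fragments(pm: PairedMultiome, seed: int = 0, frag_len: int = 120) -> pd.DataFrame:
    """Expand ATAC counts into BED-like fragment records (chrom/start/end/barcode).

    Each count at (peak, nucleus) becomes one fragment of length ``frag_len``
    placed uniformly inside the peak, so Tn5 cut sites land inside the peak.
    """
    rng = child_rng(seed, 5)
    x = pm.atac.X.tocoo() if sparse.issparse(pm.atac.X) else sparse.coo_matrix(pm.atac.X)
    reps = x.data.astype(int)
    nuc = np.repeat(pm.atac.obs_names.to_numpy()[x.row], reps)
    peak_i = np.repeat(x.col, reps)
    starts = pm.peaks.start.to_numpy()[peak_i]
    ends = pm.peaks.end.to_numpy()[peak_i]
    span = np.maximum(ends - starts - frag_len, 1)
    s = starts + (rng.random(len(nuc)) * span).astype(int)
    frags = pd.DataFrame(
        {
            "chrom": pm.peaks.chrom.to_numpy()[peak_i],
            "start": s,
            "end": s + frag_len,
            "barcode": nuc,
        }
    )
    return frags.sort_values(["chrom", "start", "end", "barcode"], kind="stable").reset_index(
        drop=True
    )
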