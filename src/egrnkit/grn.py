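"""TF mining and enhancer-gene regulatory network (eGRN) assembly.

The motif-enrichment step follows the cisTarget recipe: for each motif, all
peaks are ranked by motif score; the recovery curve of a region set (here a
cluster's DARs) is integrated over the top ``auc_fraction`` of the ranking to
give a recovery AUC, and AUCs are z-scored across motifs into normalized
enrichment scores (NES). Candidate regulators are motifs whose NES clears a
floor (default 3.0) and whose NES-across-clusters profile correlates
positively with the TF gene's expression profile. The final network is
tripartite: TF -> cis-element (a motif-bearing cluster DAR that is also a
linked peak) -> target gene.
"""
from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "motif_rankings",
    "recovery_auc",
    "nes_scores",
    "merge_enrichments",
    "cluster_motif_enrichment",
    "tf_expression_correlation",
    "select_regulators",
    "assemble_egrn",
    "export_network",
    "import_network",
]

NES_FLOOR_DEFAULT = 3.0
AUC_FRACTION_DEFAULT = 0.001
MIN_TOP_DEFAULT = 20


def motif_rankings(motif_scores: pd.DataFrame, peaks: pd.DataFrame) -> dict:
    """Per-motif total ranking of all peaks by descending score.

    ``motif_scores`` is long-form (peak_id, motif_id, score); peaks absent
    from a motif's hits score 0. Ties break by peak coordinate (chrom, start)
    then peak id, so rankings are deterministic. Returns
    {motif_id: ndarray of peak ids, best first}.
    """
    if peaks.peak_id.duplicated().any():
        dup = peaks.peak_id[peaks.peak_id.duplicated()].iloc[0]
        raise ValueError(f"duplicate peak id {dup!r}")
    coord_order = peaks.sort_values(["chrom", "start", "peak_id"], kind="stable")
    ordered_ids = coord_order.peak_id.to_numpy()
    wide = (
        motif_scores.pivot_table(index="peak_id", columns="motif_id", values="score",
                                 aggfunc="max")
        .reindex(ordered_ids)
        .fillna(0.0)
    )
    out = {}
    for motif in wide.columns:
        s = wide[motif].to_numpy()
        order = np.argsort(-s, kind="stable")  # stable: coordinate order breaks ties
        out[motif] = ordered_ids[order]
    return out


def recovery_auc(ranking: np.ndarray, region_set: set,
                 auc_fraction: float = AUC_FRACTION_DEFAULT,
                 min_top: int = MIN_TOP_DEFAULT) -> float:
    """Normalized area under the recovery curve in the top of one ranking.

    Walking down the ranking, the recovery curve is the cumulative fraction
    of ``region_set`` seen so far; the AUC is the mean recovery over the top
    ``max(ceil(auc_fraction * N), min_top)`` ranks, which lies in [0, 1].
    """
    region_set = set(region_set)
    if not region_set:
        raise ValueError("empty region set")
    n = len(ranking)
    top = min(n, max(math.ceil(auc_fraction * n), min_top))
    hits = np.isin(ranking[:top], list(region_set))
    recovery = np.cumsum(hits) / len(region_set)
    return float(recovery.mean())


def nes_scores(aucs: pd.Series | dict) -> pd.Series:
    """z-score recovery AUCs across motifs (normalized enrichment scores)."""
    aucs = pd.Series(aucs, dtype=float)
    if len(aucs) < 3:
        raise ValueError("need >= 3 motifs to normalize")
    sd = aucs.std(ddof=1)
    if sd == 0 or aucs.nunique() == 1:
        raise ValueError("all AUCs identical; NES undefined")
    return (aucs - aucs.mean()) / sd


def cluster_motif_enrichment(motif_scores: pd.DataFrame, peaks: pd.DataFrame,
                             dars: dict, motif_to_tf: dict,
                             auc_fraction: float = AUC_FRACTION_DEFAULT,
                             min_top: int = MIN_TOP_DEFAULT,
                             source: str = "egrnkit") -> pd.DataFrame:
    """Recovery-AUC/NES enrichment of every motif in every cluster's DAR set.

    ``dars`` maps cluster -> iterable of peak ids (that cluster's region
    set). Returns a long table (cluster, motif_id, tf_gene, auc, nes,
    source); NES is z-scored within each cluster.
    """
    rankings = motif_rankings(motif_scores, peaks)
    rows = []
    for cluster, region in dars.items():
        region = set(region)
        if not region:
            continue
        aucs = {m: recovery_auc(rk, region, auc_fraction, min_top) for m, rk in rankings.items()}
        if len(set(aucs.values())) == 1:
            # no motif ranking recovers the region set at all (or all equally):
            # the cluster carries no enrichment signal
            continue
        nes = nes_scores(aucs)
        for m in rankings:
            rows.append((cluster, m, motif_to_tf.get(m, ""), aucs[m], nes[m], source))
    return pd.DataFrame(rows, columns=["cluster", "motif_id", "tf_gene", "auc", "nes", "source"])


def merge_enrichments(tables: list[pd.DataFrame],
                      nes_floor: float = NES_FLOOR_DEFAULT) -> pd.DataFrame:
    """Merge enrichment tables from several sources, keeping max NES.

    Per (cluster, motif) the maximal NES across sources is kept; motifs whose
    merged NES is below ``nes_floor`` are dropped. Conflicting TF gene
    assignments for one motif raise.
    """
    allt = pd.concat(tables, ignore_index=True)
    tf_map = allt[allt.tf_gene != ""].groupby("motif_id").tf_gene.nunique()
    conflicts = tf_map[tf_map > 1]
    if len(conflicts):
        raise ValueError(f"conflicting TF assignment for motif(s): {list(conflicts.index)}")
    idx = allt.groupby(["cluster", "motif_id"]).nes.idxmax()
    merged = allt.loc[idx].reset_index(drop=True)
    return merged[merged.nes >= nes_floor].reset_index(drop=True)


def tf_expression_correlation(nes_by_cluster: pd.DataFrame,
                              mean_expr_by_cluster: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each TF's NES profile and expression profile.

    Both inputs are cluster x TF tables over a shared cluster index (>= 3
    clusters) and a shared TF set. TFs with a constant profile on either side
    are dropped with a warning column unnecessary — they are simply absent.
    Returns a table (tf_gene, r) ranked by r descending.
    """
    clusters = nes_by_cluster.index.intersection(mean_expr_by_cluster.index)
    if len(clusters) < 3:
        raise ValueError("need >= 3 clusters to correlate NES with expression")
    tfs = nes_by_cluster.columns.intersection(mean_expr_by_cluster.columns)
    rows = []
    for tf in tfs:
        a = nes_by_cluster.loc[clusters, tf].to_numpy(dtype=float)
        b = mean_expr_by_cluster.loc[clusters, tf].to_numpy(dtype=float)
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append((tf, r))
    out = pd.DataFrame(rows, columns=["tf_gene", "r"])
    out = out.sort_values(["r", "tf_gene"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_regulators(corr_ranked: pd.DataFrame, nes_table: pd.DataFrame,
                      per_cluster_top: int = 5,
                      nes_floor: float = NES_FLOOR_DEFAULT) -> dict:
    """Cluster -> list of candidate TF regulators.

    A TF qualifies in a cluster when some motif assigned to it clears the NES
    floor there and its NES-expression correlation is positive; the top
    ``per_cluster_top`` by correlation are kept, mirroring the hypothesis
    that a true activator's motif accessibility tracks its own expression.
    """
    r_by_tf = corr_ranked.set_index("tf_gene").r
    out = {}
    for cluster, sub in nes_table.groupby("cluster"):
        cands = [
            tf for tf in sub[sub.nes >= nes_floor].tf_gene.unique()
            if tf and tf in r_by_tf.index and r_by_tf[tf] > 0
        ]
        cands.sort(key=lambda tf: (-r_by_tf[tf], tf))
        out[cluster] = cands[:per_cluster_top]
    return out


def assemble_egrn(selected: dict, motif_hits: pd.DataFrame, dars: dict,
                  accepted_links: pd.DataFrame, motif_to_tf: dict,
                  nes_table: pd.DataFrame | None = None,
                  node_attrs: dict | None = None) -> nx.DiGraph:
    """Build the tripartite TF -> cis-element -> target-gene network.

    For every selected TF in a cluster, element nodes are peaks that are
    (i) DARs of that cluster, (ii) carry the TF's motif and (iii) appear in
    accepted peak-to-gene links; gene nodes are the genes linked to those
    elements. Edges carry the cluster, link correlation and NES where
    available. ``node_attrs`` may map node id -> dict of extra attributes
    (e.g. accessibility, expression scores).
    """
    links = accepted_links[accepted_links.accepted] if "accepted" in accepted_links.columns \
        else accepted_links
    linked_peaks = set(links.peak_id)
    tf_motifs: dict = {}
    for m, tf in motif_to_tf.items():
        tf_motifs.setdefault(tf, []).append(m)
    hit_sets = {m: set(s.peak_id) for m, s in motif_hits.groupby("motif_id")}
    nes_lookup = {}
    if nes_table is not None:
        for row in nes_table.itertuples():
            nes_lookup[(row.cluster, row.tf_gene)] = max(
                row.nes, nes_lookup.get((row.cluster, row.tf_gene), -np.inf)
            )
    g = nx.DiGraph()
    for cluster, tfs in selected.items():
        dar_set = set(dars.get(cluster, ()))
        for tf in tfs:
            motif_peaks = set().union(*(hit_sets.get(m, set()) for m in tf_motifs.get(tf, [])))
            elements = dar_set & motif_peaks & linked_peaks
            if not elements:
                continue  # a TF with no motif-bearing linked DAR is omitted
            g.add_node(tf, layer="tf", cluster=cluster)
            nes = nes_lookup.get((cluster, tf))
            for row in links[links.peak_id.isin(elements)].itertuples():
                g.add_node(row.peak_id, layer="element")
                g.add_node(row.gene_id, layer="gene")
                g.add_edge(tf, row.peak_id, interaction="binds", cluster=cluster,
                           **({"nes": float(nes)} if nes is not None else {}))
                g.add_edge(row.peak_id, row.gene_id, interaction="links",
                           cluster=cluster, r=float(row.r))
    for node, attrs in (node_attrs or {}).items():
        if node in g:
            g.nodes[node].update(attrs)
    return g


def export_network(network: nx.DiGraph, directory) -> None:
    """Write edge table, node attribute table and SIF; round-trips exactly."""
    from pathlib import Path

    if network.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [
            {"source": u, "interaction": d.get("interaction", ""), "target": v,
             **{k: v2 for k, v2 in d.items() if k != "interaction"}}
            for u, v, d in sorted(network.edges(data=True))
        ]
    )
    nodes = pd.DataFrame(
        [{"node": n, **d} for n, d in sorted(network.nodes(data=True))]
    )
    edges.to_csv(directory / "edges.tsv", sep="\t", index=False)
    nodes.to_csv(directory / "nodes.tsv", sep="\t", index=False)
    with open(directory / "network.sif", "w") as fh:
        for row in edges.itertuples():
            fh.write(f"{row.source}\t{row.interaction}\t{row.target}\n")


def import_network(directory) -> nx.DiGraph:
    """Rebuild a network written by :func:`export_network`."""
    from pathlib import Path

    directory = Path(directory)
    edges = pd.read_csv(directory / "edges.tsv", sep="\t")
    nodes = pd.read_csv(directory / "nodes.tsv", sep="\t")
    g = nx.DiGraph()
    for row in nodes.itertuples(index=False):
        d = {k: v for k, v in row._asdict().items() if k != "node" and pd.notna(v)}
        g.add_node(row.node, **d)
    for row in edges.itertuples(index=False):
        d = {
            k: v
            for k, v in row._asdict().items()
            if k not in ("source", "target") and pd.notna(v)
        }
        g.add_edge(row.source, row.target, **d)
    return g
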