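"""Differential testing, consensus markers, gene activity and cluster quality.

Shows the marker toolbox: Wilcoxon and ANOVA marker tables intersected by
their top ranks (the multi-method consensus), Welch-t DARs, gene-activity
scores from fragment cut sites, pseudobulk log2(CPM), Fisher set enrichment
and the Dunn / silhouette indices.
"""
import numpy as np
import pandas as pd

from egrnkit import SimConfig, depth_normalize_log1p, simulate_fragments, simulate_multiome
from egrnkit.cluster_eval import dunn_index, silhouette_mean
from egrnkit.differential import (
    anova_markers,
    consensus_top200,
    dar_ttest,
    fisher_enrichment,
    wilcoxon_markers,
)
from egrnkit.genomic import GenomicIntervalSet, gene_activity_scores, pseudobulk_log2cpm

pm, truth = simulate_multiome(SimConfig(seed=1))
labels = pm.rna.obs.true_cluster
rna_norm = pd.DataFrame(depth_normalize_log1p(pm.rna.X.T),
                        index=pm.rna.var_names, columns=pm.rna.obs_names)

wilc = wilcoxon_markers(rna_norm, labels)
anov = anova_markers(rna_norm, labels)
shared = consensus_top200([wilc, anov], top_n=200)
print(f"marker consensus: {len(shared)} genes shared by both methods' top 200")

dars = dar_ttest(pm.counts("atac"), pm.atac.obs.true_cluster)
print("DARs per cluster:", {c: len(t) for c, t in dars.items()})

# do the DAR sets enrich for the planted enhancers? (one-sided Fisher + BH)
universe = set(pm.peaks.peak_id)
enhancers = {p for (p, _) in truth.planted_links}
for cluster, table in sorted(dars.items()):
    if len(table):
        out = fisher_enrichment(set(table.feature), {"planted_enhancers": enhancers}, universe)
        print(f"  {cluster}: enhancer enrichment p = {out.p.iloc[0]:.2e}")

frags = simulate_fragments(pm, seed=1)
genes = GenomicIntervalSet(pm.genes.rename(columns={"gene_id": "id"}))
activity = gene_activity_scores(frags.head(50_000), genes, upstream=2000)
print(f"gene activity matrix: {activity.shape[0]} genes x {activity.shape[1]} nuclei")

pb = pseudobulk_log2cpm(pm.counts("rna"), pm.rna.obs.true_cluster)
print(f"pseudobulk log2(CPM): {pb.shape[0]} genes x {pb.shape[1]} clusters")

latent = pm.atac.obsm["X_latent"]
print(f"Dunn index: {dunn_index(latent, pm.atac.obs.true_cluster.to_numpy()):.3f}")
print(f"mean silhouette: {silhouette_mean(latent, pm.atac.obs.true_cluster.to_numpy()):.3f}")
# Planted enhancers concentrate in their home cluster's DAR set, and the
# latent clusters are compact enough for positive silhouette values.
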