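"""Motif rankings, recovery AUC/NES, regulator selection and network assembly."""
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from egrnkit.grn import (
    assemble_egrn,
    cluster_motif_enrichment,
    export_network,
    import_network,
    merge_enrichments,
    motif_rankings,
    nes_scores,
    recovery_auc,
    select_regulators,
    tf_expression_correlation,
)


def peaks_df(n, chrom="chr1"):
    return pd.DataFrame(
        {
            "peak_id": [f"p{i:03d}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
        }
    )


class TestMotifRankings:
    def test_distinct_scores_match_argsort_oracle(self, rng):
        peaks = peaks_df(50)
        scores = pd.DataFrame(
            {
                "peak_id": peaks.peak_id,
                "motif_id": "m1",
                "score": rng.permutation(np.arange(50, dtype=float) + 1),
            }
        )
        ranking = motif_rankings(scores, peaks)["m1"]
        lookup = scores.set_index("peak_id").score
        expected = list(lookup.sort_values(ascending=False).index)
        assert list(ranking) == expected

    def test_equal_scores_fall_back_to_coordinate_order(self):
        peaks = peaks_df(10)
        scores = pd.DataFrame(
            {"peak_id": peaks.peak_id, "motif_id": "m1", "score": 1.0}
        )
        ranking = motif_rankings(scores, peaks)["m1"]
        assert list(ranking) == list(peaks.peak_id)

    def test_unscored_peaks_rank_last(self):
        peaks = peaks_df(5)
        scores = pd.DataFrame(
            {"peak_id": ["p003"], "motif_id": ["m1"], "score": [2.0]}
        )
        ranking = motif_rankings(scores, peaks)["m1"]
        assert ranking[0] == "p003"
        assert list(ranking[1:]) == ["p000", "p001", "p002", "p004"]

    def test_duplicate_peak_ids_raise(self):
        peaks = pd.concat([peaks_df(3), peaks_df(3)])
        scores = pd.DataFrame({"peak_id": ["p000"], "motif_id": ["m"], "score": [1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            motif_rankings(scores, peaks)


class TestRecoveryAuc:
    def test_region_filling_the_top_window_is_maximal(self):
        ranking = np.array([f"p{i}" for i in range(1000)])
        region = {f"p{i}" for i in range(30)}
        top = max(math.ceil(0.001 * 1000), 20)  # 20 ranks
        # oracle: recovery at rank k is min(k, |inside|)/|region|
        expected = np.mean([min(k + 1, top) / len(region) for k in range(top)])
        assert recovery_auc(ranking, region) == pytest.approx(expected)

    def test_region_entirely_below_top_window_scores_zero(self):
        ranking = np.array([f"p{i}" for i in range(1000)])
        assert recovery_auc(ranking, {"p500", "p900"}) == 0.0

    def test_matches_cumulative_sum_oracle(self, rng):
        ranking = np.array([f"p{i}" for i in range(5000)])
        region = set(rng.choice(ranking, 100, replace=False))
        auc = recovery_auc(ranking, region, auc_fraction=0.01, min_top=20)
        top = max(math.ceil(0.01 * 5000), 20)
        hits = np.isin(ranking[:top], list(region))
        oracle = float(np.mean(np.cumsum(hits) / len(region)))
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_insensitive_to_order_below_top_window(self, rng):
        ranking = np.array([f"p{i}" for i in range(2000)])
        region = {"p0", "p5", "p1500"}
        shuffled = ranking.copy()
        shuffled[100:] = rng.permutation(shuffled[100:])
        assert recovery_auc(ranking, region) == recovery_auc(shuffled, region)

    def test_empty_region_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            recovery_auc(np.array(["p0"]), set())


class TestNes:
    def test_z_score_identity(self):
        nes = nes_scores({"a": 0.1, "b": 0.2, "c": 0.3})
        assert nes.mean() == pytest.approx(0.0, abs=1e-12)
        assert nes.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert nes["a"] < nes["b"] < nes["c"]

    def test_permutation_equivariance(self, rng):
        aucs = pd.Series(rng.random(20), index=[f"m{i}" for i in range(20)])
        nes = nes_scores(aucs)
        perm = aucs.sample(frac=1, random_state=1)
        nes_perm = nes_scores(perm)
        for m in aucs.index:
            assert nes[m] == pytest.approx(nes_perm[m])

    def test_matches_direct_oracle(self, rng):
        aucs = pd.Series(rng.random(200))
        nes = nes_scores(aucs)
        oracle = (aucs - aucs.mean()) / aucs.std(ddof=1)
        np.testing.assert_allclose(nes, oracle, atol=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match=">= 3"):
            nes_scores({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError, match="identical"):
            nes_scores({"a": 0.1, "b": 0.1, "c": 0.1})


class TestMergeEnrichments:
    def table(self, rows, source="s1"):
        return pd.DataFrame(
            rows, columns=["cluster", "motif_id", "tf_gene", "auc", "nes"]
        ).assign(source=source)

    def test_single_source_is_identity_above_floor(self):
        t = self.table([("c1", "m1", "tfA", 0.5, 4.0), ("c1", "m2", "tfB", 0.1, 1.0)])
        out = merge_enrichments([t])
        assert list(out.motif_id) == ["m1"]

    def test_max_nes_across_sources_is_kept(self):
        a = self.table([("c1", "m1", "tfA", 0.5, 2.9)], "s1")
        b = self.table([("c1", "m1", "tfA", 0.6, 3.4)], "s2")
        out = merge_enrichments([a, b])
        assert out.nes.iloc[0] == 3.4 and out.source.iloc[0] == "s2"

    def test_all_below_floor_yields_empty(self):
        t = self.table([("c1", "m1", "tfA", 0.5, 2.0)])
        assert len(merge_enrichments([t])) == 0

    def test_conflicting_tf_assignment_raises(self):
        a = self.table([("c1", "m1", "tfA", 0.5, 4.0)], "s1")
        b = self.table([("c1", "m1", "tfB", 0.5, 4.0)], "s2")
        with pytest.raises(ValueError, match="m1"):
            merge_enrichments([a, b])


class TestTfCorrelation:
    def test_proportional_profiles_rank_first(self):
        nes = pd.DataFrame(
            {"tfA": [1.0, 2.0, 3.0], "tfB": [3.0, 2.0, 1.0]},
            index=["c1", "c2", "c3"],
        )
        expr = pd.DataFrame(
            {"tfA": [2.0, 4.0, 6.0], "tfB": [2.0, 4.0, 6.0]},
            index=["c1", "c2", "c3"],
        )
        out = tf_expression_correlation(nes, expr)
        assert out.iloc[0].tf_gene == "tfA" and out.iloc[0].r == pytest.approx(1.0)
        assert out.iloc[-1].tf_gene == "tfB" and out.iloc[-1].r == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        clusters = [f"c{i}" for i in range(8)]
        tfs = [f"tf{i}" for i in range(10)]
        nes = pd.DataFrame(rng.normal(size=(8, 10)), index=clusters, columns=tfs)
        expr = pd.DataFrame(rng.normal(size=(8, 10)), index=clusters, columns=tfs)
        out = tf_expression_correlation(nes, expr).set_index("tf_gene")
        for tf in tfs:
            a, b = nes[tf].to_numpy(), expr[tf].to_numpy()
            r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
            )
            assert out.loc[tf, "r"] == pytest.approx(r, abs=1e-12)

    def test_too_few_clusters_raise(self):
        nes = pd.DataFrame({"tfA": [1.0, 2.0]}, index=["c1", "c2"])
        with pytest.raises(ValueError, match="clusters"):
            tf_expression_correlation(nes, nes)


class TestSelectRegulators:
    def test_nonpositive_correlation_never_selected(self):
        corr = pd.DataFrame({"tf_gene": ["tfA", "tfB"], "r": [0.9, -0.2], "rank": [1, 2]})
        nes = pd.DataFrame(
            {
                "cluster": ["c1", "c1"],
                "motif_id": ["m1", "m2"],
                "tf_gene": ["tfA", "tfB"],
                "auc": [0.5, 0.5],
                "nes": [5.0, 5.0],
                "source": "s",
            }
        )
        out = select_regulators(corr, nes)
        assert out == {"c1": ["tfA"]}

    def test_nes_floor_gates_selection(self):
        corr = pd.DataFrame({"tf_gene": ["tfA"], "r": [0.9], "rank": [1]})
        nes = pd.DataFrame(
            {
                "cluster": ["c1"],
                "motif_id": ["m1"],
                "tf_gene": ["tfA"],
                "auc": [0.5],
                "nes": [2.0],
                "source": "s",
            }
        )
        assert select_regulators(corr, nes, nes_floor=3.0) == {"c1": []}


def toy_network():
    selected = {"c1": ["tfA"]}
    motif_hits = pd.DataFrame(
        {"peak_id": ["p1", "p2", "p9"], "motif_id": ["mA", "mA", "mB"], "score": 5.0}
    )
    dars = {"c1": {"p1", "p2", "p3"}}
    links = pd.DataFrame(
        {
            "peak_id": ["p1", "p2", "p4"],
            "gene_id": ["gX", "gY", "gZ"],
            "r": [0.8, 0.7, 0.9],
            "accepted": True,
        }
    )
    motif_to_tf = {"mA": "tfA", "mB": "tfB"}
    return selected, motif_hits, dars, links, motif_to_tf


class TestAssembleEgrn:
    def test_complete_two_edge_paths_for_qualified_elements(self):
        g = assemble_egrn(*toy_network())
        assert g.has_edge("tfA", "p1") and g.has_edge("p1", "gX")
        assert g.has_edge("tfA", "p2") and g.has_edge("p2", "gY")
        assert "p4" not in g  # linked but not a DAR with the motif
        # every element node lies on a complete TF -> element -> gene path
        for n, d in g.nodes(data=True):
            if d["layer"] == "element":
                assert g.in_degree(n) >= 1 and g.out_degree(n) >= 1

    def test_tf_without_motif_bearing_dars_is_omitted(self):
        selected, motif_hits, dars, links, motif_to_tf = toy_network()
        selected = {"c1": ["tfB"]}  # mB hits only p9, which is not a DAR
        g = assemble_egrn(selected, motif_hits, dars, links, motif_to_tf)
        assert g.number_of_nodes() == 0

    def test_removing_a_link_removes_exactly_its_edge(self):
        selected, motif_hits, dars, links, motif_to_tf = toy_network()
        g_full = assemble_egrn(selected, motif_hits, dars, links, motif_to_tf)
        g_cut = assemble_egrn(
            selected, motif_hits, dars, links[links.peak_id != "p2"], motif_to_tf
        )
        lost = set(g_full.edges) - set(g_cut.edges)
        assert lost == {("p2", "gY"), ("tfA", "p2")}


class TestExportImport:
    def test_round_trip_preserves_graph_and_attributes(self, tmp_path):
        g = assemble_egrn(*toy_network())
        export_network(g, tmp_path)
        g2 = import_network(tmp_path)
        assert nx.utils.graphs_equal(
            nx.DiGraph(g.edges), nx.DiGraph(g2.edges)
        )
        for u, v, d in g.edges(data=True):
            for k, val in d.items():
                assert g2.edges[u, v][k] == val
        sif = (tmp_path / "network.sif").read_text().strip().splitlines()
        assert len(sif) == g.number_of_edges()

    def test_empty_network_refused(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            export_network(nx.DiGraph(), tmp_path)


class TestClusterEnrichmentEndToEnd:
    def test_planted_motif_outranks_decoys(self, small_dataset, small_config):
        pm, truth = small_dataset
        # region set = the enhancers of the first TF; its motif should be the
        # clear NES winner over all decoy motifs
        tf = sorted(truth.tf_home_cluster)[0]
        region = set(
            truth.program_table[truth.program_table.tf_gene == tf].enhancer_peak
        )
        motif_to_tf = dict(zip(pm.motif_annotation.motif_id, pm.motif_annotation.tf_gene))
        table = cluster_motif_enrichment(
            pm.motif_hits, pm.peaks, {"home": region}, motif_to_tf
        )
        best = table.loc[table.nes.idxmax()]
        assert best.motif_id == f"motif_{tf}"
        assert best.nes > 3.0
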