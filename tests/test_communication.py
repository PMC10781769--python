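"""Communication inference: ligand/TF selection, spatial importance,
LR consensus ranking and shortest-path signaling networks."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_dataset
from spotflow.activity import tf_activity
from spotflow.communication import (
    aggregate_importance,
    ligand_tf_importance,
    lr_consensus,
    select_ligands,
    select_tme_tfs,
    selected_pairs,
    shortest_path_network,
    tme_mean_expression,
)
from spotflow.core_data import ActivityMatrix, PriorKnowledge
from spotflow.preprocess import normalize


def toy_activity(ds, values):
    return ActivityMatrix(
        unit_ids=ds.spot_ids.copy(),
        features=np.array([f"TF{i}" for i in range(values.shape[1])], dtype=object),
        values=values,
    )


class TestSelectLigands:
    def make_sample(self, interface_expr, other_expr, seed=0, n=40):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5, size=(3, 2 * n)) + 1
        counts[0, :n] = interface_expr
        counts[0, n:] = other_expr
        ds = build_dataset(counts, genes=["LIGX", "GB", "GC"])
        return normalize(ds), np.array([True] * n + [False] * n)

    def prior(self):
        return PriorKnowledge(
            ligands=frozenset({"LIGX"}),
            lr_pairs=(("LIGX", "RECX"),),
            ppi_edges=(("RECX", "TFX", 1),),
            regulons={"TFX": (("GB", 1, "A"),) * 1},
            pathway_weights={},
        )

    def test_interface_overexpressed_ligand_selected(self):
        ds, mask = self.make_sample(20, 2)
        assert select_ligands([ds], [mask], self.prior()) == ["LIGX"]

    def test_ligand_expressed_outside_interface_excluded(self):
        ds, mask = self.make_sample(2, 20)
        assert select_ligands([ds], [mask], self.prior()) == []

    def test_low_detection_in_one_sample_excludes(self):
        ds1, mask1 = self.make_sample(20, 2)
        ds2, mask2 = self.make_sample(20, 2, seed=1)
        # ligand detected in <10% of interface spots of sample 2
        arr = np.asarray(ds2.counts.todense())
        arr[0, :40] = 0
        arr[0, :3] = 20
        ds2.counts = type(ds2.counts)(arr)
        ds2.norm = None
        ds2 = normalize(ds2)
        assert select_ligands([ds1, ds2], [mask1, mask2], self.prior()) == []

    def test_no_ligand_intersection_warns_empty(self):
        ds, mask = self.make_sample(20, 2)
        prior = PriorKnowledge(
            ligands=frozenset({"OTHER"}), lr_pairs=(("OTHER", "R"),),
            ppi_edges=(("R", "T", 1),), regulons={}, pathway_weights={},
        )
        with pytest.warns(UserWarning, match="ligand list"):
            assert select_ligands([ds], [mask], prior) == []


class TestSelectTMETFs:
    def test_auc_threshold_and_marker_flag(self):
        markers = pd.DataFrame(
            {
                "feature": ["TFa", "TFb", "TFc"],
                "cluster": [1, 1, 1],
                "auc": [0.74, 0.80, 0.90],
                "pct_defined": [1.0, 1.0, 1.0],
                "mean_diff": [2.0, 2.0, 2.0],
                "marker": [False, True, True],
            }
        )
        assert select_tme_tfs(markers, 1) == ["TFb", "TFc"]


class TestLigandImportance:
    def make_inputs(self, seed=0, n_rows=14, n_cols=20, n_lig=4):
        from spotflow.synthio import LayoutParams, make_layout

        lay = make_layout(n_rows, n_cols, LayoutParams(tumor_radius=0.0), seed=0)
        rng = np.random.default_rng(seed)
        n = lay.n_spots
        genes = [f"LIG{i:02d}" for i in range(n_lig)] + ["BG0"]
        counts = rng.poisson(20, size=(len(genes), n)) + 1
        import scipy.sparse as sp

        from spotflow.core_data import SpotDataset

        ds = SpotDataset(
            sample_id="imp",
            spot_ids=lay.spot_ids,
            array_coords=lay.array_coords,
            counts=sp.csr_matrix(counts),
            gene_ids=np.array(genes, dtype=object),
        )
        return normalize(ds), [f"LIG{i:02d}" for i in range(n_lig)]

    def test_per_tf_importances_standardized_exactly(self):
        ds, ligands = self.make_inputs()
        rng = np.random.default_rng(1)
        act = toy_activity(ds, rng.normal(size=(ds.n_spots, 3)))
        imp = ligand_tf_importance(ds, ligands, act)
        vals = imp.table.to_numpy()
        assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(vals.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_ligand_order_equivariance(self):
        ds, ligands = self.make_inputs(seed=2)
        rng = np.random.default_rng(3)
        act = toy_activity(ds, rng.normal(size=(ds.n_spots, 2)))
        a = ligand_tf_importance(ds, ligands, act)
        b = ligand_tf_importance(ds, ligands[::-1], act)
        assert np.allclose(
            a.table.loc[ligands].to_numpy(), b.table.loc[ligands].to_numpy(), atol=1e-9
        )

    def test_single_ligand_rejected(self):
        ds, ligands = self.make_inputs()
        act = toy_activity(ds, np.zeros((ds.n_spots, 1)))
        with pytest.raises(ValueError, match="one predictor"):
            ligand_tf_importance(ds, ligands[:1], act)

    def test_aggregate_is_mean_of_samples(self):
        ds, ligands = self.make_inputs()
        rng = np.random.default_rng(4)
        act1 = toy_activity(ds, rng.normal(size=(ds.n_spots, 2)))
        act2 = toy_activity(ds, rng.normal(size=(ds.n_spots, 2)))
        i1 = ligand_tf_importance(ds, ligands, act1)
        i2 = ligand_tf_importance(ds, ligands, act2)
        agg = aggregate_importance([i1, i2])
        assert np.allclose(
            agg.table.to_numpy(), (i1.table.to_numpy() + i2.table.to_numpy()) / 2
        )
        sel = selected_pairs(agg, threshold=-10.0)
        assert len(sel) == agg.table.size


class TestLRConsensus:
    def make_ds(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 60
        genes = ["LIG", "REC", "BG1", "BG2"]
        counts = rng.poisson(10, size=(4, n)) + 1
        clusters = np.array(["c0"] * (n // 2) + ["c1"] * (n // 2))
        counts[0, clusters == "c0"] += 40  # ligand high in c0
        counts[1, clusters == "c1"] += 40  # receptor high in c1
        ds = build_dataset(counts, genes=genes)
        return normalize(ds), clusters

    def test_zero_source_expression_worst_rank(self):
        ds, clusters = self.make_ds()
        arr = np.asarray(ds.counts.todense())
        arr[0, clusters == "c0"] = 0
        ds.counts = type(ds.counts)(arr)
        ds.norm = None
        ds = normalize(ds)
        table = lr_consensus([ds], [clusters], [("LIG", "REC"), ("BG1", "BG2")],
                             n_perm=200, seed=0)
        row = table[
            (table["ligand"] == "LIG") & (table["source"] == "c0")
            & (table["target"] == "c1")
        ].iloc[0]
        assert row["s1_product"] == 0.0
        assert not row["selected"]

    def test_single_candidate_rank_one_never_selected(self):
        ds, clusters = self.make_ds()
        sub = ds.subset_spots(np.arange(ds.n_spots))
        sub.counts = ds.counts[:2]
        sub.gene_ids = ds.gene_ids[:2]
        sub.norm = None
        sub = normalize(sub)
        one_cluster = np.array(["c0"] * ds.n_spots)
        table = lr_consensus([sub], [one_cluster], [("LIG", "REC")], n_perm=50, seed=0)
        assert len(table) == 1
        assert table["aggregate_rank"].iloc[0] == 1.0
        assert not table["selected"].any()

    def test_directional_pair_ranked_first(self):
        ds, clusters = self.make_ds()
        decoys = [("BG1", "BG2"), ("BG2", "BG1")]
        table = lr_consensus([ds], [clusters], [("LIG", "REC")] + decoys,
                             n_perm=500, seed=1)
        top = table.iloc[0]
        assert (top["ligand"], top["receptor"], top["source"], top["target"]) == (
            "LIG", "REC", "c0", "c1",
        )

    def test_absent_gene_skipped_with_warning(self):
        ds, clusters = self.make_ds()
        with pytest.warns(UserWarning, match="absent from data"):
            table = lr_consensus([ds], [clusters], [("LIG", "REC"), ("NOPE", "REC")],
                                 n_perm=50, seed=0)
        assert set(table["ligand"]) == {"LIG"}


def brute_force_shortest_edges(edges, source, target):
    """Oracle: DFS enumeration of ALL paths, keep those of minimal length."""
    adj = {}
    for s, t in edges:
        adj.setdefault(s, []).append(t)
    paths = []

    def walk(node, path):
        if node == target:
            paths.append(tuple(path))
            return
        for nxt in adj.get(node, []):
            if nxt not in path:
                walk(nxt, path + [nxt])

    walk(source, [source])
    if not paths:
        return None
    shortest = min(len(p) for p in paths)
    out = set()
    for p in paths:
        if len(p) == shortest:
            out.update(zip(p[:-1], p[1:]))
    return out


class TestSignalingNetwork:
    def make_prior(self, ppi):
        return PriorKnowledge(
            ligands=frozenset({"L"}),
            lr_pairs=(("L", "R"),),
            ppi_edges=tuple(ppi),
            regulons={"TF": (("g", 1, "A"),)},
            pathway_weights={},
        )

    def lr_hits(self):
        return pd.DataFrame(
            {"ligand": ["L"], "receptor": ["R"], "selected": [True]}
        )

    def test_direct_edge_single_path(self):
        prior = self.make_prior([("R", "TF", 1)])
        net = shortest_path_network(prior, self.lr_hits(), [("L", "TF")])
        assert set(net.graph.edges) == {("L", "R"), ("R", "TF")}
        assert net.graph["R"]["TF"]["kind"] == "PPI"
        assert net.graph["L"]["R"]["kind"] == "LR"

    def test_tied_paths_both_included(self):
        ppi = [("R", "a", 1), ("a", "TF", 1), ("R", "b", -1), ("b", "TF", 1),
               ("R", "c", 1), ("c", "d", 1), ("d", "TF", 1)]
        prior = self.make_prior(ppi)
        net = shortest_path_network(prior, self.lr_hits(), [("L", "TF")])
        oracle = brute_force_shortest_edges([(s, t) for s, t, _ in ppi], "R", "TF")
        ppi_edges = {(u, v) for u, v, d in net.graph.edges(data=True) if d["kind"] == "PPI"}
        assert ppi_edges == oracle
        assert ("c", "d") not in ppi_edges  # longer alternative excluded

    def test_unreachable_pair_reported(self):
        prior = self.make_prior([("TF", "R", 1)])  # wrong direction only
        net = shortest_path_network(prior, self.lr_hits(), [("L", "TF")])
        assert net.unreachable == [("R", "TF")]
        assert "TF" not in net.graph.nodes

    def test_unmapped_endpoint_reported(self):
        prior = self.make_prior([("X", "Y", 1)])
        net = shortest_path_network(prior, self.lr_hits(), [("L", "TF")])
        assert net.unmapped == [("R", "TF")]

    def test_node_types_and_expression_annotation(self):
        ppi = [("R", "a", 1), ("a", "TF", -1)]
        prior = self.make_prior(ppi)
        net = shortest_path_network(
            prior, self.lr_hits(), [("L", "TF")],
            node_expression={"R": 1.5, "TF": 0.25},
        )
        types = {n: d["type"] for n, d in net.graph.nodes(data=True)}
        assert types == {"L": "ligand", "R": "receptor", "a": "intermediary", "TF": "tf"}
        assert net.graph.nodes["R"]["mean_expression"] == 1.5
        assert net.graph["a"]["TF"]["sign"] == -1

    def test_sif_and_graphml_written(self, tmp_path):
        prior = self.make_prior([("R", "TF", 1)])
        net = shortest_path_network(prior, self.lr_hits(), [("L", "TF")])
        net.write_sif(tmp_path / "n.sif")
        net.write_graphml(tmp_path / "n.graphml")
        assert "R\tPPI+\tTF" in (tmp_path / "n.sif").read_text()
        import networkx as nx

        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == {"L", "R", "TF"}


def test_tme_mean_expression_across_samples():
    a = normalize(build_dataset(np.array([[2, 4], [0, 8]]), genes=["GA", "GB"]))
    masks = [np.array([True, False])]
    means = tme_mean_expression([a], masks)
    assert means["GA"] == pytest.approx(float(a.norm[0, 0]))
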