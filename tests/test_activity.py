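"""Pathway / TF / module activity scoring, clustering, ROC markers and
abundance-activity correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri
from scipy.stats import rankdata

from spotflow.activity import (
    abundance_activity_correlation,
    cluster_by_tf,
    module_score,
    pathway_activity,
    roc_markers,
    tf_activity,
    zscale_activities,
)
from spotflow.core_data import AbundanceMatrix, ActivityMatrix


def frame(values, genes=None, units=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    units = units or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes), columns=units)


class TestPathwayActivity:
    def test_constant_expression_gives_zero_activity(self):
        expr = frame(np.ones((5, 4)))
        pw = {"P": tuple((f"g{i}", 1.0, i + 1) for i in range(5))}
        act = pathway_activity(expr, pw)
        assert np.allclose(act.values, 0.0)

    def test_single_gene_weighted_formula(self):
        # gene z-scores on two spots are exactly (-1, +1); weight 2 -> (-2, +2)
        expr = frame([[1.0, 3.0]])
        act = pathway_activity(expr, {"P": (("g0", 2.0, 1),)})
        assert np.allclose(act.values[:, 0], [-2.0, 2.0])

    def test_scale_standardizes_columns(self):
        rng = np.random.default_rng(0)
        expr = frame(rng.normal(size=(20, 30)))
        pw = {"P": tuple((f"g{i}", rng.normal(), i + 1) for i in range(20))}
        act = pathway_activity(expr, pw, scale=True)
        assert np.nanmean(act.values[:, 0]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(act.values[:, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(1)
        expr = frame(rng.normal(size=(10, 8)))
        pw1 = {"P": tuple((f"g{i}", 0.5 + i, i + 1) for i in range(10))}
        pw2 = {"P": tuple((g, 2 * w, r) for g, w, r in pw1["P"])}
        a1 = pathway_activity(expr, pw1)
        a2 = pathway_activity(expr, pw2)
        assert np.allclose(a2.values, 2 * a1.values)

    def test_top_n_restricts_by_responsiveness_rank(self):
        expr = frame([[0.0, 4.0], [10.0, 0.0]])
        pw = {"P": (("g0", 1.0, 1), ("g1", 100.0, 2))}
        act = pathway_activity(expr, pw, top_n=1)
        # only g0 (rank 1) contributes: z-scores (-1, +1)
        assert np.allclose(act.values[:, 0], [-1.0, 1.0])

    def test_absent_pathway_yields_missing_column(self):
        expr = frame(np.ones((2, 3)))
        with pytest.warns(UserWarning, match="no genes"):
            act = pathway_activity(expr, {"P": (("nope", 1.0, 1),)})
        assert np.isnan(act.values).all()


class TestTFActivity:
    def test_fewer_than_min_targets_is_missing(self):
        rng = np.random.default_rng(2)
        expr = frame(rng.lognormal(size=(20, 3)))
        regulons = {"TF": tuple((f"g{i}", 1, "A") for i in range(3))}
        act = tf_activity(expr, regulons)
        assert np.isnan(act.values).all()

    def test_top_ranked_activating_targets_closed_formula(self):
        # 100 genes; the 4 regulon targets occupy the top 4 expression ranks
        n = 100
        vals = np.arange(1.0, n + 1.0)
        expr = frame(vals[:, None] * np.ones((1, 2)), genes=[f"g{i}" for i in range(n)])
        regulons = {"TF": tuple((f"g{i}", 1, "A") for i in range(n - 4, n))}
        act = tf_activity(expr, regulons)
        expected = sum(ndtri(r / (n + 1)) for r in (97, 98, 99, 100)) / 2.0
        assert np.allclose(act.values[:, 0], expected)
        assert expected > 0

    def test_repressed_targets_flip_sign(self):
        n = 50
        vals = np.arange(1.0, n + 1.0)
        expr = frame(vals[:, None], genes=[f"g{i}" for i in range(n)])
        up = {"TF": tuple((f"g{i}", 1, "A") for i in range(n - 4, n))}
        down = {"TF": tuple((f"g{i}", -1, "A") for i in range(n - 4, n))}
        assert tf_activity(expr, up).values[0, 0] == pytest.approx(
            -tf_activity(expr, down).values[0, 0]
        )

    def test_low_confidence_grades_excluded(self):
        rng = np.random.default_rng(3)
        expr = frame(rng.lognormal(size=(30, 2)))
        regulons = {"TF": tuple((f"g{i}", 1, "D") for i in range(10))}
        with pytest.warns(UserWarning, match="no graded targets"):
            with pytest.raises(ValueError, match="no regulons usable"):
                tf_activity(expr, regulons)

    def test_null_mean_and_sd_bands_small(self):
        # reduced-size version of the calibration check (full size in acceptance)
        from spotflow.benchmarks import tf_null_calibration

        cal = tf_null_calibration(3, n_spots=2000, n_genes=500, n_tfs=3)
        assert cal["max_abs_mean"] < 0.1
        lo, hi = cal["sd_range"]
        assert 0.9 < lo and hi < 1.1


class TestModuleScore:
    def test_single_bin_control_matched_null(self):
        rng = np.random.default_rng(4)
        expr = frame(rng.normal(10, 1, size=(50, 1000)))
        gene_set = {"M": [f"g{i}" for i in range(0, 50, 7)]}
        act = module_score(expr, gene_set, n_bins=1, seed=0)
        assert abs(np.nanmean(act.values)) < 0.02

    def test_planted_region_signal_detected(self):
        # the regional shift is mean-preserving so the set genes stay in the
        # same expression bins as their background peers
        rng = np.random.default_rng(5)
        base = rng.normal(5, 0.5, size=(200, 400))
        region = np.zeros(400, dtype=bool)
        region[:150] = True
        set_genes = [f"g{i}" for i in range(10)]
        base[:10, region] += 1.0
        base[:10, ~region] -= 0.6
        act = module_score(frame(base), {"M": set_genes}, seed=1)
        assert (
            np.nanmean(act.values[region, 0])
            > np.nanmean(act.values[~region, 0]) + 0.5
        )

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        expr = frame(rng.normal(size=(30, 50)))
        gs = {"M": [f"g{i}" for i in range(5)]}
        a = module_score(expr, gs, seed=9)
        b = module_score(expr, gs, seed=9)
        assert np.array_equal(a.values, b.values)


def make_blobs_activity(seed=0, n_per=60, sep=8.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 4))
    b = rng.normal(sep, 1, size=(n_per, 4))
    values = np.vstack([a, b])
    return (
        ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(2 * n_per)], dtype=object),
            features=np.array([f"TF{i}" for i in range(4)], dtype=object),
            values=values,
        ),
        np.array([0] * n_per + [1] * n_per),
    )


class TestClustering:
    def test_two_blobs_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        act, truth = make_blobs_activity()
        res = cluster_by_tf(act, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_duplication_leaves_partition_structure(self):
        from sklearn.metrics import adjusted_rand_score

        act, truth = make_blobs_activity(seed=1)
        doubled = ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(2 * len(act.unit_ids))], dtype=object),
            features=act.features.copy(),
            values=np.vstack([act.values, act.values]),
        )
        res = cluster_by_tf(doubled, seed=0)
        assert adjusted_rand_score(np.tile(truth, 2), res.labels) >= 0.99

    def test_fixed_seed_identical_labels(self):
        act, _ = make_blobs_activity(seed=2)
        a = cluster_by_tf(act, seed=5)
        b = cluster_by_tf(act, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_too_few_features_rejected(self):
        act, _ = make_blobs_activity()
        single = ActivityMatrix(
            unit_ids=act.unit_ids, features=act.features[:1], values=act.values[:, :1]
        )
        with pytest.raises(ValueError, match="2 activity features"):
            cluster_by_tf(single, seed=0)


def brute_force_auc(in_cluster, rest):
    """Oracle: concordant-pair counting with ties worth 1/2."""
    wins = 0.0
    for a in in_cluster:
        for b in rest:
            wins += 1.0 if a > b else 0.5 if a == b else 0.0
    return wins / (len(in_cluster) * len(rest))


class TestROCMarkers:
    def test_constant_feature_auc_half(self):
        act = ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(10)], dtype=object),
            features=np.array(["F"], dtype=object),
            values=np.ones((10, 1)),
        )
        labels = np.array([0] * 5 + [1] * 5)
        table = roc_markers(act, labels, return_all=True)
        assert np.allclose(table["auc"], 0.5)
        assert not table["marker"].any()

    def test_perfect_separator_is_marker(self):
        values = np.array([[1.0]] * 5 + [[0.0]] * 5)
        act = ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(10)], dtype=object),
            features=np.array(["F"], dtype=object),
            values=values,
        )
        labels = np.array([0] * 5 + [1] * 5)
        table = roc_markers(act, labels, return_all=True)
        row = table[(table["cluster"] == 0)].iloc[0]
        assert row["auc"] == 1.0 and row["mean_diff"] == 1.0 and row["marker"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_auc_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        values = np.round(rng.normal(size=(n, 2)), 1)  # rounding induces ties
        labels = rng.integers(0, 2, size=n)
        if min((labels == 0).sum(), (labels == 1).sum()) < 3:
            labels[:3] = 0
            labels[3:6] = 1
        act = ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            features=np.array(["F1", "F2"], dtype=object),
            values=values,
        )
        table = roc_markers(act, labels, return_all=True)
        for _, row in table.iterrows():
            in_c = values[labels == row["cluster"], list(act.features).index(row["feature"])]
            rest = values[labels != row["cluster"], list(act.features).index(row["feature"])]
            assert row["auc"] == pytest.approx(brute_force_auc(in_c, rest), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(30, 1))
        labels = np.array([0] * 15 + [1] * 15)
        base = ActivityMatrix(
            unit_ids=np.array([f"s{i}" for i in range(30)], dtype=object),
            features=np.array(["F"], dtype=object),
            values=values,
        )
        trans = ActivityMatrix(
            unit_ids=base.unit_ids, features=base.features, values=np.exp(values)
        )
        a = roc_markers(base, labels, return_all=True)["auc"]
        b = roc_markers(trans, labels, return_all=True)["auc"]
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestCorrelation:
    def make_pair(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        props_vals = rng.dirichlet((1, 1, 1), size=n)
        spot_ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        props = AbundanceMatrix(
            spot_ids=spot_ids,
            cell_types=np.array(list("ABC"), dtype=object),
            values=props_vals,
        )
        act = ActivityMatrix(
            unit_ids=spot_ids,
            features=np.array(["F0", "F1"], dtype=object),
            values=np.column_stack([props_vals[:, 0], rng.normal(size=n)]),
        )
        return props, act

    def test_identical_column_perfect_correlation(self):
        props, act = self.make_pair()
        r = abundance_activity_correlation(props, act, mode="pearson")
        assert r.loc["A", "F0"] == pytest.approx(1.0, abs=1e-12)
        cca = abundance_activity_correlation(props, act, mode="cca")
        assert cca["correlations"][0] == pytest.approx(1.0, abs=1e-8)

    def test_cca_correlations_sorted_in_unit_interval(self):
        props, act = self.make_pair(seed=3)
        c = abundance_activity_correlation(props, act, mode="cca")["correlations"]
        assert np.all(np.diff(c) <= 1e-12)
        assert np.all((c >= 0) & (c <= 1))

    def test_independent_columns_mostly_uncorrelated(self):
        rng = np.random.default_rng(9)
        n = 1000
        spot_ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        props = AbundanceMatrix(
            spot_ids=spot_ids,
            cell_types=np.array([f"t{i}" for i in range(5)], dtype=object),
            values=rng.normal(size=(n, 5)),
            mode="absolute",
        )
        act = ActivityMatrix(
            unit_ids=spot_ids,
            features=np.array([f"f{i}" for i in range(5)], dtype=object),
            values=rng.normal(size=(n, 5)),
        )
        r = abundance_activity_correlation(props, act, mode="pearson").to_numpy()
        assert np.mean(np.abs(r) < 0.1) >= 0.99

    def test_zero_variance_column_missing_with_warning(self):
        props, act = self.make_pair()
        act.values[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero variance"):
            r = abundance_activity_correlation(props, act, mode="pearson")
        assert r["F1"].isna().all()


def test_zscale_preserves_missingness():
    act = ActivityMatrix(
        unit_ids=np.array(["a", "b", "c"], dtype=object),
        features=np.array(["F"], dtype=object),
        values=np.array([[1.0], [np.nan], [3.0]]),
    )
    z = zscale_activities(act)
    assert np.isnan(z.values[1, 0])
    assert np.nanmean(z.values) == pytest.approx(0.0, abs=1e-12)
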