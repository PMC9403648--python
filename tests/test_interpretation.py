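"""Connection/node/network weight summaries and weight-map overlap."""

import numpy as np
import pytest

import connpredict as cp
from connpredict.connectome import Atlas
from connpredict.exceptions import IncompatibleMapsError, InvalidParameterError
from connpredict.interpretation import WeightMap


@pytest.fixture()
def atlas2x2():
    return Atlas(tuple("abcd"), tuple("abcd"), ("N1", "N1", "N2", "N2"))


class TestAverageMaps:
    def test_single_map_is_identity(self, rng):
        v = rng.standard_normal(6)
        wm = cp.average_maps([v])
        assert np.array_equal(wm.values, v)
        assert wm.n_models_averaged == 1

    def test_opposite_maps_cancel(self, rng):
        v = rng.standard_normal(6)
        assert np.allclose(cp.average_maps([v, -v]).values, 0.0)

    def test_arithmetic(self):
        wm = cp.average_maps([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        assert np.array_equal(wm.values, [1.0, 1.0])
        assert wm.n_models_averaged == 3

    def test_mixed_lengths_rejected(self):
        with pytest.raises(InvalidParameterError):
            cp.average_maps([np.zeros(3), np.zeros(4)])


class TestNodeSummary:
    def test_incident_edge_sum(self, atlas2x2):
        # 4-node edges in canonical order: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        w = np.array([0.6, -0.2, 0.2, 0.0, 0.0, 0.0])
        nodes = cp.node_summary(WeightMap("connection", w), atlas2x2)
        assert np.isclose(nodes.values[0], 0.6)

    def test_zero_map(self, atlas2x2):
        nodes = cp.node_summary(WeightMap("connection", np.zeros(6)), atlas2x2)
        assert np.array_equal(nodes.values, np.zeros(4))

    def test_handshake_identity(self, rng):
        """Node totals double-count every edge: Σ_nodes = 2 Σ_edges."""
        atlas = cp.scaled_canonical_atlas(20)
        w = rng.standard_normal(cp.n_edges(20))
        nodes = cp.node_summary(WeightMap("connection", w), atlas)
        assert np.isclose(nodes.values.sum(), 2.0 * w.sum())

    def test_absolute_variant(self, atlas2x2):
        w = np.array([0.6, -0.2, 0.2, 0.0, 0.0, 0.0])
        nodes = cp.node_summary(WeightMap("connection", w), atlas2x2,
                                signed=False)
        assert np.isclose(nodes.values[0], 1.0)


class TestNetworkSummary:
    def test_hand_enumeration(self, atlas2x2):
        # within-1 edge (0,1)=0.6; within-2 edge (2,3)=0.4;
        # between edges (0,2),(0,3),(1,2),(1,3) = -0.2, 0.2, -0.1, 0.1
        w = np.array([0.6, -0.2, 0.2, -0.1, 0.1, 0.4])
        cells, net_map = cp.network_summary(
            WeightMap("connection", w), atlas2x2
        )
        df = cells.cells.set_index(["net_a", "net_b"])
        assert np.isclose(df.loc[("N1", "N1"), "mean_weight"], 0.6)
        assert np.isclose(df.loc[("N2", "N2"), "mean_weight"], 0.4)
        assert np.isclose(df.loc[("N1", "N2"), "mean_weight"], 0.0)
        assert np.isclose(
            df.loc[("N1", "N2"), "positive_sum_normalized"], 0.075
        )
        assert np.isclose(
            df.loc[("N1", "N2"), "negative_sum_normalized"], -0.075
        )
        assert np.array_equal(net_map.values, df["mean_weight"].to_numpy())

    def test_constant_map(self, atlas2x2):
        c = 0.7
        cells, _ = cp.network_summary(
            WeightMap("connection", np.full(6, c)), atlas2x2
        )
        assert np.allclose(cells.cells["mean_weight"], c)
        assert np.allclose(cells.cells["positive_sum_normalized"], c)
        assert np.allclose(cells.cells["negative_sum_normalized"], 0.0)

    def test_default_atlas_has_36_cells(self):
        atlas = cp.load_default_atlas()
        w = np.zeros(cp.n_edges(246))
        cells, net_map = cp.network_summary(WeightMap("connection", w), atlas)
        assert len(cells.cells) == 36
        assert net_map.values.shape == (36,)

    def test_mean_cells_are_linear(self, rng):
        atlas = cp.scaled_canonical_atlas(20)
        a = rng.standard_normal(cp.n_edges(20))
        b = rng.standard_normal(cp.n_edges(20))
        alpha, beta = 1.7, -0.4
        _, map_a = cp.network_summary(WeightMap("connection", a), atlas)
        _, map_b = cp.network_summary(WeightMap("connection", b), atlas)
        _, map_ab = cp.network_summary(
            WeightMap("connection", alpha * a + beta * b), atlas
        )
        assert np.allclose(map_ab.values,
                           alpha * map_a.values + beta * map_b.values)

    def test_sign_split_bounds(self, rng):
        atlas = cp.scaled_canonical_atlas(20)
        w = rng.standard_normal(cp.n_edges(20))
        cells, _ = cp.network_summary(WeightMap("connection", w), atlas)
        assert (cells.cells["positive_sum_normalized"] >= 0).all()
        assert (cells.cells["negative_sum_normalized"] <= 0).all()
        recon = (
            cells.cells["positive_sum_normalized"]
            + cells.cells["negative_sum_normalized"]
        )
        assert np.allclose(recon, cells.cells["mean_weight"])


class TestOverlap:
    def test_identical_maps(self, rng):
        v = rng.standard_normal(50)
        res = cp.overlap(WeightMap("connection", v),
                         WeightMap("connection", v), n_perm=99, seed=0)
        assert np.isclose(res.r, 1.0)
        assert res.p == 1 / 100

    def test_negated_maps(self, rng):
        v = rng.standard_normal(50)
        res = cp.overlap(WeightMap("connection", v),
                         WeightMap("connection", -v), n_perm=99, seed=0)
        assert np.isclose(res.r, -1.0)
        assert res.p == 1 / 100  # two-sided

    def test_level_mismatch_rejected(self, rng):
        with pytest.raises(IncompatibleMapsError):
            cp.overlap(WeightMap("connection", np.zeros(36)),
                       WeightMap("network", np.zeros(36)))

    def test_null_centered_near_zero(self, rng):
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        res = cp.overlap(WeightMap("node", a), WeightMap("node", b),
                         n_perm=500, seed=3)
        assert res.p > 0.01 or abs(res.r) < 0.2

    def test_age_and_cognition_maps_anticorrelated(self, cohort60, atlas60):
        """The generator plants opposite loadings: the averaged age and
        cognition weight maps must be negatively correlated."""
        _, phen, edges = cohort60
        maps = {}
        for target in ("age", "gF"):
            cv = cp.ConnectomePLS.from_dataframe(
                phen, edges, target
            ).fit_repeated_cv(folds=5, reps=2, n_components=None, seed=7,
                              max_components=5)
            maps[target] = cp.average_maps(cv.fold_weight_maps)
        res = cp.overlap(maps["age"], maps["gF"], n_perm=999, seed=1)
        assert res.r < 0
        assert res.p < 0.01

    def test_network_aggregation_raises_similarity(self, atlas40):
        """Aggregating to network cells tends to raise |overlap r| relative
        to the connection level (statistical tendency across seeds)."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = cp.default_spec(atlas40, 120, noise_sd=0.8, seed=seed)
            phen, edges = cp.simulate_cohort(spec)
            maps = {}
            for target in ("age", "gF"):
                res = cp.ConnectomePLS.from_dataframe(
                    phen, edges, target
                ).fit(n_components=2)
                maps[target] = WeightMap("connection", res.params)
            r_conn = np.corrcoef(maps["age"].values, maps["gF"].values)[0, 1]
            nets = [
                cp.network_summary(maps[t], atlas40)[1].values
                for t in ("age", "gF")
            ]
            r_net = np.corrcoef(nets[0], nets[1])[0, 1]
            if abs(r_net) >= abs(r_conn):
                wins += 1
        assert wins >= n_seeds // 2
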