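"""Connectome construction, pruning and efficiency metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromediate import connectome as cn


def chain_graph():
    """3-node chain with unit weights 1-2 and 2-3, no 1-3 edge."""
    w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return cn.ConnectivityMatrix(w, ["L_A", "L_B", "R_A"])


class TestFisherZ:
    def test_fixed_point_at_zero(self):
        assert cn.fisher_z(0.0) == 0.0

    def test_matches_log_form(self):
        # arctanh(r) = 0.5*log((1+r)/(1-r)); independent closed form
        r = 0.5
        assert cn.fisher_z(r) == pytest.approx(0.5 * np.log(1.5 / 0.5), abs=1e-12)
        assert cn.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_function(self):
        assert cn.fisher_z(-0.3) == -cn.fisher_z(0.3)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_rejects_degenerate_correlations(self, r):
        with pytest.raises(ValueError):
            cn.fisher_z(r)


class TestFunctionalConnectivity:
    def test_without_nuisance_equals_pearson(self, rng):
        signals = rng.normal(size=(4, 200))
        cm = cn.functional_connectivity(signals)
        r = np.corrcoef(signals)
        np.fill_diagonal(r, 0.0)  # avoid arctanh(1) on the diagonal
        expected = np.arctanh(r)
        np.testing.assert_allclose(cm.weights, expected, atol=1e-10)

    def test_constant_residual_series_flagged_missing(self, rng):
        nuis = rng.normal(size=(1, 100))
        signals = np.vstack([nuis[0], nuis[0] * 2.0, rng.normal(size=100)])
        cm = cn.functional_connectivity(signals, nuis)
        # the two nuisance-copies have ~zero residuals: their edges are missing
        assert np.isnan(cm.weights[0, 1])
        assert np.isnan(cm.weights[0, 2])
        assert not np.isnan(cm.weights[2, 2])

    def test_partial_correlation_recursion_oracle(self, rng):
        # 3 series driven by one confounder z: the partial correlation of
        # x and y given z follows the recursion formula
        n = 200_000
        z = rng.normal(size=n)
        x = 0.6 * z + 0.8 * rng.normal(size=n)
        y = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=n)
        cm = cn.functional_connectivity(np.vstack([x, y]), z[None, :])
        r_xy, r_xz, r_yz = np.corrcoef(np.vstack([x, y, z]))[np.triu_indices(3, 1)]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert np.tanh(cm.weights[0, 1]) == pytest.approx(expected, abs=5e-3)

    def test_needs_enough_timepoints(self, rng):
        with pytest.raises(ValueError):
            cn.functional_connectivity(rng.normal(size=(3, 5)), rng.normal(size=(4, 5)))


def group_from_edges(edges: dict[tuple[int, int], list[float]], n_nodes: int):
    n_subj = len(next(iter(edges.values())))
    w = np.zeros((n_subj, n_nodes, n_nodes))
    for (i, j), vals in edges.items():
        w[:, i, j] = vals
        w[:, j, i] = vals
    labels = [f"L_N{k}" for k in range(n_nodes)]
    return cn.GroupConnectivity([f"s{k}" for k in range(n_subj)], w, labels)


class TestHolmPrune:
    A = [5, 6, 5, 6, 5]
    B = [0.01, -0.02, 0.0, 0.01, -0.01]
    C = [2, 3, 2, 3, 2]

    def handworked_group(self):
        # a triangle, so the upper matrix triangle holds exactly these 3 edges
        return group_from_edges({(0, 1): self.A, (1, 2): self.B, (0, 2): self.C}, 3)

    def test_handworked_example_pooled_sd(self):
        # pooled SD over all 15 weights = 2.3246; one-sided z p-values
        # A: 1.03e-7, C: 0.01048, B: 0.5008.  Holm at alpha=0.05 retains
        # A and C and removes only B; the second pass keeps both.
        mask, pruned = cn.holm_prune(self.handworked_group(), cn.PruneConfig(alpha=0.05))
        assert mask.removed_edges == 1
        assert not mask.mask[1, 2]  # B gone
        assert mask.mask[0, 1] and mask.mask[0, 2]  # A and C retained

    def test_handworked_example_t_variant(self):
        # per-edge t-test: t_B = -0.34 (p=.62), t_A, t_C huge -> only B removed
        mask, _ = cn.holm_prune(
            self.handworked_group(), cn.PruneConfig(alpha=0.01, statistic="t")
        )
        assert mask.removed_edges == 1
        assert not mask.mask[1, 2]

    def test_handworked_example_strict_alpha_removes_c_too(self):
        # at alpha=0.01 the pooled-SD Holm threshold for the 2nd-smallest
        # p-value is 0.005 < p_C = 0.01048, so C falls with B
        mask, _ = cn.holm_prune(self.handworked_group(), cn.PruneConfig(alpha=0.01))
        assert not mask.mask[1, 2]
        assert not mask.mask[0, 2]
        assert mask.mask[0, 1]

    def test_exact_null_edge_removed_first_iteration(self):
        group = group_from_edges({(0, 1): [3, 4, 3, 4], (1, 2): [0, 0, 0, 0]}, 3)
        mask, pruned = cn.holm_prune(group)
        assert not mask.mask[1, 2]
        assert mask.mask[0, 1]
        # the isolated third node is dropped
        assert "L_N2" in mask.removed_nodes
        assert pruned.n_nodes == 2

    def test_idempotent_on_clean_network(self):
        group = group_from_edges(
            {(0, 1): [10, 11, 10, 11, 10], (1, 2): [12, 11, 12, 11, 12],
             (0, 2): [9, 10, 9, 10, 9]}, 3
        )
        mask1, pruned1 = cn.holm_prune(group)
        assert mask1.removed_edges == 0
        mask2, pruned2 = cn.holm_prune(pruned1)
        assert mask2.removed_edges == 0
        np.testing.assert_array_equal(pruned1.weights, pruned2.weights)

    def test_permutation_equivariance(self, rng):
        n = 6
        w = np.abs(rng.normal(3, 1, size=(8, n, n)))
        w = (w + w.transpose(0, 2, 1)) / 2
        w[:, np.arange(n), np.arange(n)] = 0
        w[:, 0, 3] = w[:, 3, 0] = rng.normal(0, 0.01, size=8)  # one null edge
        labels = [f"L_N{k}" for k in range(n)]
        group = cn.GroupConnectivity(list("abcdefgh"), w, labels)
        mask, _ = cn.holm_prune(group)

        perm = rng.permutation(n)
        group_p = cn.GroupConnectivity(
            list("abcdefgh"), w[:, perm][:, :, perm], [labels[i] for i in perm]
        )
        mask_p, _ = cn.holm_prune(group_p)
        np.testing.assert_array_equal(mask.mask[perm][:, perm], mask_p.mask)

    def test_rejects_single_subject(self):
        group = group_from_edges({(0, 1): [1.0]}, 2)
        with pytest.raises(ValueError, match="at least 2 subjects"):
            cn.holm_prune(group)

    def test_all_edges_removed_is_an_error(self):
        group = group_from_edges({(0, 1): [0.001, -0.001, 0.0, 0.001]}, 2)
        with pytest.raises(ValueError, match="empty network"):
            cn.holm_prune(group)


def floyd_warshall_oracle(weights: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths on 1/weight lengths."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


class TestDistancesAndEfficiency:
    def test_chain_distances(self):
        d = cn.shortest_path_distances(chain_graph()).dij
        assert d[0, 2] == pytest.approx(2.0)
        assert d[0, 1] == pytest.approx(1.0)

    def test_complete_unit_graph(self):
        n = 5
        w = 1.0 - np.eye(n)
        labels = [f"L_N{k}" for k in range(n)]
        d = cn.shortest_path_distances(cn.ConnectivityMatrix(w, labels)).dij
        off = d[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)
        res = cn.efficiency(cn.ConnectivityMatrix(w, labels))
        np.testing.assert_allclose(res.nodal, 1.0)
        assert res.global_efficiency == pytest.approx(1.0)

    def test_isolated_node_infinite_distance_zero_efficiency(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 2.0
        cm = cn.ConnectivityMatrix(w, ["L_A", "L_B", "L_C"])
        d = cn.shortest_path_distances(cm).dij
        assert np.isinf(d[0, 2]) and np.isinf(d[2, 1])
        nodal = cn.nodal_efficiency(cn.DistanceMatrix(d))
        assert nodal[2] == 0.0

    def test_chain_nodal_and_global_efficiency(self):
        res = cn.efficiency(chain_graph())
        np.testing.assert_allclose(res.nodal, [0.75, 1.0, 0.75])
        assert res.global_efficiency == pytest.approx(5 / 6)

    def test_global_is_exactly_mean_of_nodal(self, rng):
        for _ in range(10):
            n = rng.integers(3, 10)
            w = np.abs(rng.normal(size=(n, n)))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0)
            res = cn.efficiency(cn.ConnectivityMatrix(w, [f"L_N{k}" for k in range(n)]))
            assert res.global_efficiency == np.mean(res.nodal)

    def test_scale_equivariance_on_chain(self):
        doubled = cn.ConnectivityMatrix(chain_graph().weights * 2, chain_graph().labels)
        res = cn.efficiency(doubled)
        assert res.global_efficiency == pytest.approx(5 / 3)

    def test_dijkstra_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            w = np.abs(rng.normal(size=(n, n))) * (rng.random((n, n)) < 0.6)
            w = np.triu(w, 1)
            w = w + w.T
            cm = cn.ConnectivityMatrix(w, [f"L_N{k}" for k in range(n)])
            d = cn.shortest_path_distances(cm).dij
            np.testing.assert_allclose(d, floyd_warshall_oracle(w), rtol=1e-10)

    def test_removing_an_edge_never_increases_efficiency(self, rng):
        n = 7
        w = np.abs(rng.normal(2, 1, size=(n, n)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = [f"L_N{k}" for k in range(n)]
        before = cn.efficiency(cn.ConnectivityMatrix(w, labels)).nodal
        w2 = w.copy()
        w2[0, 1] = w2[1, 0] = 0.0
        after = cn.efficiency(cn.ConnectivityMatrix(w2, labels)).nodal
        assert np.all(after <= before + 1e-12)

    def test_negative_weights_rejected_unless_clipped(self):
        w = np.array([[0, -0.5], [-0.5, 0]])
        cm = cn.ConnectivityMatrix(w, ["L_A", "R_A"])
        with pytest.raises(ValueError):
            cn.shortest_path_distances(cm)
        d = cn.shortest_path_distances(cm, clip_negative=True).dij
        assert np.isinf(d[0, 1])

    def test_global_efficiency_rejects_empty(self):
        with pytest.raises(ValueError):
            cn.global_efficiency(np.array([]))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(0.1, 10.0))
def test_efficiency_scales_linearly_with_weights(scale):
    base = chain_graph()
    scaled = cn.ConnectivityMatrix(base.weights * scale, base.labels)
    e0 = cn.efficiency(base).global_efficiency
    e1 = cn.efficiency(scaled).global_efficiency
    assert e1 == pytest.approx(scale * e0, rel=1e-9)


class TestAverageHemispheres:
    def test_bilateral_mean(self):
        import pandas as pd

        df = pd.DataFrame({"L_V1": [2.0], "R_V1": [4.0], "L_X": [1.0]})
        out = cn.average_hemispheres(df)
        assert out.loc[0, "V1"] == 3.0
        assert out.loc[0, "X"] == 1.0  # single-hemisphere rule

    def test_full_parcellation_region_count(self):
        import pandas as pd

        labels = [f"{h}_A{i:03d}" for h in "LR" for i in range(180)] + [
            f"{h}_SC{i}" for h in "LR" for i in range(8)
        ]
        df = pd.DataFrame(np.ones((2, len(labels))), columns=labels)
        out = cn.average_hemispheres(df)
        assert len(labels) == 376
        assert out.shape[1] == 188

    def test_unparseable_label_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            cn.average_hemispheres(pd.DataFrame({"V1": [1.0]}))


def test_matrix_tsv_round_trip(tmp_path, rng):
    w = np.abs(rng.normal(size=(4, 4)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    cm = cn.ConnectivityMatrix(w, ["L_A", "L_B", "R_A", "R_B"])
    cn.write_matrix_tsv(cm, tmp_path / "m.tsv")
    back = cn.read_matrix_tsv(tmp_path / "m.tsv")
    assert back.labels == cm.labels
    np.testing.assert_allclose(back.weights, cm.weights, rtol=1e-8)
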