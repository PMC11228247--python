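"""Proximity networks, K_avg, α-linkage, outer-ring and half-islet analyses."""

import math

import numpy as np
import pytest

from isletnet import (
    CellRecord,
    IsletMap,
    RimPolygon,
    alpha_link_partition,
    build_network,
    degree_correlation,
    degree_summary,
    half_islet_proportions,
    k_avg,
    outer_ring_immune_networks,
)

from conftest import manual_islet


class TestBuildNetwork:
    def test_forced_edge_set(self):
        # Large square rim so every cell is inside it.
        rim = RimPolygon(np.array([(-100, -100), (100, -100), (100, 100), (-100, 100)], float))
        cells = [
            ("a0", "alpha", 0.0, 0.0),
            ("t0", "T", 10.0, 0.0),
            ("t1", "T", 15.0, 0.0),
            ("a1", "alpha", 50.0, 0.0),
            ("t2", "T", 60.0, 0.0),
        ]
        net = build_network(manual_islet(rim, cells), {"alpha", "T"}, 20.0)
        assert net.edges == {("a0", "t0"), ("a0", "t1"), ("a1", "t2")}
        assert k_avg(net, "alpha") == pytest.approx(1.5)
        assert k_avg(net, "T") == pytest.approx(1.0)

    def test_inclusive_boundary(self, circle_rim):
        cells = [("a0", "alpha", 0.0, 0.0), ("t0", "T", 20.0, 0.0)]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "T"}, 20.0)
        assert ("a0", "t0") in net.edges

    def test_strictly_beyond_threshold_excluded(self, circle_rim):
        cells = [("a0", "alpha", 0.0, 0.0), ("t0", "T", 20.0001, 0.0)]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "T"}, 20.0)
        assert not net.edges

    def test_homotypic_links_never_formed(self, circle_rim):
        cells = [("a0", "alpha", 0.0, 0.0), ("a1", "alpha", 5.0, 0.0)]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "beta"}, 20.0)
        assert not net.edges

    def test_immune_margin_rule(self, circle_rim):
        # Rim radius 50: T at 69 is within the 20 um margin, T at 72 not.
        cells = [
            ("a0", "alpha", 45.0, 0.0),
            ("t_in", "T", 69.0, 0.0),
            ("t_out", "T", 72.0, 0.0),
        ]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "T"}, 25.0)
        assert set(net.nodes) == {"a0", "t_in"}

    def test_endocrine_outside_rim_excluded(self, circle_rim):
        cells = [("a0", "alpha", 55.0, 0.0), ("b0", "beta", 0.0, 0.0)]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "beta"}, 20.0)
        assert set(net.nodes) == {"b0"}

    def test_unknown_type_rejected(self, circle_rim):
        islet = manual_islet(circle_rim, [("a0", "alpha", 0.0, 0.0)])
        with pytest.raises(ValueError):
            build_network(islet, {"alpha", "gamma"}, 20.0)

    def test_nonstandard_threshold_warns(self, circle_rim):
        islet = manual_islet(circle_rim, [("a0", "alpha", 0.0, 0.0)])
        with pytest.warns(UserWarning):
            build_network(islet, {"alpha", "T"}, 17.0)

    @pytest.mark.parametrize("threshold", [15.0, 20.0, 25.0])
    def test_kdtree_equals_bruteforce(self, islet_factory, threshold):
        for seed in range(5):
            islet = islet_factory(seed=seed, target_t_beta_ratio=0.8)
            fast = build_network(islet, {"alpha", "beta", "T"}, threshold)
            slow = build_network(islet, {"alpha", "beta", "T"}, threshold, method="brute")
            assert fast.edges == slow.edges

    def test_rigid_motion_invariance(self, islet_factory):
        islet = islet_factory(seed=3, target_t_beta_ratio=0.5)
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([40.0, -7.0])
        moved = IsletMap(
            islet_id="m",
            mouse_id="m1",
            rim=RimPolygon(islet.rim.vertices @ rot.T + shift),
            cells=[
                CellRecord(c.cell_id, c.cell_type, *(rot @ (c.x, c.y) + shift))
                for c in islet.cells
            ],
        )
        a = build_network(islet, {"alpha", "T"}, 20.0)
        b = build_network(moved, {"alpha", "T"}, 20.0)
        assert a.edges == b.edges


class TestKavg:
    def test_degree_sum_identity(self, islet_factory):
        for seed in range(5):
            islet = islet_factory(seed=seed, target_t_beta_ratio=0.6)
            net = build_network(islet, {"alpha", "T"}, 20.0)
            n_a = sum(1 for t in net.nodes.values() if t == "alpha")
            n_t = sum(1 for t in net.nodes.values() if t == "T")
            if n_a and n_t:
                assert k_avg(net, "alpha") * n_a == pytest.approx(len(net.edges))
                assert k_avg(net, "T") * n_t == pytest.approx(len(net.edges))
                # K_avg of a type cannot exceed the other type's count.
                assert k_avg(net, "alpha") <= n_t

    def test_absent_type_is_nan(self, circle_rim):
        islet = manual_islet(circle_rim, [("a0", "alpha", 0.0, 0.0)])
        net = build_network(islet, {"alpha", "T"}, 20.0)
        assert math.isnan(k_avg(net, "T"))

    def test_empty_network_zero_for_present_types(self, circle_rim):
        cells = [("a0", "alpha", 0.0, 0.0), ("t0", "T", 45.0, 0.0)]
        net = build_network(manual_islet(circle_rim, cells), {"alpha", "T"}, 20.0)
        assert k_avg(net, "alpha") == 0.0 and k_avg(net, "T") == 0.0

    def test_degree_summary_matches_kavg(self, islet_factory):
        islet = islet_factory(seed=9, target_t_beta_ratio=0.5)
        net = build_network(islet, {"alpha", "beta", "T"}, 20.0)
        summ = degree_summary(net)
        for t in summ.k_avg:
            assert summ.k_avg[t] == pytest.approx(k_avg(net, t))

    def test_to_networkx_round_trip(self, islet_factory):
        islet = islet_factory(seed=2)
        net = build_network(islet, {"alpha", "beta"}, 20.0)
        g = net.to_networkx()
        assert g.number_of_nodes() == len(net.nodes)
        assert g.number_of_edges() == len(net.edges)


class TestThresholdMonotonicity:
    def test_edge_sets_nested(self, islet_factory):
        for seed in range(5):
            islet = islet_factory(seed=seed, target_t_beta_ratio=0.7)
            nets = {
                t: build_network(islet, {"alpha", "beta", "T"}, t).edges
                for t in (15.0, 20.0, 25.0)
            }
            assert nets[15.0] <= nets[20.0] <= nets[25.0]

    def test_alpha_linked_set_nested(self, islet_factory):
        for seed in range(5):
            islet = islet_factory(seed=seed)
            p15 = alpha_link_partition(islet, 15.0)
            p25 = alpha_link_partition(islet, 25.0)
            assert p15.alpha_linked_beta <= p25.alpha_linked_beta


class TestAlphaLinkPartition:
    def test_linked_and_unlinked(self, circle_rim):
        cells = [
            ("b0", "beta", 0.0, 0.0),
            ("a0", "alpha", 15.0, 0.0),
            ("b1", "beta", 0.0, -40.0),
        ]
        part = alpha_link_partition(manual_islet(circle_rim, cells), 20.0)
        assert part.alpha_linked_beta == {"b0"}
        assert part.non_alpha_linked_beta == {"b1"}

    def test_partition_is_disjoint_cover(self, islet_factory):
        islet = islet_factory(seed=4)
        part = alpha_link_partition(islet, 20.0)
        betas = set(islet.ids_of_type("beta"))
        assert part.alpha_linked_beta | part.non_alpha_linked_beta == betas
        assert not (part.alpha_linked_beta & part.non_alpha_linked_beta)

    def test_restriction_limits_alpha_donors(self, circle_rim):
        cells = [("b0", "beta", 0.0, 0.0), ("a0", "alpha", 15.0, 0.0)]
        part = alpha_link_partition(
            manual_islet(circle_rim, cells), 20.0, restrict_to={"b0"}
        )
        assert part.non_alpha_linked_beta == {"b0"}


class TestOuterRing:
    def test_no_immune_cells_gives_zero(self, circle_rim):
        cells = [
            ("a0", "alpha", 45.0, 0.0),
            ("b0", "beta", 40.0, 0.0),
            ("b1", "beta", -45.0, 0.0),
        ]
        _, _, k_l, k_n = outer_ring_immune_networks(
            manual_islet(circle_rim, cells), "T"
        )
        assert k_l == 0.0 and k_n == 0.0

    def test_empty_subset_is_nan(self, circle_rim):
        # All ring beta-cells are alpha-linked: the non-linked side is
        # undefined for this islet.
        cells = [("a0", "alpha", 45.0, 0.0), ("b0", "beta", 40.0, 0.0)]
        _, _, k_l, k_n = outer_ring_immune_networks(
            manual_islet(circle_rim, cells), "T"
        )
        assert k_l == 0.0 and math.isnan(k_n)

    def test_linked_beta_receive_the_links(self, circle_rim):
        cells = [
            ("a0", "alpha", 45.0, 0.0),
            ("b_link", "beta", 40.0, 0.0),
            ("b_far", "beta", -45.0, 0.0),
            ("t0", "T", 55.0, 0.0),
        ]
        _, _, k_l, k_n = outer_ring_immune_networks(
            manual_islet(circle_rim, cells), "T", threshold=20.0
        )
        assert k_l == 1.0 and k_n == 0.0


class TestHalfIsletProportions:
    def test_mirror_symmetric(self, square_rim):
        cells = [
            ("a0", "alpha", -5.0, 0.0), ("a1", "alpha", 5.0, 0.0),
            ("t0", "T", -11.0, 0.0), ("t1", "T", 11.0, 0.0),
        ]
        res = half_islet_proportions(manual_islet(square_rim, cells), "vertical")
        assert res.proportions["alpha"] == (0.5, 0.5)
        assert res.proportions["T"] == (0.5, 0.5)

    def test_fully_polarized(self, square_rim):
        cells = [
            ("a0", "alpha", -5.0, 0.0), ("a1", "alpha", -6.0, 2.0),
            ("t0", "T", -11.0, 0.0),
        ]
        res = half_islet_proportions(manual_islet(square_rim, cells), "vertical")
        assert res.proportions["alpha"] == (1.0, 0.0)
        assert res.proportions["T"] == (1.0, 0.0)

    def test_absent_type_is_missing(self, square_rim):
        res = half_islet_proportions(
            manual_islet(square_rim, [("b0", "beta", 0.0, 0.0)]), "vertical"
        )
        assert res.proportions["myeloid"] is None

    def test_proportions_sum_to_one(self, islet_factory):
        islet = islet_factory(seed=6)
        res = half_islet_proportions(islet, "horizontal")
        for prop in res.proportions.values():
            if prop is not None:
                assert prop[0] + prop[1] == pytest.approx(1.0)


class TestDegreeCorrelation:
    def test_pair_with_itself_is_identity(self, islet_factory):
        cohort = [islet_factory(seed=s, target_t_beta_ratio=0.5) for s in range(6)]
        res = degree_correlation(cohort, ("beta", "T"), ("beta", "T"))
        assert res["slope"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_too_few_islets_rejected(self, islet_factory):
        with pytest.raises(ValueError):
            degree_correlation(
                [islet_factory(seed=0)], ("beta", "T"), ("beta", "macrophage")
            )
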