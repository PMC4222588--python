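import numpy as np
import pytest

import callusim as cs
from callusim.params import VesselParams
from callusim.scenarios import toy_fixture, standard_compromised, host_case
from callusim.vasculature import (Branch, VesselNetwork, seed_vessels,
                                  migrate_tips, anastomose, active_segments,
                                  branch_and_select_tips, network_edges)


def _single_tip_network(pos, direction=(-1.0, 0.0)):
    net = VesselNetwork()
    p0 = np.asarray(pos) - 0.05 * np.asarray(direction)
    net.add_branch(Branch([p0, np.asarray(pos, float)], parent=None))
    return net


class TestMigration:
    def test_no_gradient_no_noise_no_motion(self, gradient_corridor, rng):
        dom, st, _ = gradient_corridor
        gv = np.full(dom.shape, 1.0)          # flat, above threshold
        params = VesselParams(noise_weight=0.0, persistence=0.0)
        net = _single_tip_network((2.0, 1.0))
        tip_before = net.branches[0].tip.copy()
        migrate_tips(net, gv, dom, 0.25, rng, params)
        assert np.allclose(net.branches[0].tip, tip_before)

    def test_below_sprouting_threshold_no_motion(self, gradient_corridor, rng):
        dom, st, _ = gradient_corridor
        net = _single_tip_network((0.2, 1.0))   # gv ~ 0.05 < threshold
        tip_before = net.branches[0].tip.copy()
        migrate_tips(net, st.gv, dom, 0.25, rng)
        assert np.allclose(net.branches[0].tip, tip_before)

    def test_tip_climbs_gradient(self, gradient_corridor):
        dom, st, _ = gradient_corridor
        net = _single_tip_network((2.0, 1.0))
        params = VesselParams(noise_weight=0.0, v_tip=0.2)
        rng = np.random.default_rng(0)
        for _ in range(10):
            migrate_tips(net, st.gv, dom, 0.25, rng, params)
        # g_v grows with x in this corridor
        assert net.branches[0].tip[0] > 2.0

    def test_fixed_seed_reproducible(self, gradient_corridor):
        dom, st, _ = gradient_corridor
        tips = []
        for _ in range(2):
            net = _single_tip_network((2.0, 1.0))
            rng = np.random.default_rng(42)
            for _ in range(20):
                migrate_tips(net, st.gv, dom, 0.25, rng)
            tips.append(net.branches[0].tip.copy())
        assert np.array_equal(tips[0], tips[1])


class TestAnastomosis:
    def _long_branch(self, y, x0=0.0, x1=2.0, n=40):
        pts = [np.array([x0 + (x1 - x0) * k / n, y]) for k in range(n + 1)]
        return Branch(pts)

    def test_parallel_branches_do_not_fuse(self):
        net = VesselNetwork()
        net.add_branch(self._long_branch(0.5))
        net.add_branch(self._long_branch(1.5))
        anastomose(net, radius=0.1)
        assert net.junctions == []
        assert all(b.tip_active for b in net.branches)

    def test_tip_crossing_a_segment_fuses_once(self):
        net = VesselNetwork()
        net.add_branch(self._long_branch(1.0))            # horizontal
        vert = [np.array([1.0, 2.0 - 0.05 * k]) for k in range(20)]
        net.add_branch(Branch(vert))                      # descends onto it
        anastomose(net, radius=0.08,
                   params=VesselParams(min_fusion_length=0.3))
        assert len(net.junctions) == 1
        assert net.branches[1].tip_active is False

    def test_three_branch_fusion_count_matches_geometry(self):
        # geometric oracle: only the one tip within the radius fuses
        net = VesselNetwork()
        net.add_branch(self._long_branch(1.0))
        near = [np.array([0.5, 1.56 - 0.05 * k]) for k in range(11)]  # ends 0.06 above
        far = [np.array([1.5, 2.6 - 0.05 * k]) for k in range(11)]    # ends 1.06 above
        net.add_branch(Branch(near))
        net.add_branch(Branch(far))
        anastomose(net, radius=0.08,
                   params=VesselParams(min_fusion_length=0.3))
        assert len(net.junctions) == 1
        assert net.junctions[0][0] == 1
        assert net.branches[2].tip_active is True

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            anastomose(VesselNetwork(), radius=0.0)


class TestActivity:
    def test_seed_connected_branch_is_active(self):
        net = VesselNetwork()
        s = net.add_branch(Branch([np.zeros(2), np.array([0.1, 0.0])],
                                  is_seed=True))
        child = net.add_branch(Branch([np.array([0.1, 0.0]),
                                       np.array([0.2, 0.0])], parent=s))
        active_segments(net)
        assert net.active[s] and net.active[child]

    def test_orphan_fragment_is_inactive(self):
        net = VesselNetwork()
        net.add_branch(Branch([np.zeros(2), np.array([0.1, 0.0])],
                              is_seed=True))
        orphan = net.add_branch(Branch([np.array([2.0, 2.0]),
                                        np.array([2.1, 2.0])]))
        active_segments(net)
        assert net.active[orphan] is False


class TestSeeding:
    def test_case_A_covers_the_full_gap(self, desk_params):
        dom = cs.build_domain(5.0, 0.25)
        net = seed_vessels(dom, host_case("A", 5.0), desk_params.vessels)
        muscle_x = [b.points[0][0] for b in net.branches
                    if b.is_seed and b.points[0][1] > 1.25]
        assert min(muscle_x) < 0.3 and max(muscle_x) > 2.2

    def test_case_B_covers_a_subinterval(self, desk_params):
        dom = cs.build_domain(5.0, 0.25)
        net = seed_vessels(dom, host_case("B", 5.0), desk_params.vessels)
        muscle_x = [b.points[0][0] for b in net.branches
                    if b.is_seed and b.points[0][1] > 1.25]
        assert min(muscle_x) > 1.0        # only the outer half of the gap

    def test_standard_seeds_near_bony_end(self, desk_params):
        dom = cs.build_domain(5.0, 0.25)
        net = seed_vessels(dom, standard_compromised(5.0), desk_params.vessels)
        assert all(min(p[0] for p in b.points) > dom.half_gap
                   for b in net.branches)
        assert all(net.active)


def test_branching_denser_in_high_vegf_corridor(gradient_corridor):
    # one-sided comparison over replicate seeds
    dom, st, _ = gradient_corridor
    lo = np.full(dom.shape, 0.3)
    hi = np.full(dom.shape, 2.0)
    counts = {"lo": 0, "hi": 0}
    for level, gv in (("lo", lo), ("hi", hi)):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = VesselNetwork()
            pts = [np.array([1.0 + 0.05 * k, 1.0]) for k in range(30)]
            net.add_branch(Branch(pts))
            for _ in range(30):
                branch_and_select_tips(net, gv, dom, rng)
            counts[level] += len(net.branches) - 1
    assert counts["hi"] > counts["lo"]


def test_edge_list_export_shape(gradient_corridor):
    _, _, net = gradient_corridor
    rows = network_edges(net)
    assert rows and set(rows[0]) == {"x1", "y1", "x2", "y2", "branch", "active"}
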