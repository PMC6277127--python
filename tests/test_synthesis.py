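import numpy as np
import pytest

import microvasc as mv
from microvasc.network import DomainDescriptor
from microvasc.solver import BoundaryConditions, solve_pressure_flow
from microvasc.synthesis import (
    CorticalTargets,
    DistSpec,
    GrowthTree,
    SynthesisConfig,
    apply_tortuosity,
    close_capillary_bed,
    grow_tree,
    optimize_bifurcation,
    sample_terminal_sites,
)

DOM = DomainDescriptor(lx=1000, ly=1000, depth=1000)


def murray_violation(tree):
    g = tree.gamma
    viol = 0.0
    for j, ch in enumerate(tree.children):
        if len(ch) >= 2:
            lhs = tree.diameters[j] ** g
            rhs = sum(tree.diameters[c] ** g for c in ch)
            viol = max(viol, abs(lhs - rhs) / lhs)
    return viol


class TestTerminalSites:
    def test_single_point_inside_domain(self):
        pts = sample_terminal_sites(DOM, 1, 0.0, np.random.default_rng(0))
        assert DOM.contains(pts).all()

    def test_min_separation_holds(self):
        pts = sample_terminal_sites(DOM, 100, 20.0, np.random.default_rng(1))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 20.0

    def test_same_seed_identical(self):
        a = sample_terminal_sites(DOM, 50, 15.0, np.random.default_rng(7))
        b = sample_terminal_sites(DOM, 50, 15.0, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError, match="min_sep"):
            sample_terminal_sites(DOM, 500, 400.0, np.random.default_rng(0))


class TestRecomputeDiameters:
    def test_murray_mode_closed_form(self):
        tree = GrowthTree([0, 0, 0], [0, 0, -100], gamma=3.0)
        tree._insert(0, np.array([0, 0, -50.0]), np.array([50, 0, -100.0]))
        d = tree.recompute_diameters(mode="murray", terminal_diameters=6.0)
        assert d[0] == pytest.approx(6.0 * 2 ** (1 / 3), rel=1e-12)

    def test_chain_keeps_diameter(self):
        tree = GrowthTree([0, 0, 0], [0, 0, -100], gamma=3.0)
        d = tree.recompute_diameters(mode="murray", terminal_diameters=5.0)
        assert d[0] == pytest.approx(5.0)

    def test_random_tree_murray_invariant(self):
        rng = np.random.default_rng(5)
        cfg = SynthesisConfig(domain=DOM, n_terminals=50, rng_seed=5)
        tree = grow_tree(cfg, rng=rng)
        assert murray_violation(tree) <= 1e-9

    def test_cycle_rejected(self):
        tree = GrowthTree([0, 0, 0], [0, 0, -100])
        tree.children[0] = [0]  # malformed self-cycle
        with pytest.raises(ValueError, match="cycle"):
            tree.recompute_diameters(mode="murray", terminal_diameters=5.0)


class TestOptimizeBifurcation:
    def test_mirror_symmetry_of_the_volume_objective(self):
        # reflecting the configuration reflects the optimum (and adding a
        # terminal always increases volume)
        tree = GrowthTree([0, 500, 0], [1000, 500, 0], gamma=3.0)
        t = np.array([500.0, 800.0, 0.0])
        x, dv = optimize_bifurcation(tree, 0, t, domain=DOM)
        assert dv > 0
        mirrored = GrowthTree([1000, 500, 0], [0, 500, 0], gamma=3.0)
        xm, dvm = optimize_bifurcation(mirrored, 0, t, domain=DOM)
        assert abs((1000.0 - xm[0]) - x[0]) <= 5.0
        assert dvm == pytest.approx(dv, rel=0.01)
        # the optimum stays in the plane of the three points
        assert abs(x[2]) <= 2.0

    def test_beats_random_candidate_points(self):
        rng = np.random.default_rng(3)
        cfg = SynthesisConfig(domain=DOM, n_terminals=12)
        tree = grow_tree(cfg, rng=np.random.default_rng(12))
        t = np.array([600.0, 420.0, -350.0])
        seg = 3
        x_star, dv_star = optimize_bifurcation(tree, seg, t, domain=DOM)

        def volume_with(x):
            jd, jt = tree._insert(seg, x, t)
            tree.recompute_diameters(mode="balanced")
            v = tree.volume()
            tree._undo_insert(seg, jd, jt)
            tree.recompute_diameters(mode="balanced")
            return v

        v_star = volume_with(x_star)
        for _ in range(20):
            x_rand = np.array(
                [rng.uniform(0, 1000), rng.uniform(0, 1000), -rng.uniform(0, 1000)]
            )
            assert v_star <= volume_with(x_rand) + 1e-9 * v_star

    def test_degenerate_collinear_falls_back(self):
        tree = GrowthTree([0, 500, 0], [1000, 500, 0], gamma=3.0)
        t = np.array([500.0, 500.0, 0.0])  # on the segment itself
        x, dv = optimize_bifurcation(tree, 0, t, domain=DOM)
        assert np.all(np.isfinite(x))


class TestGrowTree:
    def test_exact_terminal_count(self):
        cfg = SynthesisConfig(domain=DOM, n_terminals=200, rng_seed=2)
        tree = grow_tree(cfg, rng=np.random.default_rng(2))
        assert len(tree.terminal_segments()) == 200
        assert murray_violation(tree) <= 1e-9

    def test_same_seed_identical_topology(self):
        cfg = SynthesisConfig(domain=DOM, n_terminals=25, rng_seed=9)
        t1 = grow_tree(cfg, rng=np.random.default_rng(9))
        t2 = grow_tree(cfg, rng=np.random.default_rng(9))
        assert t1.seg_tail == t2.seg_tail and t1.seg_head == t2.seg_head
        np.testing.assert_array_equal(np.asarray(t1.node_pos), np.asarray(t2.node_pos))
        np.testing.assert_array_equal(t1.diameters, t2.diameters)

    def test_terminals_inside_domain_and_volume_monotone(self):
        cfg = SynthesisConfig(domain=DOM, n_terminals=30, rng_seed=4)
        tree = grow_tree(cfg, rng=np.random.default_rng(4))
        pos = np.asarray(tree.node_pos)
        assert DOM.contains(pos).all()

    def test_equal_terminal_outflows_under_poiseuille(self):
        """Balanced diameters equalise single-phase terminal flows."""
        cfg = SynthesisConfig(domain=DOM, n_terminals=40, rng_seed=6, terminal_diameter=8.0)
        tree = grow_tree(cfg, rng=np.random.default_rng(6))
        net = tree.to_network(DOM, root_role="arterial_inlet", terminal_role="venous_outlet")
        h = np.full(net.n_segments, 0.35)
        _, Q = solve_pressure_flow(net, h, BoundaryConditions())
        term = [j for j, ch in enumerate(tree.children) if not ch]
        tq = np.abs(Q[term])
        spread = (tq.max() - tq.min()) / tq.mean()
        assert spread <= 0.05


class TestTortuosity:
    def _line_net(self, n=50):
        rng = np.random.default_rng(0)
        nodes = [[i * 37.0, 500 + 11 * np.sin(i), -40.0 * i / n - 1] for i in range(n + 1)]
        net = mv.VascularNetwork(
            node_ids=range(n + 1),
            positions=np.array(nodes, float),
            roles=["arterial_inlet"] + ["interior"] * (n - 1) + ["venous_outlet"],
            seg_ids=range(n),
            tails=range(n),
            heads=range(1, n + 1),
            diameters=np.full(n, 6.0),
        )
        return net

    def test_point_mass_unity_identity(self):
        net = self._line_net()
        before = net.positions.copy()
        apply_tortuosity(net, DistSpec("point", 1.0), np.random.default_rng(1))
        np.testing.assert_allclose(net.lengths, net.chords(), rtol=1e-9)
        np.testing.assert_array_equal(net.positions, before)

    def test_point_mass_1p2_achieved_within_numeric_tolerance(self):
        net = self._line_net()
        apply_tortuosity(net, DistSpec("point", 1.2), np.random.default_rng(2))
        tau = net.lengths / net.chords()
        assert np.all((tau >= 1.18) & (tau <= 1.22))

    def test_endpoints_unchanged(self):
        net = self._line_net()
        a0 = net.positions[net.tail_idx].copy()
        b0 = net.positions[net.head_idx].copy()
        apply_tortuosity(net, DistSpec("normal", 1.3, 0.1, 1.0, 1.6), np.random.default_rng(3))
        np.testing.assert_allclose(net.positions[net.tail_idx], a0, atol=1e-9)
        np.testing.assert_allclose(net.positions[net.head_idx], b0, atol=1e-9)
        # control points bow away from the chord
        assert any(cp is not None for cp in net.control_points)

    def test_support_below_one_rejected(self):
        net = self._line_net()
        with pytest.raises(ValueError):
            apply_tortuosity(net, DistSpec("point", 0.8), np.random.default_rng(0))


class TestCapillaryClosure:
    def _fragment(self, side, seed):
        cfg = SynthesisConfig(domain=DOM, n_terminals=8, rng_seed=seed, terminal_diameter=6.0)
        tree = grow_tree(cfg, rng=np.random.default_rng(seed))
        role = "arterial_inlet" if side == "arterial" else "venous_outlet"
        comp = "PEC" if side == "arterial" else "POC"
        return tree.to_network(DOM, root_role=role, compartment=comp)

    def test_two_fragments_closed_without_dangling_nodes(self):
        art = self._fragment("arterial", 21)
        ven = self._fragment("venous", 22)
        cfg = SynthesisConfig(domain=DOM)
        net = close_capillary_bed(art, ven, cfg, np.random.default_rng(5))
        diag = mv.validate(net)
        assert diag["n_dangling_interior"] == 0
        assert diag["n_components"] == 1
        cap = net.compartments == "CAP"
        assert cap.sum() > 0
        assert np.all(net.diameters[cap] < 6.0)

    def test_single_pair_yields_single_chain(self):
        art = GrowthTree([0, 500, 0], [400, 500, -300]).to_network(DOM, "arterial_inlet", compartment="PEC")
        ven = GrowthTree([1000, 500, 0], [600, 500, -300]).to_network(DOM, "venous_outlet", compartment="POC")
        net = close_capillary_bed(art, ven, SynthesisConfig(domain=DOM), np.random.default_rng(1), mode="chain")
        assert len(net.inlet_idx) == 1 and len(net.outlet_idx) == 1
        diag = mv.validate(net)
        assert diag["n_dangling_interior"] == 0


class TestCorticalSample:
    def test_densities_and_structure(self, small_sample, small_targets):
        diag = mv.validate(small_sample)
        assert diag["n_components"] == 1
        assert diag["n_dangling_interior"] == 0
        assert diag["n_multifurcations"] < 250
        # everything inside the closed slab: nothing severed at the bounds
        assert small_sample.domain.contains(small_sample.positions).all()
        cap = small_sample.compartments == "CAP"
        assert np.all(small_sample.diameters[cap] < 6.0)

    def test_determinism_same_seed(self, small_targets):
        n1 = mv.synthesize_cortical_sample(small_targets, rng=77)
        n2 = mv.synthesize_cortical_sample(small_targets, rng=77)
        assert n1.n_segments == n2.n_segments
        np.testing.assert_array_equal(n1.tails, n2.tails)
        np.testing.assert_allclose(n1.positions, n2.positions, rtol=0, atol=0)
        np.testing.assert_allclose(n1.diameters, n2.diameters, rtol=0, atol=0)

    def test_compartments_cover_the_hierarchy(self, small_sample):
        comps = set(small_sample.compartments.tolist())
        assert comps == {"PIA", "PEA", "PEC", "CAP", "POC", "AV", "PV"}


class TestMcaTerritory:
    def test_root_diameter_and_penetrating_density(self):
        net = mv.synthesize_mca_territory(scale=0.05, rng=3)
        assert net.diameters[0] == pytest.approx(142.0)
        # penetrating arteriole surface density ~ 13 per mm^2
        pea = np.flatnonzero(net.compartments == "PEA")
        tops = {int(net.tail_idx[k]) for k in pea} - {int(net.head_idx[k]) for k in pea}
        area = net.domain.lx * net.domain.ly / 1e6
        density = len(tops) / area
        assert 10.0 <= density <= 16.0

    def test_scale_below_one_mm2_rejected(self):
        with pytest.raises(ValueError):
            mv.synthesize_mca_territory(scale=0.01, rng=0)
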