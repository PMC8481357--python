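"""Meshfree Stokes solver: discretization, solves, forces, scenes.

Heavier validation (Wannier benchmark at three gaps, manufactured-solution
convergence order, two-body reciprocity at fine resolution) lives in the
acceptance suite; these tests cover contracts and physics at small sizes.
"""

import numpy as np
import pytest

from zorbkit.errors import AdaptiveError, ArgumentError, GeometryError
from zorbkit.gmls import GMLSConfig
from zorbkit.stokes import (
    ColonySceneConfig,
    FluidDomain,
    GlidingSceneConfig,
    RigidBody,
    StokesSystem,
    adaptive_solve,
    convergence_order,
    discretize,
    manufactured_case,
    scene_colonies,
    scene_gliding_bacteria,
    solve_stokes,
    traction_force,
)
from zorbkit.wannier import taylor_couette_inner_torque, taylor_couette_velocity

CFG = GMLSConfig(order=4)
UNIT_DOMAIN = FluidDomain(drop_radius_um=1.0, nu_m2_s=1.0, rho_kg_m3=1.0)


def disk(body_id, pos, r, v=(0.0, 0.0), omega=0.0):
    return RigidBody(body_id=body_id, shape="disk", position=pos,
                     radius_um=r, velocity_um_s=v,
                     angular_velocity_rad_s=omega)


class TestDiscretize:
    def test_empty_drop_boundary_node_count_and_placement(self):
        nodes = discretize(UNIT_DOMAIN, [], 0.1, CFG)
        wall = nodes.positions[nodes.node_kind == "drop_boundary"]
        assert len(wall) >= 62  # 2 pi / 0.1
        assert np.max(np.abs(np.linalg.norm(wall, axis=1) - 1.0)) < 1e-10

    def test_no_interior_nodes_inside_bodies(self):
        body = disk(0, (0.2, 0.1), 0.3)
        nodes = discretize(UNIT_DOMAIN, [body], 0.08, CFG)
        fluid = nodes.positions[nodes.node_kind == "fluid"]
        assert np.all(body.sdf(fluid) > 0)

    def test_body_touching_wall_rejected(self):
        with pytest.raises(GeometryError):
            discretize(UNIT_DOMAIN, [disk(0, (0.8, 0.0), 0.3)], 0.1, CFG)

    def test_overlapping_bodies_rejected(self):
        with pytest.raises(GeometryError):
            discretize(UNIT_DOMAIN,
                       [disk(0, (-0.1, 0.0), 0.25),
                        disk(1, (0.1, 0.0), 0.25)], 0.1, CFG)

    def test_narrow_gap_receives_refined_nodes(self):
        """Two disks separated by less than the base spacing: local node
        spacing in the gap drops to at most half the gap width."""
        bodies = [disk(0, (-0.33, 0.0), 0.3), disk(1, (0.32, 0.0), 0.3)]
        sep = 0.65 - 0.6  # 0.05
        nodes = discretize(UNIT_DOMAIN, bodies, 0.1, CFG)
        mid = np.array([-0.005, 0.0])
        near_gap = np.linalg.norm(nodes.positions - mid, axis=1) < sep
        assert near_gap.any()
        assert nodes.spacing[near_gap].min() <= sep / 2

    def test_capsule_boundary_nodes_on_surface(self):
        body = RigidBody(body_id=0, shape="capsule", position=(0.0, 0.0),
                         length_um=0.8, width_um=0.2, orientation_rad=0.4,
                         velocity_um_s=(0, 0))
        nodes = discretize(UNIT_DOMAIN, [body], 0.06, CFG)
        surf = nodes.positions[nodes.node_kind == "body_boundary"]
        assert len(surf) > 20
        assert np.max(np.abs(body.sdf(surf))) < 1e-9


class TestSolve:
    def test_quiescent_null(self):
        """Zero boundary data: zero fields, zero force and torque."""
        body = disk(0, (0.2, 0.0), 0.3)
        nodes = discretize(UNIT_DOMAIN, [body], 0.1, CFG)
        sol = solve_stokes(nodes, UNIT_DOMAIN, [body], CFG)
        assert np.max(np.abs(sol.velocity)) < 1e-12
        assert np.ptp(sol.q) < 1e-12
        bf = traction_force(sol, body)
        assert np.linalg.norm(bf.force_N) < 1e-12
        assert abs(bf.torque_Nm) < 1e-12

    def test_taylor_couette_velocity_and_torque(self):
        """Rotating concentric disk: azimuthal profile within 0.5 %, torque
        within 1 % of the closed form."""
        body = disk(0, (0.0, 0.0), 0.4, omega=1.0)
        nodes = discretize(UNIT_DOMAIN, [body], 0.04, CFG)
        sol = solve_stokes(nodes, UNIT_DOMAIN, [body], CFG)
        r = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        u, _, _ = sol.fields_at(np.column_stack([r, np.zeros_like(r)]))
        expected = taylor_couette_velocity(r, 0.4, 1.0, 1.0)
        assert np.max(np.abs(u[:, 1] - expected) / np.abs(expected)) < 0.005
        bf = traction_force(sol, body)
        T = bf.torque_per_depth_N / (1e-12 * UNIT_DOMAIN.mu_pa_s)
        T_exact = taylor_couette_inner_torque(0.4, 1.0, 1.0, 0.0, 1.0)
        assert abs(T - T_exact) / abs(T_exact) < 0.01

    def test_linearity_in_speed_and_viscosity(self):
        """Drag scales exactly with prescribed speed (same factorization)
        and with dynamic viscosity (unit conversion)."""
        body1 = disk(0, (0.1, 0.0), 0.3, v=(1.0, 0.0))
        nodes = discretize(UNIT_DOMAIN, [body1], 0.0625, CFG)
        system = StokesSystem(nodes, UNIT_DOMAIN, CFG)
        f1 = traction_force(system.solve([body1]),
                            body1).force_per_depth_N_per_m
        body2 = disk(0, (0.1, 0.0), 0.3, v=(2.0, 0.0))
        f2 = traction_force(system.solve([body2]),
                            body2).force_per_depth_N_per_m
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-8)
        thick = FluidDomain(drop_radius_um=1.0, nu_m2_s=3.0, rho_kg_m3=1.0)
        nodes3 = discretize(thick, [body1], 0.0625, CFG)
        f3 = traction_force(
            solve_stokes(nodes3, thick, [body1], CFG), body1
        ).force_per_depth_N_per_m
        np.testing.assert_allclose(f3, 3 * f1, rtol=1e-8)

    def test_mirror_symmetric_pair_opposite_forces(self):
        """Mirror-image disks with opposite velocities feel equal and
        opposite forces."""
        bodies = [disk(0, (-0.4, 0.0), 0.2, v=(1.0, 0.0)),
                  disk(1, (0.4, 0.0), 0.2, v=(-1.0, 0.0))]
        nodes = discretize(UNIT_DOMAIN, bodies, 0.0625, CFG)
        sol = solve_stokes(nodes, UNIT_DOMAIN, bodies, CFG)
        f0 = traction_force(sol, bodies[0]).force_per_depth_N_per_m
        f1 = traction_force(sol, bodies[1]).force_per_depth_N_per_m
        assert np.linalg.norm(f0 + f1) / np.linalg.norm(f0) < 1e-6

    def test_wall_effect_increases_drag(self):
        """Drag on a disk at fixed speed grows as the drop shrinks."""
        drags = []
        for R in (2.0, 1.4, 1.0):
            domain = FluidDomain(drop_radius_um=R, nu_m2_s=1.0,
                                 rho_kg_m3=1.0)
            body = disk(0, (0.0, 0.0), 0.3, v=(1.0, 0.0))
            nodes = discretize(domain, [body], R / 16, CFG)
            f = traction_force(solve_stokes(nodes, domain, [body], CFG),
                               body).force_per_depth_N_per_m
            drags.append(np.linalg.norm(f))
        assert drags[0] < drags[1] < drags[2]

    def test_native_discrete_divergence_vanishes(self):
        """The scheme's velocity reconstructions are solenoidal by
        construction: their divergence is machine zero everywhere."""
        body = disk(0, (0.1, 0.0), 0.3, v=(1.0, 0.0))
        nodes = discretize(UNIT_DOMAIN, [body], 0.0625, CFG)
        sol = solve_stokes(nodes, UNIT_DOMAIN, [body], CFG)
        diag = sol.divergence_diagnostics()
        assert diag["native_divergence_linf"] < 1e-8

    def test_free_body_rejected_in_resistance_mode(self):
        body = RigidBody(body_id=0, shape="disk", position=(0.1, 0.0),
                         radius_um=0.3, velocity_um_s=None)
        nodes = discretize(UNIT_DOMAIN, [body], 0.1, CFG)
        with pytest.raises(ArgumentError):
            solve_stokes(nodes, UNIT_DOMAIN, [body], CFG, mode="resistance")

    def test_mobility_quiescent_body_stays_at_rest(self):
        body = RigidBody(body_id=0, shape="disk", position=(0.1, 0.0),
                         radius_um=0.3, velocity_um_s=None)
        nodes = discretize(UNIT_DOMAIN, [body], 0.08, CFG)
        sol = solve_stokes(nodes, UNIT_DOMAIN, [body], CFG, mode="mobility")
        V = np.array(sol.resolved_velocities[0])
        assert np.linalg.norm(V) < 1e-10
        bf = traction_force(sol, sol.bodies[0])
        assert np.linalg.norm(bf.force_N) < 1e-10


class TestAdaptive:
    def test_estimator_decreases_and_refines(self):
        body = disk(0, (0.1, 0.0), 0.3, v=(1.0, 0.0))
        sol = adaptive_solve(UNIT_DOMAIN, [body], CFG, target_estimate=0.5,
                             initial_spacing=0.12, max_iterations=5)
        est = [h["estimate"] for h in sol.refinement_history]
        nn = [h["nodes"] for h in sol.refinement_history]
        assert est[-1] <= 0.5
        assert all(b <= a + 1e-12 for a, b in zip(est, est[1:]))
        assert nn[-1] >= nn[0]

    def test_halved_target_needs_more_nodes(self):
        body = disk(0, (0.1, 0.0), 0.3, v=(1.0, 0.0))
        loose = adaptive_solve(UNIT_DOMAIN, [body], CFG, target_estimate=1.0,
                               initial_spacing=0.12, max_iterations=6)
        tight = adaptive_solve(UNIT_DOMAIN, [body], CFG, target_estimate=0.5,
                               initial_spacing=0.12, max_iterations=6)
        assert tight.refinement_history[-1]["nodes"] > \
            loose.refinement_history[-1]["nodes"]

    def test_exhaustion_raises_with_last_estimate(self):
        body = disk(0, (0.1, 0.0), 0.3, v=(1.0, 0.0))
        with pytest.raises(AdaptiveError) as exc:
            adaptive_solve(UNIT_DOMAIN, [body], CFG, target_estimate=1e-12,
                           initial_spacing=0.15, max_iterations=2)
        assert np.isfinite(exc.value.last_estimate)


class TestConvergence:
    def test_low_order_configuration_still_converges(self):
        """Order-2 basis: observed order comfortably above the first-order
        consistency floor (quasi-symmetric stencils superconverge past the
        nominal estimate)."""
        res = convergence_order([0.2, 0.1, 0.05], GMLSConfig(order=2))
        assert res["order"] >= 1.5
        assert not res["non_monotone_warning"]

    def test_too_few_spacings_rejected(self):
        with pytest.raises(ArgumentError):
            convergence_order([0.2, 0.1])

    def test_manufactured_case_is_divergence_free(self):
        case = manufactured_case()
        pts = np.random.default_rng(0).uniform(-0.5, 0.5, (50, 2))
        eps = 1e-6
        dudx = (case["velocity"](pts + [eps, 0])[:, 0]
                - case["velocity"](pts - [eps, 0])[:, 0]) / (2 * eps)
        dvdy = (case["velocity"](pts + [0, eps])[:, 1]
                - case["velocity"](pts - [0, eps])[:, 1]) / (2 * eps)
        assert np.max(np.abs(dudx + dvdy)) < 1e-8


class TestScenes:
    def test_gliding_scene_defaults(self):
        domain, bodies = scene_gliding_bacteria()
        assert domain.drop_radius_um == 18.0
        assert len(bodies) == 8
        assert all(b.velocity_um_s == (2.0, 0.0) for b in bodies)
        assert all(b.shape == "capsule" for b in bodies)
        assert bodies[0].position == (0.0, 0.0)  # target cell centered

    def test_gliding_scene_single_cell(self):
        _, bodies = scene_gliding_bacteria(GlidingSceneConfig(n_cells=1))
        assert len(bodies) == 1

    def test_gliding_scene_unpackable_density_rejected(self):
        with pytest.raises(GeometryError):
            scene_gliding_bacteria(GlidingSceneConfig(pitch_um=0.5))

    def test_colony_scene_defaults(self):
        domain, bodies = scene_colonies()
        assert domain.drop_radius_um == 1000.0
        assert len(bodies) == 21
        speeds = [np.linalg.norm(b.velocity_um_s) for b in bodies]
        np.testing.assert_allclose(speeds, 0.031, rtol=1e-12)
        assert bodies[0].position == (0.0, 0.0)

    def test_colony_scene_single_colony_centered(self):
        _, bodies = scene_colonies(ColonySceneConfig(n_colonies=1))
        assert len(bodies) == 1
        assert bodies[0].position == (0.0, 0.0)

    def test_colony_scene_seed_reproducible_but_distinct(self):
        _, a1 = scene_colonies(ColonySceneConfig(seed=3))
        _, a2 = scene_colonies(ColonySceneConfig(seed=3))
        _, b = scene_colonies(ColonySceneConfig(seed=4))
        assert [x.position for x in a1] == [x.position for x in a2]
        assert [x.position for x in a1] != [x.position for x in b]
        sa = sorted(np.linalg.norm(x.velocity_um_s) for x in a1)
        sb = sorted(np.linalg.norm(x.velocity_um_s) for x in b)
        np.testing.assert_allclose(sa, sb)  # identical speed statistics

    def test_doubling_speed_doubles_center_cell_drag(self):
        """Stokes linearity at the scene level, with a small cell crowd."""
        cfg_scene = GlidingSceneConfig(n_cells=3, drop_radius_um=10.0)
        domain, bodies = scene_gliding_bacteria(cfg_scene)
        nodes = discretize(domain, bodies, 0.35, CFG)
        system = StokesSystem(nodes, domain, CFG)
        f1 = traction_force(system.solve(bodies),
                            bodies[0]).force_per_depth_N_per_m
        from dataclasses import replace
        fast = [replace(b, velocity_um_s=(4.0, 0.0)) for b in bodies]
        f2 = traction_force(system.solve(fast),
                            fast[0]).force_per_depth_N_per_m
        np.testing.assert_allclose(f2, 2 * f1, rtol=1e-8)
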