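"""Numerical oracles for the pulse-wave scheme and its boundary couplings."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cuffwave import (
    MMHG_TO_PA,
    ArterialTree,
    Probe,
    SolverSettings,
    VesselSegment,
    WallStiffness,
    WindkesselTerminal,
    run_to_steady_state,
)
from cuffwave.solver import FRICTION_COEF, build_mesh
from conftest import gaussian_inflow


def uniform_vessel(length=2.0, radius=0.005, stiffness=None, term=None,
                   split_at=None) -> ArterialTree:
    """A uniform (untapered) vessel, optionally split into two segments."""
    ws = stiffness or WallStiffness()
    term = term or WindkesselTerminal(R1=2e7, R2=1.2e8, C=1.1e-8,
                                      p_out=0.0)
    if split_at is None:
        segs = {"v": VesselSegment(id="v", name="v", length=length,
                                   r_prox=radius, r_dist=radius, stiffness=ws)}
        return ArterialTree(segments=segs, terminals={"v": term})
    a = VesselSegment(id="a", name="a", length=split_at, r_prox=radius,
                      r_dist=radius, stiffness=ws, children=("b",))
    b = VesselSegment(id="b", name="b", length=length - split_at,
                      r_prox=radius, r_dist=radius, stiffness=ws, parent="a")
    return ArterialTree(segments={"a": a, "b": b}, terminals={"b": term})


class TestEquilibrium:
    def test_quiescent_state_is_fixed_point(self):
        # uniform luminal pressure equal to the Windkessel back-pressure,
        # zero flow, zero inflow: nothing may move beyond round-off
        p_eq = 10.0 * MMHG_TO_PA
        tree = uniform_vessel(length=0.5, term=WindkesselTerminal(
            R1=2e7, R2=1.2e8, C=1.1e-8, p_out=p_eq))
        T, q = 0.5, np.zeros(8)
        s = SolverSettings(dx=5e-3, eps_ss=1e-7, max_cycles=3)
        res = run_to_steady_state(tree, None, s, [Probe("v", 0.25, "mid")],
                                  inflow=(T, q), init_pressure=p_eq,
                                  raise_on_failure=False)
        rec = res.records["mid"]
        assert np.allclose(rec.pressure, p_eq / MMHG_TO_PA, rtol=1e-10)
        assert np.allclose(rec.flow, 0.0, atol=1e-10)

    def test_deterministic_rerun_bit_identical(self, toy1, fast_settings):
        probes = [Probe("s0", 0.075, "mid")]
        a = run_to_steady_state(toy1.tree, toy1.heart, fast_settings, probes)
        b = run_to_steady_state(toy1.tree, toy1.heart, fast_settings, probes)
        assert np.array_equal(a.records["mid"].pressure, b.records["mid"].pressure)
        assert np.array_equal(a.records["mid"].flow, b.records["mid"].flow)
        assert a.volume_in == b.volume_in


class TestWaveSpeedOracle:
    def test_small_pulse_travels_at_tube_law_speed(self):
        # foot-to-foot timing over 1 m of uniform vessel vs the analytic
        # c(A0) = sqrt(beta/(2 rho)) of the law (pulse small, u << c)
        tree = uniform_vessel(length=2.0, radius=0.005)
        rho = tree.blood.density
        seg = tree.segments["v"]
        from cuffwave.wall import segment_area0, wave_speed

        a0 = segment_area0(seg, 1.0)
        c0 = wave_speed(a0, seg, 1.0, rho)
        T = 1.0
        _, q = gaussian_inflow(T, t0=0.10, width=0.01, peak=2e-6, n=1024)
        s = SolverSettings(dx=2.5e-3, eps_ss=1e-6, max_cycles=2,
                           n_samples=2048)
        res = run_to_steady_state(
            tree, None, s, [Probe("v", 0.5, "p1"), Probe("v", 1.5, "p2")],
            inflow=(T, q), init_pressure=0.0, raise_on_failure=False)

        def peak_time(rec):
            return rec.time[np.argmax(rec.pressure)]

        dt = peak_time(res.records["p2"]) - peak_time(res.records["p1"])
        c_measured = 1.0 / dt
        assert c_measured == pytest.approx(c0, rel=0.02)


class TestFrictionOracle:
    def test_steady_flow_matches_adopted_friction_law(self):
        # nearly rigid tube, constant inflow: dP/dx = -kf rho Q / A^2
        ws = WallStiffness(k1=0.0, k2=-1.0, k3=8.65e7)  # 1000x stiff
        q0 = 2e-6
        term = WindkesselTerminal(R1=2e7, R2=1.2e8, C=1.1e-8, p_out=0.0)
        tree = uniform_vessel(length=0.5, radius=0.002, stiffness=ws,
                              term=term)
        T = 0.5
        s = SolverSettings(dx=2.5e-3, eps_ss=1e-6, max_cycles=40)
        res = run_to_steady_state(
            tree, None, s, [Probe("v", 0.1, "p1"), Probe("v", 0.4, "p2")],
            inflow=(T, np.full(8, q0)), init_pressure=0.0)
        r1 = res.records["p1"]
        r2 = res.records["p2"]
        rho = tree.blood.density
        mu = tree.blood.viscosity
        area = np.mean(r1.area) * 1e-6
        dpdx_expected = FRICTION_COEF * math.pi * mu * q0 / area**2
        dpdx = (np.mean(r1.pressure) - np.mean(r2.pressure)) * MMHG_TO_PA / 0.3
        assert dpdx == pytest.approx(dpdx_expected, rel=0.01)


class TestJunctions:
    def test_symmetric_bifurcation_splits_flow_equally(self, toy3,
                                                       fast_settings):
        kids = toy3.tree.segments[toy3.tree.root_id].children
        probes = [Probe(kids[0], 0.075, "c1"), Probe(kids[1], 0.075, "c2")]
        res = run_to_steady_state(toy3.tree, toy3.heart, fast_settings, probes)
        q1 = res.records["c1"].flow
        q2 = res.records["c2"].flow
        assert np.allclose(q1, q2, rtol=1e-9, atol=1e-12)

    def test_flow_conservation_residual_below_1e10(self, toy3, fast_settings):
        probes = [Probe(toy3.tree.root_id, 0.075, "root")]
        res = run_to_steady_state(toy3.tree, toy3.heart, fast_settings, probes)
        assert res.max_junction_residual < 1e-10

    def test_serial_junction_of_identical_segments_reflects_nothing(self):
        # impedance-matched serial junction: reflected pulse < 1e-3 of incident
        whole = uniform_vessel(length=2.0)
        split = uniform_vessel(length=2.0, split_at=1.0)
        T = 1.0
        _, q = gaussian_inflow(T, t0=0.08, width=0.01, peak=2e-6, n=1024)
        s = SolverSettings(dx=2.5e-3, eps_ss=1e-6, max_cycles=2,
                           n_samples=2048)
        res_w = run_to_steady_state(
            whole, None, s, [Probe("v", 0.5, "p")], inflow=(T, q),
            init_pressure=0.0, raise_on_failure=False)
        res_s = run_to_steady_state(
            split, None, s, [Probe("a", 0.5, "p")], inflow=(T, q),
            init_pressure=0.0, raise_on_failure=False)
        pw = res_w.records["p"].pressure
        ps = res_s.records["p"].pressure
        incident = pw.max() - pw[0]
        # any junction reflection shows up as a deviation from the unsplit run
        assert np.max(np.abs(ps - pw)) < 1e-3 * incident


class TestWindkessel:
    def test_capacitor_discharge_matches_exponential(self):
        # the kernel advances Pc by forward Euler: with zero inflow the
        # discrete solution must track exp(-t/(R2 C)) within 0.5% over 3 tau
        R2, C, p_out = 1.2e8, 1.1e-8, 0.0
        tau = R2 * C
        dt = tau / 5000.0
        n = int(3 * tau / dt)
        pc = 1.0e4
        t = 0.0
        for i in range(n):
            pc += dt * (0.0 - (pc - p_out) / R2) / C
            t += dt
        assert pc == pytest.approx(1.0e4 * math.exp(-t / tau), rel=5e-3)

    def test_dc_limit_input_impedance_is_r1_plus_r2(self):
        # constant inflow: steady inlet pressure = P_out + Q (R1 + R2 + R_tube)
        q0 = 2e-6
        p_out = 5.0 * MMHG_TO_PA
        term = WindkesselTerminal(R1=3e7, R2=2e8, C=5e-9, p_out=p_out)
        tree = uniform_vessel(length=0.3, radius=0.004, term=term)
        T = 0.5
        s = SolverSettings(dx=5e-3, eps_ss=1e-7, max_cycles=40)
        res = run_to_steady_state(
            tree, None, s, [Probe("v", 0.29, "end")], inflow=(T, np.full(8, q0)),
            init_pressure=p_out)
        p_end = np.mean(res.records["end"].pressure) * MMHG_TO_PA
        expected = p_out + q0 * (term.R1 + term.R2)
        assert p_end == pytest.approx(expected, rel=0.01)


class TestConservation:
    def test_volume_balance_on_toy_tree(self, toy3, coarse):
        probes = [Probe(toy3.tree.root_id, 0.075, "root")]
        res = run_to_steady_state(toy3.tree, toy3.heart, coarse, probes)
        assert res.volume_error < 0.005

    def test_no_nan_in_any_record(self, toy1, fast_settings):
        res = run_to_steady_state(toy1.tree, toy1.heart, fast_settings,
                                  [Probe("s0", 0.075, "mid")])
        rec = res.records["mid"]
        for ch in (rec.pressure, rec.flow, rec.area):
            assert np.all(np.isfinite(ch))

    def test_doubling_max_cycles_keeps_converged_cycle(self, toy1):
        probes = [Probe("s0", 0.075, "mid")]
        s1 = SolverSettings(dx=5e-3, eps_ss=1e-4, max_cycles=20)
        s2 = SolverSettings(dx=5e-3, eps_ss=1e-4, max_cycles=40)
        a = run_to_steady_state(toy1.tree, toy1.heart, s1, probes)
        b = run_to_steady_state(toy1.tree, toy1.heart, s2, probes)
        # same convergence criterion -> identical converged cycle
        assert np.array_equal(a.records["mid"].pressure,
                              b.records["mid"].pressure)


class TestMesh:
    def test_every_segment_has_at_least_four_cells(self, baseline, coarse):
        mesh = build_mesh(baseline.tree, coarse)
        assert int(mesh.seg_ncell.min()) >= 4
        assert len(mesh.order) == 71

    def test_probe_cell_lookup_clamps_to_segment(self, toy1, coarse):
        mesh = build_mesh(toy1.tree, coarse)
        first = mesh.cell_index(toy1.tree, "s0", -1.0)
        last = mesh.cell_index(toy1.tree, "s0", 99.0)
        assert first == int(mesh.seg_cstart[0])
        assert last == int(mesh.seg_cstart[0] + mesh.seg_ncell[0] - 1)
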