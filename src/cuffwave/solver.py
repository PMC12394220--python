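"""Time-domain solution of the 1-D mass/momentum equations on the tree.

Governing equations per segment (x distal, A area, u mean velocity,
Q = A u volumetric flow):

    dA/dt + d(A u)/dx = 0
    du/dt + d(u^2/2 + P/rho)/dx = -kf u/A,     kf = 22 pi mu / rho

with luminal pressure P = P_ext + PT(A; x) from the elastic tube law (the
x-dependence of P carries the taper, so both equations are in conservation
form).  The scheme is a finite-volume two-step Lax-Wendroff (Richtmyer):
half-step states at cell interfaces, then a conservative update of the cell
averages, with semi-implicit friction.  Mass is conserved to round-off by
construction.  Boundary interfaces are handled with Riemann invariants of
the tube law, W+/- = u +/- 4c (c the local wave speed), constant along
dx/dt = u +/- c.  Junctions impose a single luminal pressure and
conservation of flow, solved per step as a scalar root problem in the
junction pressure; terminals couple the outgoing invariant to a
three-element Windkessel; the root couples the incoming invariant to the
elastance heart (or to a prescribed periodic inflow, used by the
verification oracles).

Convergence to the periodic steady state is detected as a relative L2
distance between consecutive cycles of the root pressure waveform.  The hot
loop is compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .metrics import WaveformRecord
from .units import MMHG_TO_PA
from .vascular import ArterialTree, HeartParameters

FRICTION_COEF = 22.0  # flat-ish velocity profile; Poiseuille would be 8


class SolverError(RuntimeError):
    """Simulation failure (divergence, non-convergence, junction failure)."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the pulse-wave solver.

    dx: target spatial step (m); each segment uses the nearest step that
    divides its length (at least 4 cells).  cfl: Courant number.  eps_ss:
    relative L2 tolerance on the root-pressure waveform between consecutive
    cycles.  area_floor: floor on A as a fraction of the local reference
    area, bounding the wave speed in collapsed states.
    """

    dx: float = 2.5e-3
    cfl: float = 0.9
    eps_ss: float = 1e-4
    max_cycles: int = 60
    area_floor: float = 1e-6
    n_samples: int = 256

    def __post_init__(self) -> None:
        if not (0 < self.cfl < 1):
            raise ValueError("require 0 < CFL < 1")
        if self.eps_ss <= 0:
            raise ValueError("require eps_ss > 0")
        if self.max_cycles < 2:
            raise ValueError("require max_cycles >= 2")


#: acceptance-grade and desk-scale presets
FINE = SolverSettings(dx=2.5e-3, eps_ss=1e-4, max_cycles=60)
COARSE = SolverSettings(dx=5.0e-3, eps_ss=5e-4, max_cycles=40)

PRESETS = {"fine": FINE, "coarse": COARSE}


@dataclass
class Probe:
    """A recording site: segment id + distance from the proximal end (m)."""

    segment: str
    x: float
    label: str


@dataclass
class SimulationResult:
    """Converged-cycle waveforms plus convergence/conservation diagnostics."""

    records: dict[str, WaveformRecord]
    period: float
    cycles: int
    converged: bool
    residual_history: np.ndarray
    segment_mean_pressure: dict[str, float]  # Pa, luminal, at segment midpoints
    volume_in: float  # m^3 ejected into the root over the cycle
    volume_out: float  # m^3 leaving through all terminals over the cycle
    stroke_volume: float  # m^3
    # junction flow-conservation residual |Qp - sum Qc| over the converged
    # cycle, relative to max(|Qp|, sum|Qc|, 1e-3 c A) -- the hydraulic flow
    # scale keeps the measure meaningful at flow-reversal zero crossings
    max_junction_residual: float
    valve_flow_min: float = 0.0  # most negative aortic valve flow, m^3/s

    @property
    def volume_error(self) -> float:
        """Relative mass-conservation error over the converged cycle."""
        scale = max(abs(self.volume_in), abs(self.volume_out), 1e-30)
        return abs(self.volume_in - self.volume_out) / scale


# ---------------------------------------------------------------------------
# compiled kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lum_p(A, beta, a0, pext):
    return pext + beta * (math.sqrt(A / a0) - 1.0)


@njit(cache=True)
def _wspeed(A, beta, a0, rho):
    return math.sqrt(beta / (2.0 * rho) * math.sqrt(A / a0))


@njit(cache=True)
def _area_from_p(P, beta, a0, pext, floor):
    """Invert the elastic law; clamp at the area floor below buckling."""
    u = 1.0 + (P - pext) / beta
    if u < 0.0:
        u = 0.0
    A = a0 * u * u
    if A < floor * a0:
        A = floor * a0
    return A


@njit(cache=True)
def _solve_junction(Phat0, wplus, wminus1, wminus2, two_children,
                    beta_p, a0_p, pext_p, beta_1, a0_1, pext_1,
                    beta_2, a0_2, pext_2, rho, floor):
    """Find the junction luminal pressure equalizing flow.

    Returns (Phat, Ap, Qp, A1, Q1, A2, Q2, rel_residual).
    g(P) = Q_parent(P) - sum Q_child(P) is monotonically decreasing near the
    physiological branch; Newton with a bisection safeguard.
    """

    cp0 = _wspeed(_area_from_p(Phat0, beta_p, a0_p, pext_p, floor),
                  beta_p, a0_p, rho)
    q_scale = 1e-3 * cp0 * _area_from_p(Phat0, beta_p, a0_p, pext_p, floor)

    def _g(P):
        Ap = _area_from_p(P, beta_p, a0_p, pext_p, floor)
        cp = _wspeed(Ap, beta_p, a0_p, rho)
        Qp = (wplus - 4.0 * cp) * Ap
        A1 = _area_from_p(P, beta_1, a0_1, pext_1, floor)
        c1 = _wspeed(A1, beta_1, a0_1, rho)
        Q1 = (wminus1 + 4.0 * c1) * A1
        Q2 = 0.0
        A2 = 0.0
        if two_children:
            A2 = _area_from_p(P, beta_2, a0_2, pext_2, floor)
            c2 = _wspeed(A2, beta_2, a0_2, rho)
            Q2 = (wminus2 + 4.0 * c2) * A2
        return Qp - Q1 - Q2, Ap, Qp, A1, Q1, A2, Q2

    P = Phat0
    g, Ap, Qp, A1, Q1, A2, Q2 = _g(P)
    scale = max(abs(Qp), abs(Q1) + abs(Q2), q_scale)
    tol = 1e-13 * scale
    # Newton with the analytic derivative:
    # dQ/dP = (u -/+ c) dA/dP (parent/child), dA/dP = A/(rho c^2)
    for _ in range(100):
        if abs(g) < tol:
            return P, Ap, Qp, A1, Q1, A2, Q2, abs(g) / scale
        cp = _wspeed(Ap, beta_p, a0_p, rho)
        dg = (Qp / Ap - cp) * Ap / (rho * cp * cp)
        c1 = _wspeed(A1, beta_1, a0_1, rho)
        dg -= (Q1 / A1 + c1) * A1 / (rho * c1 * c1)
        if two_children:
            c2 = _wspeed(A2, beta_2, a0_2, rho)
            dg -= (Q2 / A2 + c2) * A2 / (rho * c2 * c2)
        if dg == 0.0:
            break
        Pn = P - g / dg
        if not math.isfinite(Pn):
            break
        # damp overly large steps
        if abs(Pn - P) > 2.0 * (abs(P) + 1e4):
            Pn = P + 2.0 * (abs(P) + 1e4) * (1.0 if Pn > P else -1.0)
        P = Pn
        g, Ap, Qp, A1, Q1, A2, Q2 = _g(P)
        scale = max(abs(Qp), abs(Q1) + abs(Q2), q_scale)
        tol = 1e-13 * scale
    # bisection fallback: expand a bracket around Phat0
    lo = Phat0 - 1e4
    hi = Phat0 + 1e4
    glo = _g(lo)[0]
    ghi = _g(hi)[0]
    for _ in range(60):
        if glo * ghi <= 0.0:
            break
        lo -= 2.0 * (Phat0 - lo)
        hi += 2.0 * (hi - Phat0)
        glo = _g(lo)[0]
        ghi = _g(hi)[0]
    if glo * ghi > 0.0:
        # no root: a boundary area sits at the floor (hydraulically
        # disconnected state); report the flow mismatch as-is
        return P, Ap, Qp, A1, Q1, A2, Q2, abs(g) / scale
    for _ in range(200):
        P = 0.5 * (lo + hi)
        g, Ap, Qp, A1, Q1, A2, Q2 = _g(P)
        scale = max(abs(Qp), abs(Q1) + abs(Q2), q_scale)
        if abs(g) < 1e-13 * scale or (hi - lo) < 1e-13 * (abs(P) + 1.0):
            break
        if g * glo > 0.0:
            lo = P
            glo = g
        else:
            hi = P
    return P, Ap, Qp, A1, Q1, A2, Q2, abs(g) / scale


@njit(cache=True)
def _solve_inlet(A0g, wminus, q_in, beta, a0, pext, rho, floor):
    """Root-inlet area from the incoming invariant and the prescribed flow.

    Solves (wminus + 4 c(A)) A = q_in by damped Newton from the previous A.
    """
    A = A0g
    for _ in range(100):
        c = _wspeed(A, beta, a0, rho)
        g = (wminus + 4.0 * c) * A - q_in
        # dg/dA = wminus + 4c + 4A dc/dA ; dc/dA = c/(4A)  =>  dg/dA = wminus + 5c
        dg = wminus + 5.0 * c
        if dg == 0.0:
            break
        An = A - g / dg
        if An < floor * a0:
            An = 0.5 * (A + floor * a0)
        if abs(An - A) < 1e-14 * a0 + 1e-12 * A:
            A = An
            break
        A = An
    return A


@njit(cache=True)
def _solve_terminal(Aprev, wplus, Pc, R1, beta, a0, pext, rho, floor):
    """Terminal area from the outgoing invariant and the Windkessel relation.

    Solves  P(A) - Pc - (wplus - 4 c(A)) A R1 = 0  (luminal P = pext + PT).
    """
    A = Aprev
    for _ in range(100):
        c = _wspeed(A, beta, a0, rho)
        u = wplus - 4.0 * c
        P = _lum_p(A, beta, a0, pext)
        g = P - Pc - u * A * R1
        # dP/dA = rho c^2 / A ; d(uA)/dA = wplus - 4c - c = wplus - 5c
        dP = rho * c * c / A
        dg = dP - (wplus - 5.0 * c) * R1
        if dg == 0.0:
            break
        An = A - g / dg
        if An < floor * a0:
            An = 0.5 * (A + floor * a0)
        if abs(An - A) < 1e-14 * a0 + 1e-12 * A:
            A = An
            break
        A = An
    return A


@njit(cache=True)
def _elastance_nb(t, T, Emin, Emax, tm):
    tau = t % T
    if tau < tm:
        return Emin + (Emax - Emin) * 0.5 * (1.0 - math.cos(2.0 * math.pi * tau / tm))
    return Emin


@njit(cache=True)
def _simulate(seg_cstart, seg_ncell, seg_fstart, seg_dx, seg_c1, seg_c2,
              seg_term,
              A0c, betac, pextc, A0f, betaf, pextf,
              tR1, tR2, tC, tPout,
              rho, kf,
              hp, inflow_mode, inflow_q,
              T, cfl, eps_ss, max_cycles, floor_fac, n_samples,
              probe_cell, mid_cell,
              A_init, u_init, Pc_init, V_init):
    nseg = seg_cstart.shape[0]
    ncells = A0c.shape[0]
    nfaces = A0f.shape[0]
    nprobe = probe_cell.shape[0]

    A = A_init.copy()
    u = u_init.copy()
    Pc = Pc_init.copy()
    P = np.empty(ncells)
    F1 = np.zeros(nfaces)  # mass flux A u at interfaces
    G = np.zeros(nfaces)  # momentum flux u^2/2 + P/rho at interfaces
    q_term = np.zeros(tR1.shape[0])  # previous terminal boundary flow

    # heart parameters
    hT = hp[0]; hEmin = hp[1]; hEmax = hp[2]; htm = hp[3]
    hV0 = hp[4]; hpla = hp[6]
    hRlv = hp[7]; hLlv = hp[8]; hRla = hp[9]; hLla = hp[10]; hVb = hp[11]
    V = V_init
    q_mv = 0.0
    q_av = 0.0
    retro = 0.0
    mitral_open = False
    aortic_open = False
    p_root = _lum_p(A[0], betac[0], A0c[0], pextc[0])

    probe_P = np.zeros((nprobe, n_samples))
    probe_Q = np.zeros((nprobe, n_samples))
    probe_A = np.zeros((nprobe, n_samples))
    root_prev = np.zeros(n_samples)
    root_cur = np.zeros(n_samples)
    resid_hist = np.full(max_cycles, np.nan)
    mean_p_acc = np.zeros(nseg)
    mean_p = np.zeros(nseg)

    status = 1  # 0 converged, 1 max cycles, 2 blow-up
    n_cycles = 0
    vol_in = 0.0
    vol_out = 0.0
    stroke = 0.0
    max_jres = 0.0
    qav_min = 0.0
    n_in = inflow_q.shape[0]

    dt_s = T / n_samples
    converged = False
    for cycle in range(max_cycles):
        t_cyc = 0.0
        sample = 0
        for ip in range(nprobe):
            j = probe_cell[ip]
            probe_P[ip, 0] = _lum_p(A[j], betac[j], A0c[j], pextc[j])
            probe_Q[ip, 0] = A[j] * u[j]
            probe_A[ip, 0] = A[j]
        root_cur[0] = p_root
        vol_in = 0.0
        vol_out = 0.0
        stroke = 0.0
        max_jres = 0.0
        qav_min = 0.0
        for i in range(nseg):
            mean_p_acc[i] = 0.0

        while sample < n_samples:
            t_target = (sample + 1) * dt_s
            while t_cyc < t_target - 1e-12:
                # --- CFL time step
                dt = 1e9
                for i in range(nseg):
                    s0 = seg_cstart[i]
                    n = seg_ncell[i]
                    dxl = seg_dx[i]
                    for j in range(s0, s0 + n):
                        c = _wspeed(A[j], betac[j], A0c[j], rho)
                        loc = dxl / (abs(u[j]) + c)
                        if loc < dt:
                            dt = loc
                dt *= cfl
                if dt > t_target - t_cyc:
                    dt = t_target - t_cyc
                t_new = t_cyc + dt

                # --- cell pressures
                for j in range(ncells):
                    P[j] = _lum_p(A[j], betac[j], A0c[j], pextc[j])

                # --- heart / inflow (explicit coupling via p_root)
                t_abs = cycle * T + t_cyc
                if inflow_mode == 0:
                    E = _elastance_nb(t_abs + dt, hT, hEmin, hEmax, htm)
                    p_lv = E * (V - hV0)
                    if (not mitral_open) and hpla > p_lv:
                        mitral_open = True
                        q_mv = 0.0
                    if mitral_open:
                        q_mv += dt * (hpla - p_lv - hRla * q_mv) / hLla
                        if q_mv < 0.0:
                            q_mv = 0.0
                            mitral_open = False
                    else:
                        q_mv = 0.0
                    if (not aortic_open) and p_lv > p_root:
                        aortic_open = True
                        q_av = 0.0
                        retro = 0.0
                    if aortic_open:
                        q_av += dt * (p_lv - p_root - hRlv * q_av) / hLlv
                        if q_av < 0.0:
                            retro += -q_av * dt
                            if retro >= hVb:
                                q_av = 0.0
                                aortic_open = False
                    else:
                        q_av = 0.0
                    V += dt * (q_mv - q_av)
                    q_in = q_av
                    if q_av < qav_min:
                        qav_min = q_av
                    if q_av > 0.0:
                        stroke += q_av * dt
                else:
                    tt = (t_abs + dt) % T
                    fidx = tt / T * n_in
                    i0 = int(fidx) % n_in
                    i1 = (i0 + 1) % n_in
                    w = fidx - int(fidx)
                    q_in = inflow_q[i0] * (1.0 - w) + inflow_q[i1] * w

                # --- interior interface fluxes (Richtmyer half step)
                for i in range(nseg):
                    s0 = seg_cstart[i]
                    n = seg_ncell[i]
                    f0 = seg_fstart[i]
                    dxl = seg_dx[i]
                    for k in range(1, n):
                        jl = s0 + k - 1
                        jr = s0 + k
                        fi = f0 + k
                        f1l = A[jl] * u[jl]
                        f1r = A[jr] * u[jr]
                        gl = 0.5 * u[jl] * u[jl] + P[jl] / rho
                        gr = 0.5 * u[jr] * u[jr] + P[jr] / rho
                        Ah = 0.5 * (A[jl] + A[jr]) - 0.5 * dt / dxl * (f1r - f1l)
                        if Ah < floor_fac * A0f[fi]:
                            Ah = floor_fac * A0f[fi]
                        fr = kf * 0.5 * (u[jl] / A[jl] + u[jr] / A[jr])
                        uh = (0.5 * (u[jl] + u[jr]) - 0.5 * dt / dxl * (gr - gl)) \
                            / (1.0 + 0.5 * dt * fr / 1.0)
                        Ph = _lum_p(Ah, betaf[fi], A0f[fi], pextf[fi])
                        F1[fi] = Ah * uh
                        G[fi] = 0.5 * uh * uh + Ph / rho

                # --- junction boundary fluxes
                for i in range(nseg):
                    c1 = seg_c1[i]
                    if c1 < 0:
                        continue
                    c2 = seg_c2[i]
                    e = seg_cstart[i] + seg_ncell[i] - 1  # last cell of parent
                    fe = seg_fstart[i] + seg_ncell[i]  # parent outlet interface
                    cp = _wspeed(A[e], betac[e], A0c[e], rho)
                    wplus = u[e] + 4.0 * cp
                    j1 = seg_cstart[c1]
                    fc1 = seg_fstart[c1]
                    cc1 = _wspeed(A[j1], betac[j1], A0c[j1], rho)
                    wm1 = u[j1] - 4.0 * cc1
                    two = c2 >= 0
                    if two:
                        j2 = seg_cstart[c2]
                        fc2 = seg_fstart[c2]
                        cc2 = _wspeed(A[j2], betac[j2], A0c[j2], rho)
                        wm2 = u[j2] - 4.0 * cc2
                        b2 = betaf[fc2]; a02 = A0f[fc2]; px2 = pextf[fc2]
                    else:
                        j2 = -1
                        fc2 = -1
                        wm2 = 0.0
                        b2 = 1.0; a02 = 1.0; px2 = 0.0
                    Phat0 = P[e]
                    (Ph, Ap, Qp, A1, Q1, A2, Q2, jres) = _solve_junction(
                        Phat0, wplus, wm1, wm2, two,
                        betaf[fe], A0f[fe], pextf[fe],
                        betaf[fc1], A0f[fc1], pextf[fc1],
                        b2, a02, px2, rho, floor_fac)
                    floored = (Ap <= 1.01 * floor_fac * A0f[fe]
                               or A1 <= 1.01 * floor_fac * A0f[fc1])
                    if two and not floored:
                        floored = A2 <= 1.01 * floor_fac * A0f[fc2]
                    if jres > max_jres and not floored:
                        max_jres = jres
                    F1[fe] = Qp
                    G[fe] = 0.5 * (Qp / Ap) ** 2 + Ph / rho
                    F1[fc1] = Q1
                    G[fc1] = 0.5 * (Q1 / A1) ** 2 + Ph / rho
                    if two:
                        F1[fc2] = Q2
                        G[fc2] = 0.5 * (Q2 / A2) ** 2 + Ph / rho

                # --- terminal boundary fluxes
                for i in range(nseg):
                    ti = seg_term[i]
                    if ti < 0:
                        continue
                    e = seg_cstart[i] + seg_ncell[i] - 1
                    fe = seg_fstart[i] + seg_ncell[i]
                    Pc[ti] += dt * (q_term[ti] - (Pc[ti] - tPout[ti]) / tR2[ti]) \
                        / tC[ti]
                    cp = _wspeed(A[e], betac[e], A0c[e], rho)
                    wplus = u[e] + 4.0 * cp
                    An = _solve_terminal(A[e], wplus, Pc[ti], tR1[ti],
                                         betaf[fe], A0f[fe], pextf[fe],
                                         rho, floor_fac)
                    cn = _wspeed(An, betaf[fe], A0f[fe], rho)
                    un = wplus - 4.0 * cn
                    q_term[ti] = An * un
                    F1[fe] = An * un
                    G[fe] = 0.5 * un * un + _lum_p(An, betaf[fe], A0f[fe],
                                                   pextf[fe]) / rho
                    vol_out += An * un * dt

                # --- root inlet flux
                j1 = 0
                ci = _wspeed(A[j1], betac[j1], A0c[j1], rho)
                wminus = u[j1] - 4.0 * ci
                An = _solve_inlet(A[j1], wminus, q_in, betaf[0], A0f[0],
                                  pextf[0], rho, floor_fac)
                F1[0] = q_in
                un = q_in / An
                G[0] = 0.5 * un * un + _lum_p(An, betaf[0], A0f[0],
                                              pextf[0]) / rho
                p_root = _lum_p(An, betaf[0], A0f[0], pextf[0])
                vol_in += q_in * dt

                # --- conservative update of cell averages
                for i in range(nseg):
                    s0 = seg_cstart[i]
                    n = seg_ncell[i]
                    f0 = seg_fstart[i]
                    dxl = seg_dx[i]
                    for k in range(n):
                        j = s0 + k
                        An = A[j] - dt / dxl * (F1[f0 + k + 1] - F1[f0 + k])
                        if An < floor_fac * A0c[j]:
                            An = floor_fac * A0c[j]
                        un = (u[j] - dt / dxl * (G[f0 + k + 1] - G[f0 + k])) \
                            / (1.0 + dt * kf / An)
                        A[j] = An
                        u[j] = un

                # --- mean-pressure accumulators
                for i in range(nseg):
                    jm = mid_cell[i]
                    mean_p_acc[i] += _lum_p(A[jm], betac[jm], A0c[jm],
                                            pextc[jm]) * dt

                t_cyc = t_new

            if sample + 1 < n_samples:
                sidx = sample + 1
                for ip in range(nprobe):
                    j = probe_cell[ip]
                    probe_P[ip, sidx] = _lum_p(A[j], betac[j], A0c[j], pextc[j])
                    probe_Q[ip, sidx] = A[j] * u[j]
                    probe_A[ip, sidx] = A[j]
                root_cur[sidx] = p_root
            sample += 1

        n_cycles = cycle + 1
        ok = True
        for j in range(ncells):
            if not (math.isfinite(A[j]) and math.isfinite(u[j])):
                ok = False
                break
        if not ok:
            status = 2
            break
        if cycle > 0:
            num = 0.0
            den = 0.0
            for s in range(n_samples):
                diff = root_cur[s] - root_prev[s]
                num += diff * diff
                den += root_cur[s] * root_cur[s]
            resid = math.sqrt(num / max(den, 1e-30))
            resid_hist[cycle] = resid
            if resid < eps_ss:
                status = 0
                converged = True
        for s in range(n_samples):
            root_prev[s] = root_cur[s]
        for i in range(nseg):
            mean_p[i] = mean_p_acc[i] / T
        if converged:
            break

    return (probe_P, probe_Q, probe_A, resid_hist, n_cycles, status,
            mean_p, vol_in, vol_out, stroke, max_jres, qav_min, A, u, Pc, V)


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

@dataclass
class _Mesh:
    """Flattened finite-volume representation of a tree for the kernel."""

    order: list[str]
    seg_cstart: np.ndarray
    seg_ncell: np.ndarray
    seg_fstart: np.ndarray
    seg_dx: np.ndarray
    seg_c1: np.ndarray
    seg_c2: np.ndarray
    seg_term: np.ndarray
    A0c: np.ndarray
    betac: np.ndarray
    pextc: np.ndarray
    A0f: np.ndarray
    betaf: np.ndarray
    pextf: np.ndarray
    tR1: np.ndarray
    tR2: np.ndarray
    tC: np.ndarray
    tPout: np.ndarray
    term_order: list[str]
    mid_cell: np.ndarray

    def cell_index(self, tree: ArterialTree, segment: str, x: float) -> int:
        """Global index of the cell whose center is nearest to x."""
        i = self.order.index(segment)
        seg = tree.segments[segment]
        n = int(self.seg_ncell[i])
        frac = min(max(x / seg.length, 0.0), 1.0)
        k = min(int(frac * n), n - 1)
        return int(self.seg_cstart[i]) + k


def build_mesh(tree: ArterialTree, settings: SolverSettings) -> _Mesh:
    """Discretize the tree into the kernel's flat arrays (BFS order, root first)."""

    from .wall import segment_area0, segment_beta

    order: list[str] = []
    queue = [tree.root_id]
    while queue:
        sid = queue.pop(0)
        order.append(sid)
        queue.extend(tree.segments[sid].children)
    idx = {sid: i for i, sid in enumerate(order)}

    nseg = len(order)
    seg_cstart = np.zeros(nseg, dtype=np.int64)
    seg_ncell = np.zeros(nseg, dtype=np.int64)
    seg_fstart = np.zeros(nseg, dtype=np.int64)
    seg_dx = np.zeros(nseg)
    seg_c1 = np.full(nseg, -1, dtype=np.int64)
    seg_c2 = np.full(nseg, -1, dtype=np.int64)
    seg_term = np.full(nseg, -1, dtype=np.int64)
    cstart = 0
    fstart = 0
    for i, sid in enumerate(order):
        seg = tree.segments[sid]
        ncell = max(4, int(round(seg.length / settings.dx)))
        seg_cstart[i] = cstart
        seg_ncell[i] = ncell
        seg_fstart[i] = fstart
        seg_dx[i] = seg.length / ncell
        cstart += ncell
        fstart += ncell + 1
        kids = seg.children
        if kids:
            seg_c1[i] = idx[kids[0]]
            if len(kids) > 1:
                seg_c2[i] = idx[kids[1]]
    ncells = cstart
    nfaces = fstart

    A0c = np.zeros(ncells)
    betac = np.zeros(ncells)
    pextc = np.zeros(ncells)
    A0f = np.zeros(nfaces)
    betaf = np.zeros(nfaces)
    pextf = np.zeros(nfaces)
    mid_cell = np.zeros(nseg, dtype=np.int64)
    for i, sid in enumerate(order):
        seg = tree.segments[sid]
        n = int(seg_ncell[i])
        dxl = seg_dx[i]
        for k in range(n):
            x = (k + 0.5) * dxl
            g = int(seg_cstart[i]) + k
            A0c[g] = segment_area0(seg, x)
            betac[g] = segment_beta(seg, x)
            pextc[g] = seg.p_ext
        for k in range(n + 1):
            x = k * dxl
            g = int(seg_fstart[i]) + k
            A0f[g] = segment_area0(seg, x)
            betaf[g] = segment_beta(seg, x)
            pextf[g] = seg.p_ext
        mid_cell[i] = int(seg_cstart[i]) + (n - 1) // 2

    term_order = [sid for sid in order if sid in tree.terminals]
    tR1 = np.zeros(len(term_order))
    tR2 = np.zeros(len(term_order))
    tC = np.zeros(len(term_order))
    tPout = np.zeros(len(term_order))
    for k, sid in enumerate(term_order):
        t = tree.scaled_terminal(sid)
        tR1[k] = t.R1
        tR2[k] = t.R2
        tC[k] = t.C
        tPout[k] = t.p_out
    for i, sid in enumerate(order):
        if sid in tree.terminals:
            seg_term[i] = term_order.index(sid)

    return _Mesh(order, seg_cstart, seg_ncell, seg_fstart, seg_dx,
                 seg_c1, seg_c2, seg_term,
                 A0c, betac, pextc, A0f, betaf, pextf,
                 tR1, tR2, tC, tPout, term_order, mid_cell)


def _heart_param_array(h: HeartParameters) -> np.ndarray:
    return np.array([h.T, h.Emin, h.Emax, h.tm, h.V0, h.Vlv, h.pla,
                     h.Rlv, h.Llv, h.Rla, h.Lla, h.Vb, 0.0])


def run_to_steady_state(
    tree: ArterialTree,
    heart: HeartParameters | None,
    settings: SolverSettings,
    probes: list[Probe],
    inflow: tuple[float, np.ndarray] | None = None,
    init_pressure: float = 80.0 * MMHG_TO_PA,
    raise_on_failure: bool = True,
) -> SimulationResult:
    """Run until the periodic steady state and return the converged cycle.

    Either ``heart`` (elastance inflow) or ``inflow`` = (period, q samples
    over one period) must be given.  The tree is initialized at a uniform
    luminal pressure ``init_pressure`` with zero flow; Windkessel capacitors
    start at the same pressure.
    """

    if (heart is None) == (inflow is None):
        raise ValueError("give exactly one of heart or inflow")
    mesh = build_mesh(tree, settings)

    if heart is not None:
        T = heart.T
        hp = _heart_param_array(heart)
        inflow_mode = 0
        inflow_q = np.zeros(2)
        V_init = heart.Vlv
    else:
        T, inflow_q = inflow
        inflow_q = np.asarray(inflow_q, dtype=float)
        hp = _heart_param_array(HeartParameters())
        inflow_mode = 1
        V_init = hp[5]

    u0 = 1.0 + (init_pressure - mesh.pextc) / mesh.betac
    u0 = np.maximum(u0, 0.0)
    A_init = mesh.A0c * u0 * u0
    A_init = np.maximum(A_init, settings.area_floor * mesh.A0c)
    u_init = np.zeros_like(A_init)
    Pc_init = np.full(len(mesh.term_order), init_pressure, dtype=float)

    probe_cell = np.array(
        [mesh.cell_index(tree, p.segment, p.x) for p in probes], dtype=np.int64
    )
    rho = tree.blood.density
    kf = FRICTION_COEF * math.pi * tree.blood.viscosity / rho

    (probe_P, probe_Q, probe_A, resid_hist, n_cycles, status, mean_p,
     vol_in, vol_out, stroke, max_jres, qav_min, _A, _u, _Pc, _V) = _simulate(
        mesh.seg_cstart, mesh.seg_ncell, mesh.seg_fstart, mesh.seg_dx,
        mesh.seg_c1, mesh.seg_c2, mesh.seg_term,
        mesh.A0c, mesh.betac, mesh.pextc, mesh.A0f, mesh.betaf, mesh.pextf,
        mesh.tR1, mesh.tR2, mesh.tC, mesh.tPout,
        rho, kf, hp, inflow_mode, inflow_q,
        T, settings.cfl, settings.eps_ss, settings.max_cycles,
        settings.area_floor, settings.n_samples,
        probe_cell, mesh.mid_cell, A_init, u_init, Pc_init, V_init)

    if status == 2:
        raise SolverError("simulation diverged (non-finite state)")
    if status == 1 and raise_on_failure:
        raise SolverError(
            f"no steady state within {settings.max_cycles} cycles; "
            f"residual history: {resid_hist[~np.isnan(resid_hist)][-5:]}"
        )

    t = np.arange(settings.n_samples) * (T / settings.n_samples)
    records = {
        p.label: WaveformRecord(
            probe=p.label, time=t.copy(), pressure=probe_P[k] / MMHG_TO_PA,
            flow=probe_Q[k] * 1e6, area=probe_A[k] * 1e6,
        )
        for k, p in enumerate(probes)
    }
    seg_mean = {sid: mean_p[i] for i, sid in enumerate(mesh.order)}
    return SimulationResult(
        records=records, period=T, cycles=int(n_cycles),
        converged=(status == 0), residual_history=resid_hist,
        segment_mean_pressure=seg_mean, volume_in=vol_in, volume_out=vol_out,
        stroke_volume=stroke, max_junction_residual=max_jres,
        valve_flow_min=qav_min,
    )
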