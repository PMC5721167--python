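"""Quasi-1D compliant pulse-wave solver on a branched network.

Cross-sectionally averaged mass and momentum balances,

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A + B)/∂x = f_fric + S_geom,   B = β A^{3/2} / (3ρ),

are closed by the moving-boundary tube law p = p_ext + β(√A − √A0) with
β = 2√A0 / C_A (see :mod:`pulsead.wall`), giving the wave speed
c(A) = √(β √A / 2ρ) and Riemann invariants W₁,₂ = u ± 4c.  The friction
source assumes a Poiseuille profile, f = −8π μ(γ̇_w) Q / (ρ A), with the
Carreau–Yasuda apparent viscosity evaluated at the wall shear rate; the
momentum-flux coefficient is 1 (flat profile), adequate at the high
Womersley number (~23) of the aorta.

Discretization: explicit two-step (Richtmyer) Lax–Wendroff on (A, Q) per
segment, characteristic-based coupling at boundaries and junctions
(static-pressure continuity + mass conservation, scalar Newton per
junction), and backward-Euler Windkessel outlets.  The solver sub-steps
internally to satisfy the CFL condition and reports results on the
requested output grid (default 1 ms).

A dissection is a true-lumen segment in the main path plus a false-lumen
segment fed only through a quasi-steady entry-tear orifice,
Q = sign(ΔP)·Cd·A_tear·√(2|ΔP|/ρ), with a closed distal end.  The rigid
flag freezes A ≡ A0, which turns the network into an exact
inertance–resistance lumped system; it is then solved with the implicit
0D machinery (an explicit hyperbolic scheme has no rigid limit) and the
false lumen carries identically zero flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import NetworkGeometry, TearOrifice, lumped_equivalent
from .rheology import RheologyParams, cy_viscosity, wall_shear
from .units import MMHG_TO_PA
from .waveform import Waveform, from_samples
from .windkessel import FlowSource, WK3State, solve_lumped, wk3_coefficients

ML_S_TO_M3_S = 1e-6

#: Linearized-core half-width of the tear orifice law (Pa).  Below this
#: transmural pressure the √|ΔP| law is replaced by its secant so the
#: explicit tear coupling stays stable through ΔP sign changes.
TEAR_EPS_PA = 50.0


def tear_flow(deltaP: float, tear: TearOrifice, rho: float = 1056.0) -> float:
    """Quasi-steady orifice flow (m³/s), odd in the transmural pressure ΔP (Pa)."""
    return math.copysign(
        tear.Cd * tear.A_tear * math.sqrt(2.0 * abs(deltaP) / rho), deltaP
    )


def _tear_flow_regularized(deltaP: float, tear: TearOrifice, rho: float) -> float:
    if abs(deltaP) >= TEAR_EPS_PA:
        return tear_flow(deltaP, tear, rho)
    return tear.Cd * tear.A_tear * math.sqrt(2.0 / rho) * deltaP / math.sqrt(TEAR_EPS_PA)


# ---------------------------------------------------------------------------
# Result container


@dataclass
class SimResult:
    """Per-node time series of the last (periodic) cycle, SI units."""

    time: np.ndarray                     # s, output grid over one period
    T: float
    dt: float
    P: dict[str, np.ndarray]             # segment -> (n_t, n_x) Pa
    Q: dict[str, np.ndarray]             # m³/s
    A: dict[str, np.ndarray]             # m²
    tau_w: dict[str, np.ndarray]         # Pa
    cycles_run: int
    converged: bool
    residual: float
    rigid: bool
    volume_error: float                  # cycle volume imbalance / stroke volume

    def _field(self, name: str) -> dict[str, np.ndarray]:
        return {"P": self.P, "Q": self.Q, "A": self.A, "tau_w": self.tau_w}[name]

    def waveform(self, field_name: str, segment: str, node: int | None = None,
                 s: float | None = None) -> Waveform:
        """Extract one node's time series as a Waveform.

        ``node`` is a grid index (negative allowed); alternatively ``s`` in
        [0, 1] picks the node nearest that axial fraction.
        """
        arr = self._field(field_name)[segment]
        if s is not None:
            node = int(round(s * (arr.shape[1] - 1)))
        if node is None:
            raise ValueError("give either node or s")
        units = {"P": "Pa", "Q": "m^3/s", "A": "m^2", "tau_w": "Pa"}[field_name]
        return from_samples(arr[:, node], self.T, units=units)

    def inlet_pressure(self, segment: str = "ASC") -> Waveform:
        return self.waveform("P", segment, node=0)

    def outlet_flow(self, segment: str) -> Waveform:
        return self.waveform("Q", segment, node=-1)


# ---------------------------------------------------------------------------
# Runtime segment state


class _Seg:
    __slots__ = ("name", "A", "Q", "A0", "beta", "p_ext", "dx", "n",
                 "dbeta", "dA0", "sqrtA0", "rho")

    def __init__(self, seg, rho: float):
        self.name = seg.name
        self.n = seg.n_nodes
        self.dx = seg.dx
        self.rho = rho
        self.A0 = seg.A0.copy()
        if np.any(seg.C_A <= 0):
            raise ValueError(
                f"{seg.name}: compliant solver needs C_A > 0 everywhere "
                "(use rigid=True for a rigid run)"
            )
        self.beta = 2.0 * np.sqrt(self.A0) / seg.C_A  # Pa/m
        self.p_ext = float(np.mean(seg.p_ext)) if np.ndim(seg.p_ext) else float(seg.p_ext)
        self.sqrtA0 = np.sqrt(self.A0)
        self.dbeta = np.gradient(self.beta, self.dx)
        self.dA0 = np.gradient(self.A0, self.dx)
        self.A = self.A0.copy()
        self.Q = np.zeros(self.n)

    # tube law -------------------------------------------------------------
    def pressure(self, A=None) -> np.ndarray:
        A = self.A if A is None else A
        return self.p_ext + self.beta * (np.sqrt(A) - self.sqrtA0)

    def p_at(self, i: int, A: float) -> float:
        return self.p_ext + self.beta[i] * (math.sqrt(A) - self.sqrtA0[i])

    def area_at(self, i: int, p: float) -> float:
        s = (p - self.p_ext) / self.beta[i] + self.sqrtA0[i]
        if s <= 0:
            raise FloatingPointError(f"wall collapse in {self.name} at node {i}")
        return s * s

    def c_at(self, i: int, A: float) -> float:
        return math.sqrt(self.beta[i] * math.sqrt(A) / (2.0 * self.rho))

    def wavespeed(self, A=None) -> np.ndarray:
        A = self.A if A is None else A
        return np.sqrt(self.beta * np.sqrt(A) / (2.0 * self.rho))

    # characteristic feet (first order in dt) --------------------------------
    def w2_foot(self, dt: float) -> float:
        """Incoming invariant W₂ = u − 4c for the proximal boundary."""
        u0 = self.Q[0] / self.A[0]
        u1 = self.Q[1] / self.A[1]
        c0 = self.c_at(0, self.A[0])
        c1 = self.c_at(1, self.A[1])
        w0 = u0 - 4.0 * c0
        w1 = u1 - 4.0 * c1
        frac = min(max((c0 - u0) * dt / self.dx, 0.0), 1.0)
        return w0 + frac * (w1 - w0)

    def w1_foot(self, dt: float) -> float:
        """Incoming invariant W₁ = u + 4c for the distal boundary."""
        un = self.Q[-1] / self.A[-1]
        um = self.Q[-2] / self.A[-2]
        cn = self.c_at(self.n - 1, self.A[-1])
        cm = self.c_at(self.n - 2, self.A[-2])
        wn = un + 4.0 * cn
        wm = um + 4.0 * cm
        frac = min(max((un + cn) * dt / self.dx, 0.0), 1.0)
        return wn + frac * (wm - wn)


def _solve_area_for_flow(seg: _Seg, i: int, w_inc: float, Q_si: float, sign: float) -> float:
    """Solve u ± 4c = w_inc with u = Q/A for the boundary area.

    ``sign`` is −1 at a proximal end (u − 4c = W₂) and +1 at a distal end
    (u + 4c = W₁).
    """
    A = seg.A[i]
    for _ in range(60):
        c = seg.c_at(i, A)
        g = Q_si / A + sign * 4.0 * c - w_inc
        dg = -Q_si / A**2 + sign * c / A
        step = g / dg
        A_new = A - step
        if A_new <= 0:
            A_new = 0.5 * A
        if abs(A_new - A) < 1e-14 + 1e-10 * A:
            return A_new
        A = A_new
    return A


class _WK3Boundary:
    def __init__(self, seg: _Seg, params, p_init_mmhg: float):
        self.seg = seg
        self.params = params
        self.state = WK3State(P=p_init_mmhg, Q_prev=0.0, P_prev=p_init_mmhg)

    def apply(self, dt: float) -> None:
        seg = self.seg
        i = seg.n - 1
        w1 = seg.w1_foot(dt)
        a_c, b_c = wk3_coefficients(self.state, self.params, dt)
        # pressure continuity: p(A) = (a_c + b_c * Q_ml) * MMHG, Q_ml = u*A/1e-6
        A = seg.A[i]
        for _ in range(60):
            c = seg.c_at(i, A)
            u = w1 - 4.0 * c
            q_ml = u * A / ML_S_TO_M3_S
            g = seg.p_at(i, A) - (a_c + b_c * q_ml) * MMHG_TO_PA
            dg = seg.beta[i] / (2.0 * math.sqrt(A)) - MMHG_TO_PA * b_c * (w1 - 5.0 * c) / ML_S_TO_M3_S
            A_new = A - g / dg
            if A_new <= 0:
                A_new = 0.5 * A
            if abs(A_new - A) < 1e-14 + 1e-10 * A:
                A = A_new
                break
            A = A_new
        c = seg.c_at(i, A)
        u = w1 - 4.0 * c
        q_ml = u * A / ML_S_TO_M3_S
        p_mmhg = a_c + b_c * q_ml
        self.state.P_prev = self.state.P
        self.state.Q_prev = q_ml
        self.state.P = p_mmhg
        seg.A[i] = A
        seg.Q[i] = u * A


class _Junction:
    """Static-pressure-continuity junction with optional tear sink."""

    def __init__(self, ends: list[tuple[_Seg, str]], p_init: float):
        self.ends = ends
        self.p = p_init          # junction pressure state (Pa)
        self.tear: TearOrifice | None = None
        self.fl: _Seg | None = None
        self.rho = ends[0][0].rho
        self.q_tear = 0.0

    def apply(self, dt: float) -> None:
        feet = []
        for seg, side in self.ends:
            if side == "dist":
                feet.append(seg.w1_foot(dt))
            else:
                feet.append(seg.w2_foot(dt))
        # explicit tear flow from lagged pressures
        if self.tear is not None:
            p_fl = self.fl.p_at(0, self.fl.A[0])
            self.q_tear = _tear_flow_regularized(self.p - p_fl, self.tear, self.rho)
        p = self.p
        for _ in range(80):
            r = -self.q_tear if self.tear is not None else 0.0
            dr = 0.0
            for (seg, side), w in zip(self.ends, feet):
                i = seg.n - 1 if side == "dist" else 0
                A = seg.area_at(i, p)
                c = seg.c_at(i, A)
                dAdp = 2.0 * math.sqrt(A) / seg.beta[i]
                if side == "dist":
                    u = w - 4.0 * c
                    r += u * A
                    dr += (w - 5.0 * c) * dAdp
                else:
                    u = w + 4.0 * c
                    r -= u * A
                    dr -= (w + 5.0 * c) * dAdp
            if dr == 0.0:
                break
            p_new = p - r / dr
            if abs(p_new - p) < 1e-9 + 1e-12 * abs(p):
                p = p_new
                break
            p = p_new
        self.p = p
        for (seg, side), w in zip(self.ends, feet):
            i = seg.n - 1 if side == "dist" else 0
            A = seg.area_at(i, p)
            c = seg.c_at(i, A)
            u = (w - 4.0 * c) if side == "dist" else (w + 4.0 * c)
            seg.A[i] = A
            seg.Q[i] = u * A


# ---------------------------------------------------------------------------
# Compliant solver


def solve_pulsewave(
    geom: NetworkGeometry,
    sources: dict[str, Waveform],
    dt: float = 1e-3,
    n_cycles: int = 12,
    rigid: bool = False,
    rheo: RheologyParams = RheologyParams(),
    cfl: float = 0.9,
    tol: float = 0.01,
    p_init_mmhg: float = 80.0,
) -> SimResult:
    """Run the network to periodic steady state.

    ``sources`` maps boundary segment names (inflow/outflow kinds) to flow
    waveforms in ml/s (clinical convention of the input CSVs); results are
    SI.  ``dt`` is the output step; the scheme sub-steps internally to the
    CFL limit.  Convergence: cycle-to-cycle max relative pressure change
    below ``tol`` (default 1%).
    """
    geom.validate()
    for b in geom.boundaries:
        if b.kind in ("inflow", "outflow") and b.segment not in sources:
            raise ValueError(f"missing source waveform for boundary {b.segment}")
    if rigid:
        return _solve_rigid(geom, sources, dt, n_cycles, rheo, tol, p_init_mmhg)

    T = next(iter(sources.values())).T
    for wf in sources.values():
        if abs(wf.T - T) > 1e-9 * T:
            raise ValueError("all source waveforms must share one period")
    n_out = round(T / dt)
    if abs(n_out * dt - T) > 1e-9 * T:
        raise ValueError(f"dt={dt} does not divide the period T={T}")

    rho = rheo.rho
    p_init = p_init_mmhg * MMHG_TO_PA
    segs = {s.name: _Seg(s, rho) for s in geom.segments}
    for s in segs.values():
        s.A = np.array([s.area_at(i, p_init) for i in range(s.n)])

    junctions = []
    for j in geom.junctions:
        junctions.append(_Junction([(segs[n], side) for n, side in j.ends], p_init))
    if geom.dissection is not None:
        tj = junctions[geom.dissection.tear_junction]
        tj.tear = geom.dissection.tear
        tj.fl = segs[geom.dissection.fl]

    wk3_bcs, flow_bcs, closed_bcs = [], [], []
    for b in geom.boundaries:
        if b.kind == "wk3":
            wk3_bcs.append(_WK3Boundary(segs[b.segment], b.wk3, p_init_mmhg))
        elif b.kind in ("inflow", "outflow"):
            flow_bcs.append((segs[b.segment], b.side, b.kind, sources[b.segment]))
        elif b.kind == "closed":
            closed_bcs.append((segs[b.segment], b.side))
    fl_name = geom.dissection.fl if geom.dissection is not None else None

    names = list(segs)
    P_hist = {n: np.zeros((n_out, segs[n].n)) for n in names}
    Q_hist = {n: np.zeros((n_out, segs[n].n)) for n in names}
    A_hist = {n: np.zeros((n_out, segs[n].n)) for n in names}
    prev_P = None
    residual = math.inf
    converged = False
    cycles = 0
    vol_in = vol_out = 0.0
    v_start = v_end = 0.0

    def total_volume() -> float:
        return sum(float(np.trapezoid(s.A, dx=s.dx)) for s in segs.values())

    for cyc in range(n_cycles):
        vol_in = vol_out = 0.0
        v_start = total_volume()
        t_cycle = 0.0
        for step in range(n_out):
            # CFL-limited sub-stepping for this output interval
            max_speed = max(
                float(np.max(np.abs(s.Q / s.A) + s.wavespeed())) for s in segs.values()
            )
            min_dx = min(s.dx for s in segs.values())
            dt_cfl = cfl * min_dx / max_speed
            n_sub = max(1, int(math.ceil(dt / dt_cfl)))
            if n_sub > 1000:
                raise FloatingPointError(
                    f"CFL collapse: required sub-step {dt / n_sub:.2e}s; "
                    f"suggest output dt <= {dt_cfl:.2e}s"
                )
            h = dt / n_sub
            for _ in range(n_sub):
                _advance(segs.values(), h, rheo)
                for seg, side, kind, wf in flow_bcs:
                    q = wf(t_cycle) * ML_S_TO_M3_S
                    if side == "prox":  # prescribed inflow into the segment
                        A = _solve_area_for_flow(seg, 0, seg.w2_foot(h), q, -1.0)
                        seg.A[0] = A
                        seg.Q[0] = q
                    else:               # prescribed outflow at the distal end
                        A = _solve_area_for_flow(seg, seg.n - 1, seg.w1_foot(h), q, +1.0)
                        seg.A[-1] = A
                        seg.Q[-1] = q
                for seg, side in closed_bcs:
                    if side == "dist":
                        c = seg.w1_foot(h) / 4.0
                        seg.A[-1] = (2.0 * rho * c * c / seg.beta[-1]) ** 2
                        seg.Q[-1] = 0.0
                    else:
                        c = -seg.w2_foot(h) / 4.0
                        seg.A[0] = (2.0 * rho * c * c / seg.beta[0]) ** 2
                        seg.Q[0] = 0.0
                for j in junctions:
                    j.apply(h)
                if fl_name is not None:
                    # FL proximal end: prescribed tear inflow
                    fl = segs[fl_name]
                    tj = junctions[geom.dissection.tear_junction]
                    A = _solve_area_for_flow(fl, 0, fl.w2_foot(h), tj.q_tear, -1.0)
                    fl.A[0] = A
                    fl.Q[0] = tj.q_tear
                for bc in wk3_bcs:
                    bc.apply(h)
                t_cycle += h
            for name, s in segs.items():
                P_hist[name][step] = s.pressure()
                Q_hist[name][step] = s.Q
                A_hist[name][step] = s.A
        for seg, side, kind, wf in flow_bcs:
            node = 0 if side == "prox" else seg.n - 1
            v = float(np.sum(Q_hist[seg.name][:, node])) * dt
            if kind == "inflow":
                vol_in += v
            else:
                vol_out += v
        for bc in wk3_bcs:
            vol_out += float(np.sum(Q_hist[bc.seg.name][:, -1])) * dt
        v_end = total_volume()
        cycles = cyc + 1
        if prev_P is not None:
            scale = max(np.max(np.abs(P_hist[n])) for n in names)
            residual = max(
                float(np.max(np.abs(P_hist[n] - prev_P[n]))) for n in names
            ) / scale
            if residual < tol:
                converged = True
                break
        prev_P = {n: P_hist[n].copy() for n in names}

    inflow_total = sum(
        wf.cycle_integral() * ML_S_TO_M3_S
        for seg, side, kind, wf in flow_bcs
        if kind == "inflow"
    )
    stroke_volume = max(inflow_total, 1e-12)
    volume_error = abs(vol_in - vol_out - (v_end - v_start)) / stroke_volume

    tau = {
        n: wall_shear(Q_hist[n], A_hist[n], rheo) for n in names
    }

    def roll(d):
        return {k: np.roll(v, 1, axis=0) for k, v in d.items()}

    return SimResult(
        time=np.arange(n_out) * dt,
        T=T,
        dt=dt,
        P=roll(P_hist),
        Q=roll(Q_hist),
        A=roll(A_hist),
        tau_w=roll(tau),
        cycles_run=cycles,
        converged=converged,
        residual=residual,
        rigid=False,
        volume_error=volume_error,
    )


def _advance(segs, h: float, rheo: RheologyParams) -> None:
    """One Richtmyer Lax–Wendroff step on the interior nodes of each segment."""
    rho = rheo.rho
    for s in segs:
        A, Q = s.A, s.Q
        sqrtA = np.sqrt(A)
        B = s.beta * A * sqrtA / (3.0 * rho)
        F2 = Q * Q / A + B
        S2 = _momentum_source(s, A, Q, sqrtA, rheo)
        # half step at interfaces
        Ah = 0.5 * (A[:-1] + A[1:]) - 0.5 * h / s.dx * (Q[1:] - Q[:-1])
        Qh = (
            0.5 * (Q[:-1] + Q[1:])
            - 0.5 * h / s.dx * (F2[1:] - F2[:-1])
            + 0.25 * h * (S2[:-1] + S2[1:])
        )
        beta_h = 0.5 * (s.beta[:-1] + s.beta[1:])
        sqrtAh = np.sqrt(Ah)
        F2h = Qh * Qh / Ah + beta_h * Ah * sqrtAh / (3.0 * rho)
        S2h = _momentum_source(s, Ah, Qh, sqrtAh, rheo, half=True)
        # full step, interior nodes
        A[1:-1] -= h / s.dx * (Qh[1:] - Qh[:-1])
        Q[1:-1] -= h / s.dx * (F2h[1:] - F2h[:-1])
        Q[1:-1] += 0.5 * h * (S2h[1:] + S2h[:-1])
        if np.any(A[1:-1] <= 0):
            bad = int(np.flatnonzero(A[1:-1] <= 0)[0]) + 1
            raise FloatingPointError(f"wall collapse in {s.name} at node {bad}")


def _momentum_source(s, A, Q, sqrtA, rheo: RheologyParams, half: bool = False):
    rho = rheo.rho
    r3 = (A / np.pi) ** 1.5
    gamma = 4.0 * np.abs(Q) / (np.pi * r3)
    mu = cy_viscosity(gamma, rheo)
    fric = -8.0 * np.pi * mu * Q / (rho * A)
    if half:
        dbeta = 0.5 * (s.dbeta[:-1] + s.dbeta[1:])
        dA0 = 0.5 * (s.dA0[:-1] + s.dA0[1:])
        beta = 0.5 * (s.beta[:-1] + s.beta[1:])
        sqrtA0 = 0.5 * (s.sqrtA0[:-1] + s.sqrtA0[1:])
    else:
        dbeta, dA0, beta, sqrtA0 = s.dbeta, s.dA0, s.beta, s.sqrtA0
    geom_src = (
        dbeta * A * sqrtA / (3.0 * rho)
        - (A / rho) * dbeta * (sqrtA - sqrtA0)
        + beta * A / (2.0 * rho * sqrtA0) * dA0
    )
    return fric + geom_src


# ---------------------------------------------------------------------------
# Rigid mode (exact lumped limit)


def _solve_rigid(geom, sources, dt, n_cycles, rheo, tol, p_init_mmhg) -> SimResult:
    # Poiseuille resistance in the lumped blocks uses the high-shear
    # Carreau–Yasuda plateau region evaluated at a representative shear
    # rate; the Newtonian reference 4e-3 Pa·s is the conventional choice.
    net, bc_nodes = lumped_equivalent(geom, mu=4e-3, rho=rheo.rho, include_fl=True)
    for b in geom.boundaries:
        if b.kind == "inflow":
            net.sources.append(FlowSource(b.segment, bc_nodes[b.segment], sources[b.segment], +1))
        elif b.kind == "outflow":
            net.sources.append(FlowSource(b.segment, bc_nodes[b.segment], sources[b.segment], -1))
    res = solve_lumped(net, n_cycles=n_cycles, dt=dt, p_init=p_init_mmhg, tol=tol)

    T = net.sources[0].waveform.T
    n_out = round(T / dt)
    time = np.arange(n_out) * dt
    node_of = {}
    for i, j in enumerate(geom.junctions):
        for e in j.ends:
            node_of[e] = f"J{i}"
    if geom.dissection is not None:
        node_of[(geom.dissection.fl, "prox")] = f"J{geom.dissection.tear_junction}"
    for b in geom.boundaries:
        node_of.setdefault((b.segment, b.side), bc_nodes[b.segment])

    P, Q, A, tau = {}, {}, {}, {}
    for s in geom.segments:
        nn = s.n_nodes
        q = res.block_flows[s.name].v * ML_S_TO_M3_S  # uniform along a rigid segment
        p_up = res.pressures[node_of[(s.name, "prox")]].v * MMHG_TO_PA
        p_dn = res.pressures[node_of[(s.name, "dist")]].v * MMHG_TO_PA
        frac = np.linspace(0.0, 1.0, nn)
        P[s.name] = p_up[:, None] * (1 - frac) + p_dn[:, None] * frac
        Q[s.name] = np.repeat(q[:, None], nn, axis=1)
        A[s.name] = np.repeat(s.A0[None, :], n_out, axis=0)
        tau[s.name] = wall_shear(Q[s.name], A[s.name], rheo)

    return SimResult(
        time=time,
        T=T,
        dt=dt,
        P=P,
        Q=Q,
        A=A,
        tau_w=tau,
        cycles_run=res.cycles_run,
        converged=res.converged,
        residual=res.residual,
        rigid=True,
        volume_error=0.0,
    )
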