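"""Lumped (0D) vascular elements and network solver.

The three-element Windkessel (WK3) relates flow and mean pressure at a
coupled boundary through

    P + R2*C*dP/dt = (R1 + R2)*Q + R1*R2*C*dQ/dt

with proximal resistance ``R1`` (wave absorption), distal resistance ``R2``
and distal-vasculature compliance ``C``.  Vessel segments are lumped into
inertance–resistance (LR) blocks, ``L*dQ/dt = P_in - P_out - R*Q``.  Both
elements are integrated with first-order backward Euler; an assembled
network is solved fully implicitly (one sparse-free linear solve for the
junction pressures per step, with the backward-Euler element relations
folded in).

All quantities in this module are in clinical units: mmHg, ml/s, s,
mmHg·s/ml, ml/mmHg, mmHg·s²/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .waveform import Waveform, from_samples


@dataclass(frozen=True)
class WK3Params:
    """RCR triplet of a three-element Windkessel outlet."""

    R1: float  # proximal resistance, mmHg·s/ml
    R2: float  # distal resistance, mmHg·s/ml
    C: float   # compliance, ml/mmHg

    def __post_init__(self) -> None:
        if not (self.R1 >= 0 and self.R2 > 0 and self.C > 0):
            raise ValueError(f"invalid WK3 parameters: {self}")
        if not all(map(math.isfinite, (self.R1, self.R2, self.C))):
            raise ValueError("WK3 parameters must be finite")

    @property
    def R_tot(self) -> float:
        return self.R1 + self.R2


@dataclass(frozen=True)
class LRBlock:
    """Inertance–resistance building block of a vessel segment."""

    L: float  # inertance, mmHg·s²/ml
    R: float  # resistance, mmHg·s/ml

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("inertance L must be positive")
        if self.R < 0:
            raise ValueError("resistance R must be non-negative")


@dataclass
class WK3State:
    """Lagged boundary quantities carried between backward-Euler steps."""

    P: float = 0.0        # boundary pressure at current step, mmHg
    Q_prev: float = 0.0   # flow at previous step, ml/s
    P_prev: float = 0.0   # pressure at previous step, mmHg

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.P, self.Q_prev, self.P_prev))):
            raise ValueError("WK3 state must be finite")


def wk3_coefficients(state: WK3State, params: WK3Params, dt: float) -> tuple[float, float]:
    """Linearize the backward-Euler WK3 update as ``P_now = a + b*Q_now``.

    This is the exact implicit relation for the current step given the
    lagged state, used both by :func:`wk3_step` and by the network solver.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = params.R2 * params.C / dt
    k = params.R1 * params.R2 * params.C / dt
    denom = 1.0 + tau
    a = (tau * state.P - k * state.Q_prev) / denom
    b = (params.R_tot + k) / denom
    return a, b


def wk3_step(state: WK3State, Q_now: float, params: WK3Params, dt: float) -> float:
    """Advance a WK3 boundary one backward-Euler step; returns P_now (mmHg).

    Updates the lagged quantities in ``state`` in place.
    """
    if not math.isfinite(Q_now):
        raise ValueError("flow must be finite")
    a, b = wk3_coefficients(state, params, dt)
    P_now = a + b * Q_now
    state.P_prev = state.P
    state.Q_prev = Q_now
    state.P = P_now
    return P_now


def lr_step(Q: float, P_in: float, P_out: float, block: LRBlock, dt: float) -> float:
    """Advance ``L*dQ/dt = P_in - P_out - R*Q`` one backward-Euler step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return (Q + dt / block.L * (P_in - P_out)) / (1.0 + dt * block.R / block.L)


# ---------------------------------------------------------------------------
# Network assembly and solution


@dataclass
class NamedBlock:
    name: str
    block: LRBlock
    from_node: str
    to_node: str


@dataclass
class FlowSource:
    """Prescribed-flow boundary; positive flow is into the network node."""

    name: str
    node: str
    waveform: Waveform
    sign: int = 1  # +1 inflow, -1 withdrawal


@dataclass
class LumpedNetwork:
    """LR blocks + WK3 terminals + prescribed-flow sources on named nodes."""

    blocks: list[NamedBlock]
    terminals: dict[str, tuple[str, WK3Params]]  # outlet name -> (node, params)
    sources: list[FlowSource]

    def nodes(self) -> list[str]:
        names: list[str] = []
        for b in self.blocks:
            for n in (b.from_node, b.to_node):
                if n not in names:
                    names.append(n)
        for node, _ in self.terminals.values():
            if node not in names:
                names.append(node)
        for s in self.sources:
            if s.node not in names:
                names.append(s.node)
        return names

    def validate(self) -> None:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes()}
        for b in self.blocks:
            adj[b.from_node].add(b.to_node)
            adj[b.to_node].add(b.from_node)
        seen: set[str] = set()
        stack = [s.node for s in self.sources]
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj[n] - seen)
        unreachable = [t for t, (node, _) in self.terminals.items() if node not in seen]
        if unreachable:
            raise ValueError(f"terminals not reachable from any source: {unreachable}")


@dataclass
class LumpedResult:
    pressures: dict[str, Waveform]        # node -> P(t) mmHg, last cycle
    block_flows: dict[str, Waveform]      # block -> Q(t) ml/s
    terminal_flows: dict[str, Waveform]   # outlet -> Q(t) ml/s
    cycles_run: int
    converged: bool
    residual: float  # cycle-to-cycle max relative pressure change at exit


def solve_lumped(
    net: LumpedNetwork,
    n_cycles: int = 20,
    dt: float = 1e-3,
    p_init: float = 80.0,
    tol: float = 0.5e-2,
) -> LumpedResult:
    """Run the lumped network to periodic steady state (backward Euler).

    All sources must share one period ``T``; ``dt`` must divide ``T``.  The
    run stops once the cycle-to-cycle maximum relative change of every node
    pressure drops below ``tol`` (default 0.5%), or after ``n_cycles``
    cycles, in which case the partial result is flagged ``converged=False``.
    """
    net.validate()
    if not net.sources:
        raise ValueError("network needs at least one flow source")
    T = net.sources[0].waveform.T
    for s in net.sources:
        if abs(s.waveform.T - T) > 1e-9 * T:
            raise ValueError("all source waveforms must share one period")
    n_steps = round(T / dt)
    if abs(n_steps * dt - T) > 1e-9 * T:
        raise ValueError(f"dt={dt} does not divide the period T={T}")

    nodes = net.nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    nn = len(nodes)

    # Backward-Euler block relation Q_new = a_b + b_b*(P_from - P_to)
    b_coef = np.array(
        [(dt / b.block.L) / (1.0 + dt * b.block.R / b.block.L) for b in net.blocks]
    )
    q_keep = np.array([1.0 / (1.0 + dt * b.block.R / b.block.L) for b in net.blocks])

    term_names = list(net.terminals)
    term_nodes = [idx[net.terminals[t][0]] for t in term_names]
    term_params = [net.terminals[t][1] for t in term_names]
    term_states = [WK3State(P=p_init, Q_prev=0.0, P_prev=p_init) for _ in term_names]

    # Constant system matrix: node conservation in the junction pressures.
    M = np.zeros((nn, nn))
    for k, b in enumerate(net.blocks):
        i, j = idx[b.from_node], idx[b.to_node]
        # inflow at to-node, outflow at from-node
        M[j, j] += b_coef[k]
        M[j, i] -= b_coef[k]
        M[i, i] += b_coef[k]
        M[i, j] -= b_coef[k]
    beta_t = np.empty(len(term_names))
    for m, (ni, prm) in enumerate(zip(term_nodes, term_params)):
        _, beta = wk3_coefficients(WK3State(), prm, dt)
        beta_t[m] = beta
        M[ni, ni] += 1.0 / beta
    lu = scipy.linalg.lu_factor(M)

    src_nodes = [idx[s.node] for s in net.sources]
    src_vals = [s.sign * s.waveform(np.arange(1, n_steps + 1) * dt) for s in net.sources]

    Q = np.zeros(len(net.blocks))
    P_hist = np.zeros((n_steps, nn))
    Q_hist = np.zeros((n_steps, len(net.blocks)))
    Qt_hist = np.zeros((n_steps, len(term_names)))
    prev_P_hist = None
    residual = math.inf
    cycles = 0
    converged = False

    from_idx = np.array([idx[b.from_node] for b in net.blocks], dtype=int)
    to_idx = np.array([idx[b.to_node] for b in net.blocks], dtype=int)

    for cyc in range(n_cycles):
        for step in range(n_steps):
            rhs = np.zeros(nn)
            a_b = q_keep * Q
            np.add.at(rhs, to_idx, -a_b)
            np.add.at(rhs, from_idx, a_b)
            for sn, sv in zip(src_nodes, src_vals):
                rhs[sn] -= sv[step]
            alpha_t = np.empty(len(term_names))
            for m, (st, prm) in enumerate(zip(term_states, term_params)):
                a, _ = wk3_coefficients(st, prm, dt)
                alpha_t[m] = a
                rhs[term_nodes[m]] -= alpha_t[m] / beta_t[m]
            P = scipy.linalg.lu_solve(lu, -rhs)
            Q = a_b + b_coef * (P[from_idx] - P[to_idx])
            for m, st in enumerate(term_states):
                q_t = (P[term_nodes[m]] - alpha_t[m]) / beta_t[m]
                st.P_prev = st.P
                st.Q_prev = q_t
                st.P = P[term_nodes[m]]
                Qt_hist[step, m] = q_t
            P_hist[step] = P
            Q_hist[step] = Q
        cycles = cyc + 1
        if prev_P_hist is not None:
            scale = max(np.max(np.abs(P_hist)), 1e-12)
            residual = float(np.max(np.abs(P_hist - prev_P_hist)) / scale)
            if residual < tol:
                converged = True
                break
        prev_P_hist = P_hist.copy()

    def mk(vals: np.ndarray, units: str) -> Waveform:
        # histories are sampled at t = dt..T; roll so index 0 is t = 0 (= T)
        return from_samples(np.roll(vals, 1), T, units=units)

    return LumpedResult(
        pressures={n: mk(P_hist[:, idx[n]], "mmHg") for n in nodes},
        block_flows={b.name: mk(Q_hist[:, k], "ml/s") for k, b in enumerate(net.blocks)},
        terminal_flows={t: mk(Qt_hist[:, m], "ml/s") for m, t in enumerate(term_names)},
        cycles_run=cycles,
        converged=converged,
        residual=residual,
    )


def simulate_wk3(
    inflow: Waveform,
    params: WK3Params,
    dt: float = 1e-3,
    n_cycles: int = 30,
    p_init: float = 80.0,
    tol: float = 1e-4,
) -> Waveform:
    """Periodic steady-state pressure of a single WK3 driven by ``inflow``.

    Convenience wrapper around :func:`wk3_step`; used by tuning step 1.
    """
    n_steps = round(inflow.T / dt)
    if abs(n_steps * dt - inflow.T) > 1e-9 * inflow.T:
        raise ValueError(f"dt={dt} does not divide the period T={inflow.T}")
    q = np.asarray(inflow(np.arange(1, n_steps + 1) * dt))
    tau = params.R2 * params.C / dt
    k = params.R1 * params.R2 * params.C / dt
    denom = 1.0 + tau
    P = np.empty(n_steps)
    p_cur, q_prev = p_init, 0.0
    prev_cycle = None
    for _cyc in range(n_cycles):
        for i in range(n_steps):
            q_now = q[i]
            p_cur = (tau * p_cur - k * q_prev + (params.R_tot + k) * q_now) / denom
            q_prev = q_now
            P[i] = p_cur
        if prev_cycle is not None:
            if np.max(np.abs(P - prev_cycle)) / max(np.max(np.abs(P)), 1e-12) < tol:
                break
        prev_cycle = P.copy()
    return from_samples(np.roll(P, 1), inflow.T, units="mmHg")
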