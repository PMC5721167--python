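"""0D elements: WK3 and LR backward-Euler updates, lumped network solver."""

import math

import numpy as np
import pytest

from pulsead.waveform import from_samples
from pulsead.windkessel import (
    FlowSource,
    LRBlock,
    LumpedNetwork,
    NamedBlock,
    WK3Params,
    WK3State,
    lr_step,
    simulate_wk3,
    solve_lumped,
    wk3_step,
)

ABAO = WK3Params(R1=0.115, R2=3.608, C=0.157)  # abdominal-aorta outlet values


class TestWK3Step:
    def test_constant_flow_reaches_resistive_steady_state(self):
        state = WK3State(P=80.0, Q_prev=0.0, P_prev=80.0)
        for _ in range(100_000):
            p = wk3_step(state, 30.5, ABAO, 1e-3)
        assert p == pytest.approx((ABAO.R1 + ABAO.R2) * 30.5, rel=1e-6)  # 113.55 mmHg

    @pytest.mark.parametrize("dt", [4e-3, 2e-3, 1e-3, 5e-4])
    def test_zero_flow_decay_matches_exponential(self, dt):
        tau = ABAO.R2 * ABAO.C  # 0.5664 s
        state = WK3State(P=100.0, Q_prev=0.0, P_prev=100.0)
        n = round(tau / dt)
        for _ in range(n):
            p = wk3_step(state, 0.0, ABAO, dt)
        assert p == pytest.approx(100.0 * math.exp(-1.0), rel=0.05)

    def test_decay_error_is_first_order_in_dt(self):
        tau = ABAO.R2 * ABAO.C

        def err(dt):
            state = WK3State(P=100.0, Q_prev=0.0, P_prev=100.0)
            n = round(tau / dt)
            for _ in range(n):
                p = wk3_step(state, 0.0, ABAO, dt)
            return abs(p - 100.0 * math.exp(-n * dt / tau))

        ratio = err(2e-3) / err(1e-3)
        assert 1.7 < ratio < 2.3

    def test_zero_state_zero_flow_is_fixed_point(self):
        state = WK3State()
        for _ in range(100):
            assert wk3_step(state, 0.0, ABAO, 1e-3) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wk3_step(WK3State(), 1.0, ABAO, dt=0.0)
        with pytest.raises(ValueError):
            wk3_step(WK3State(), float("nan"), ABAO, 1e-3)
        with pytest.raises(ValueError):
            WK3Params(R1=-0.1, R2=1.0, C=1.0)


class TestLRStep:
    def test_ohmic_steady_state(self):
        block = LRBlock(L=0.01, R=2.0)
        q = 0.0
        for _ in range(10_000):
            q = lr_step(q, 10.0, 0.0, block, 1e-3)
        assert q == pytest.approx(5.0, rel=1e-9)

    def test_exponential_decay_time_constant(self):
        block = LRBlock(L=0.01, R=1.0)  # tau = 10 ms
        q = 8.0
        dt = 1e-4
        for _ in range(100):  # one time constant
            q = lr_step(q, 50.0, 50.0, block, dt)
        assert q == pytest.approx(8.0 * math.exp(-1.0), rel=0.01)

    def test_step_response_first_order_accurate(self):
        # backward Euler vs closed-form step response: worst error ~0.9·dt/tau
        # of the step amplitude (first order), i.e. < 1% at dt = 0.05·L/R
        block = LRBlock(L=0.01, R=1.0)
        tau = block.L / block.R

        def worst_err(dt):
            q, worst = 0.0, 0.0
            for n in range(1, 120):
                q = lr_step(q, 1.0, 0.0, block, dt)
                exact = (1.0 - math.exp(-n * dt / tau)) / block.R
                worst = max(worst, abs(q - exact))
            return worst

        assert worst_err(0.05 * tau) < 0.01  # of the 1 ml/s step amplitude
        ratio = worst_err(0.1 * tau) / worst_err(0.05 * tau)
        assert 1.7 < ratio < 2.3

    def test_nonpositive_inertance_rejected(self):
        with pytest.raises(ValueError):
            LRBlock(L=0.0, R=1.0)


def _single_terminal_net(wf):
    net = LumpedNetwork(
        blocks=[], terminals={"out": ("n0", ABAO)}, sources=[FlowSource("in", "n0", wf)]
    )
    return net


class TestSolveLumped:
    def test_single_terminal_matches_wk3_step_oracle(self, inflow):
        res = solve_lumped(_single_terminal_net(inflow), n_cycles=3, dt=1e-3, tol=-1.0)
        # replay the identical discretization with the scalar update
        n = round(inflow.T / 1e-3)
        state = WK3State(P=80.0, Q_prev=0.0, P_prev=80.0)
        trace = np.empty(n)
        for cyc in range(3):
            for i in range(n):
                trace[i] = wk3_step(state, float(inflow((i + 1) * 1e-3)), ABAO, 1e-3)
        np.testing.assert_allclose(res.pressures["n0"].v, np.roll(trace, 1), rtol=1e-10)

    def test_resistive_divider_limit(self):
        # negligible L and C: terminal flows split as 1/R_tot
        wf = from_samples(100 + 20 * np.sin(2 * np.pi * np.arange(800) / 800), 0.8)
        t1 = WK3Params(R1=0.1, R2=1.9, C=1e-7)
        t2 = WK3Params(R1=0.2, R2=3.8, C=1e-7)
        net = LumpedNetwork(
            blocks=[
                NamedBlock("b1", LRBlock(L=1e-9, R=0.0), "J", "n1"),
                NamedBlock("b2", LRBlock(L=1e-9, R=0.0), "J", "n2"),
            ],
            terminals={"t1": ("n1", t1), "t2": ("n2", t2)},
            sources=[FlowSource("in", "J", wf)],
        )
        res = solve_lumped(net, dt=1e-3, tol=1e-5)
        q1 = res.terminal_flows["t1"].cycle_mean()
        q2 = res.terminal_flows["t2"].cycle_mean()
        assert q1 / q2 == pytest.approx(t2.R_tot / t1.R_tot, rel=1e-3)
        assert q1 + q2 == pytest.approx(100.0, rel=1e-3)

    def test_periodic_state_conserves_charge(self, inflow):
        # cycle-mean inlet flow equals the sum of cycle-mean terminal flows
        import pulsead as pa
        from pulsead.network import lumped_equivalent

        geom = pa.idealized_dissected_aorta()
        net, bc = lumped_equivalent(geom, include_fl=False)
        net.sources.append(FlowSource("ASC", bc["ASC"], inflow, +1))
        car = pa.synth_branch_flows({"RCC": 12.7, "LCC": 8.9}, n_samples=inflow.n)
        for s in ("RCC", "LCC"):
            net.sources.append(FlowSource(s, bc[s], car[s], -1))
        res = solve_lumped(net, dt=1e-3, tol=1e-4, n_cycles=40)
        assert res.converged
        total_out = sum(w.cycle_mean() for w in res.terminal_flows.values())
        net_in = inflow.cycle_mean() - 12.7 - 8.9
        assert abs(total_out - net_in) / net_in < 1e-3

    def test_series_chain_matches_analytic_impedance(self):
        # sinusoidal forcing through L-R + WK3: amplitude and phase within 1%
        T = 0.8
        omega = 2 * np.pi / T
        n = 4000
        wf = from_samples(50 + 10 * np.sin(omega * np.arange(n) * (T / n)), T)
        block = LRBlock(L=5e-4, R=0.05)
        term = WK3Params(R1=0.1, R2=2.0, C=0.5)
        net = LumpedNetwork(
            blocks=[NamedBlock("b", block, "src", "n1")],
            terminals={"t": ("n1", term)},
            sources=[FlowSource("in", "src", wf)],
        )
        res = solve_lumped(net, dt=T / n, tol=1e-6, n_cycles=60)
        assert res.converged
        z_wk3 = term.R1 + term.R2 / (1 + 1j * omega * term.R2 * term.C)
        z = block.R + 1j * omega * block.L + z_wk3
        spec_p = np.fft.rfft(res.pressures["src"].v) / n
        spec_q = np.fft.rfft(wf.v) / n
        h = spec_p[1] / spec_q[1]
        assert abs(h) == pytest.approx(abs(z), rel=0.01)
        assert math.remainder(np.angle(h) - np.angle(z), 2 * math.pi) == pytest.approx(
            0.0, abs=0.01
        )

    def test_capacitor_charge_sums_to_zero_over_cycle(self, inflow):
        # |∮ C dP| per terminal is a tiny fraction of the stroke volume
        res = solve_lumped(_single_terminal_net(inflow), dt=1e-3, tol=1e-6, n_cycles=60)
        p = res.pressures["n0"].v
        charge = ABAO.C * float(np.sum(np.diff(np.append(p, p[0]))))
        assert abs(charge) < 1e-3 * 107.6

    def test_unreachable_terminal_rejected(self):
        wf = from_samples(np.ones(100), 1.0)
        net = LumpedNetwork(
            blocks=[], terminals={"t": ("far", ABAO)}, sources=[FlowSource("in", "n0", wf)]
        )
        with pytest.raises(ValueError, match="not reachable"):
            solve_lumped(net)


def test_simulate_wk3_matches_dense_ivp_oracle(inflow):
    from scipy.integrate import solve_ivp

    tr = simulate_wk3(inflow, ABAO, dt=2e-4, tol=1e-7, n_cycles=60)

    R1, R2, C = ABAO.R1, ABAO.R2, ABAO.C
    sol = solve_ivp(
        lambda t, y: [(inflow(t) - y[0] / R2) / C],
        [0, 40 * inflow.T],
        [80.0],
        max_step=2e-3,
        rtol=1e-9,
        atol=1e-11,
        dense_output=True,
    )
    tt = np.linspace(39 * inflow.T, 40 * inflow.T, 1500)
    p_oracle = R1 * np.asarray(inflow(tt)) + sol.sol(tt)[0]
    assert tr.cycle_max() == pytest.approx(p_oracle.max(), rel=2e-3)
    assert tr.cycle_min() == pytest.approx(p_oracle.min(), rel=2e-3)
    assert tr.cycle_mean() == pytest.approx(
        (R1 + R2) * inflow.cycle_mean(), rel=1e-3
    )
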