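"""Clinical post-processing indices of a pulse-wave simulation.

Foot-to-foot pulse-wave velocity, percentage cross-sectional area
variation, time-averaged wall shear stress (TAWSS) and oscillatory shear
index (OSI), true/false-lumen transmural pressure (TMP), and the systolic
stored volume of the compliant aorta.  All integrals use trapezoidal
quadrature on the periodic closure of the (last simulated) cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import Waveform


@dataclass
class IndexReport:
    PWV: float | None = None                       # m/s
    delta_area_peak_pct: dict[str, float] | None = None
    TAWSS: dict[str, float] | None = None          # Pa
    OSI: dict[str, float] | None = None
    TMP: Waveform | None = None                    # mmHg
    stored_volume_ml: float | None = None


def _upstroke_foot(wf: Waveform) -> float:
    """Foot time: the minimum immediately preceding the systolic upstroke.

    The upstroke is located as the maximal cyclic forward slope; from
    there the minimum is found walking backwards, and refined to
    sub-sample precision by a parabola through the three samples around
    it.  Ties break to the earliest time.
    """
    v = wf.v
    n = v.size
    slope = np.roll(v, -1) - v  # cyclic forward difference
    i_up = int(np.argmax(slope))
    # walk backwards (cyclically) to the preceding local minimum
    i = i_up
    for _ in range(n):
        j = (i - 1) % n
        if v[j] >= v[i]:
            break
        i = j
    # parabolic refinement around i
    ym = v[(i - 1) % n]
    y0 = v[i]
    yp = v[(i + 1) % n]
    denom = ym - 2.0 * y0 + yp
    offset = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return ((i + offset) * wf.dt) % wf.T


def foot_to_foot_pwv(P_a: Waveform, P_b: Waveform, distance: float) -> float:
    """Pulse-wave velocity (m/s) from the wave-foot transit time.

    ``P_a`` is the upstream and ``P_b`` the downstream pressure signal;
    ``distance`` (m) separates the two stations along the vessel.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if abs(P_a.T - P_b.T) > 1e-9 * P_a.T:
        raise ValueError("waveforms must share one period")
    t_a = _upstroke_foot(P_a)
    t_b = _upstroke_foot(P_b)
    delay = (t_b - t_a) % P_a.T
    if delay <= 0 or delay > 0.5 * P_a.T:
        raise ValueError(
            f"unresolvable foot delay ({delay:.4g}s); use a finer time step "
            "or a longer separation"
        )
    return distance / delay


def delta_area_pct(A: Waveform) -> Waveform:
    """ΔA% = 100·(A − A_min)/A_min with A_min the lowest area of the cycle."""
    if np.any(A.v <= 0):
        raise ValueError("area samples must be positive")
    a_min = A.cycle_min()
    return Waveform(A.t, 100.0 * (A.v - a_min) / a_min, A.T, units="%")


def tawss_osi(tau_w: Waveform) -> tuple[float, float]:
    """Time-averaged wall shear stress (Pa) and oscillatory shear index.

    TAWSS = (1/T)∫|τ|dt; OSI = ½(1 − |∫τ dt| / ∫|τ|dt) ∈ [0, 0.5], zero
    for unidirectional shear.  An identically zero signal has TAWSS = 0
    and OSI defined as 0.
    """
    abs_int = Waveform(tau_w.t, np.abs(tau_w.v), tau_w.T).cycle_integral()
    tawss = abs_int / tau_w.T
    if abs_int == 0.0:
        return 0.0, 0.0
    osi = 0.5 * (1.0 - abs(tau_w.cycle_integral()) / abs_int)
    return tawss, float(min(max(osi, 0.0), 0.5))


def transmural_pressure(P_TL: Waveform, P_FL: Waveform) -> Waveform:
    """TMP = P_TL − P_FL across the intimal flap (units follow the inputs)."""
    if abs(P_TL.T - P_FL.T) > 1e-9 * P_TL.T or P_TL.n != P_FL.n:
        raise ValueError("TL/FL pressures must share one time base")
    return Waveform(P_TL.t, P_TL.v - P_FL.v, P_TL.T, units=P_TL.units)


def systole_window(Q_in: Waveform, threshold: float = 0.01) -> tuple[float, float]:
    """Default systole window: inflow upstroke to return-to-baseline.

    Bounds are the first/last crossings of ``threshold``·peak around the
    inflow maximum.
    """
    peak = Q_in.cycle_max()
    i_peak = int(np.argmax(Q_in.v))
    above = Q_in.v > threshold * peak
    n = Q_in.n
    i0 = i_peak
    for _ in range(n):
        j = (i0 - 1) % n
        if not above[j]:
            break
        i0 = j
    i1 = i_peak
    for _ in range(n):
        j = (i1 + 1) % n
        if not above[j]:
            break
        i1 = j
    return (i0 * Q_in.dt) % Q_in.T, ((i1 + 1) * Q_in.dt) % Q_in.T


def stored_volume(
    Q_in: Waveform,
    Q_outs: list[Waveform],
    window: tuple[float, float] | None = None,
) -> float:
    """Blood volume accumulated during systole: ∫(Q_in − ΣQ_out) dt.

    Flows in ml/s give a result in ml.  The window defaults to the inflow
    systole (upstroke to return-to-baseline); an explicit window must lie
    within one period.
    """
    if window is None:
        t0, t1 = systole_window(Q_in)
    else:
        t0, t1 = window
        if not (0 <= t0 < Q_in.T) or not (0 < t1 <= Q_in.T + 1e-12):
            raise ValueError("window must lie within one period")
    if t1 <= t0:
        t1 += Q_in.T
    tt = np.linspace(t0, t1, max(200, Q_in.n))
    net = np.asarray(Q_in(tt), dtype=float)
    for q in Q_outs:
        net = net - np.asarray(q(tt))
    return float(np.trapezoid(net, tt))
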