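"""Moving-boundary wall-compliance law, embodied axisymmetrically.

Each wall node displaces along the outward normal in linear proportion to
the local transmural pressure,

    δ = (p − p_ext) / K,

where the nodal stiffness K (N/m³) follows from the area compliance C_A of
a circular cross-section: differentiating A = π r² with dr/dp = 1/K gives
C_A = dA/dp = 2 π r0 / K, hence

    K = 2 √(π A0) / C_A.

In the axisymmetric embodiment the outward normal is the radial direction
and the nodal law becomes the tube law A(p) = π (r0 + δ)², equivalently
p = p_ext + β (√A − √A0) with β = K/√π = 2 √A0 / C_A — the classic
quasi-1D pressure–area closure, whose linearization at p_ext is exactly
C_A and whose wave speed at the reference state is c0 = √(A0/(ρ C_A))
(the Bramwell–Hill speed 1/√(ρ D) with distensibility D = C_A/A0).
"""

from __future__ import annotations

import numpy as np

RIGID_K = np.inf  # sentinel stiffness for C_A = 0 (rigid node)


def nodal_stiffness(C_A, A0):
    """Wall stiffness K (N/m³) from area compliance C_A (m²/Pa), area A0 (m²).

    C_A = 0 signals a rigid node and returns the ``inf`` sentinel honoured
    by the displacement and tube laws.
    """
    C_A = np.asarray(C_A, dtype=float)
    A0 = np.asarray(A0, dtype=float)
    if np.any(A0 <= 0):
        raise ValueError("reference area A0 must be positive")
    if np.any(C_A < 0):
        raise ValueError("area compliance C_A must be non-negative")
    with np.errstate(divide="ignore"):
        K = np.where(C_A > 0, 2.0 * np.sqrt(np.pi * A0) / np.where(C_A > 0, C_A, 1.0), RIGID_K)
    return float(K) if K.ndim == 0 else K


def wall_displacement(p, p_ext, K):
    """Radial wall displacement δ (m) at pressure p given stiffness K."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("stiffness K must be positive")
    d = (np.asarray(p, dtype=float) - p_ext) / K
    return float(d) if d.ndim == 0 else d


def area_from_pressure(A0, K, p, p_ext):
    """Lumen area A (m²) at pressure p under the linear-displacement law.

    A = π (r0 + δ)² with r0 = √(A0/π); aborts on wall collapse r0 + δ ≤ 0.
    """
    A0 = np.asarray(A0, dtype=float)
    r0 = np.sqrt(A0 / np.pi)
    r = r0 + wall_displacement(p, p_ext, K)
    if np.any(r <= 0):
        where = np.flatnonzero(np.atleast_1d(r) <= 0)
        raise FloatingPointError(f"wall collapse (r <= 0) at node index {where[:5].tolist()}")
    A = np.pi * r**2
    return float(A) if A.ndim == 0 else A


def pressure_from_area(A, A0, K, p_ext):
    """Inverse tube law: p = p_ext + K (√(A/π) − √(A0/π))."""
    A = np.asarray(A, dtype=float)
    A0 = np.asarray(A0, dtype=float)
    p = p_ext + np.asarray(K, dtype=float) * (np.sqrt(A / np.pi) - np.sqrt(A0 / np.pi))
    # rigid sentinel: K = inf with A = A0 gives nan; pin to p_ext
    p = np.where(np.isinf(np.asarray(K, dtype=float)), p_ext, p)
    return float(p) if p.ndim == 0 else p
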