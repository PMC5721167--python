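"""Blood rheology: Carreau–Yasuda shear-thinning viscosity and wall shear.

Blood is modelled as incompressible (ρ = 1056 kg/m³) with a shear-thinning
apparent viscosity

    μ(γ̇) = μ∞ + (μ0 − μ∞) · [1 + (λ·γ̇)^a]^((n−1)/a)

bounded between the low-shear plateau μ0 and the high-shear plateau μ∞.
Default coefficients follow the Gijsen et al. aortic blood fit commonly used
in large-artery CFD; they are literature defaults, editable per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BLOOD_DENSITY: float = 1056.0  # kg/m³
NEWTONIAN_MU: float = 4e-3     # Pa·s, high-shear reference used for Reynolds estimates


@dataclass(frozen=True)
class RheologyParams:
    rho: float = BLOOD_DENSITY
    mu_0: float = 22e-3    # Pa·s, low-shear plateau
    mu_inf: float = 2.2e-3 # Pa·s, high-shear plateau
    lam: float = 0.110     # s, relaxation time
    a_cy: float = 0.644
    n_cy: float = 0.392

    def __post_init__(self) -> None:
        if not (self.mu_0 >= self.mu_inf > 0):
            raise ValueError("require mu_0 >= mu_inf > 0")
        if self.lam <= 0:
            raise ValueError("relaxation time must be positive")
        if self.rho <= 0:
            raise ValueError("density must be positive")


NEWTONIAN = RheologyParams(mu_0=NEWTONIAN_MU, mu_inf=NEWTONIAN_MU)


def cy_viscosity(gamma_dot, rheo: RheologyParams = RheologyParams()):
    """Carreau–Yasuda apparent viscosity (Pa·s) at shear rate γ̇ (1/s)."""
    g = np.asarray(gamma_dot, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = rheo.mu_inf + (rheo.mu_0 - rheo.mu_inf) * (
        1.0 + (rheo.lam * g) ** rheo.a_cy
    ) ** ((rheo.n_cy - 1.0) / rheo.a_cy)
    return float(mu) if np.isscalar(gamma_dot) else mu


def wall_shear(Q, A, rheo: RheologyParams = RheologyParams(), n_iter: int = 5):
    """Wall shear stress (Pa) of Poiseuille-profile flow Q (m³/s) in area A (m²).

    τ_w = 4 μ(γ̇_w) Q / (π r³) with γ̇_w = 4|Q|/(π r³); since the
    Carreau–Yasuda viscosity depends on γ̇_w only through |Q| and r, the
    Poiseuille wall shear rate is closed directly and the fixed-point loop
    is kept only as a guard for alternative profile closures.
    """
    Q = np.asarray(Q, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    r3 = (A / np.pi) ** 1.5
    gamma = 4.0 * np.abs(Q) / (np.pi * r3)
    mu = cy_viscosity(gamma, rheo)
    for _ in range(n_iter - 1):
        mu_new = cy_viscosity(gamma, rheo)
        if np.allclose(mu_new, mu, rtol=1e-12):
            break
        mu = mu_new
    tau = 4.0 * mu * Q / (np.pi * r3)
    return float(tau) if (np.isscalar(tau) or tau.ndim == 0) else tau
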