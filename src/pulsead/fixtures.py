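"""Synthetic inputs standing in for the patient's imaging data.

Real studies of this kind draw their inputs from PC-MRI flow mapping, cine
MRI area tracking and CT angiography.  None of those are available to a
desk-scale reconstruction, so this module generates physiologically shaped
stand-ins: an aortic inflow waveform with a prescribed stroke volume and
heart rate, carotid branch flows with exact cycle means, cine-like area
waveforms consistent with a chosen distensibility, and an idealized
dissected-aorta geometry whose topology mirrors the clinical case (arch
branches, visceral branches, and a true/false-lumen pair communicating
through a single 18.5 mm² entry tear).

Default dimensions are documented literature-typical adult values, not
patient measurements; the inlet diameter (32 mm) keeps the mean Reynolds
(~1400) and Womersley (~23) numbers of the study's flow regime under the
default blood properties and inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    BoundaryCondition,
    Dissection,
    Junction,
    NetworkGeometry,
    TearOrifice,
    VesselSegment1D,
)
from .rheology import BLOOD_DENSITY
from .units import MMHG_TO_PA
from .waveform import Waveform, from_samples
from .windkessel import WK3Params

#: Mean-flow tuning targets (ml/s) at the coupled outlets.
TARGET_MEAN_FLOWS: dict[str, float] = {
    "RSA": 9.8,
    "LSA": 9.8,
    "CT": 20.7,
    "SMA": 14.0,
    "RRA": 14.0,
    "LRA": 14.0,
    "AbAo": 30.5,
}

#: Mean flows (ml/s) at the prescribed-flow carotid boundaries.
CAROTID_MEAN_FLOWS: dict[str, float] = {"RCC": 12.7, "LCC": 8.9}

INLET_MEAN_FLOW: float = 134.5  # ml/s


@dataclass(frozen=True)
class InflowSpec:
    """Shape parameters of the synthetic aortic inflow."""

    SV: float = 107.6              # stroke volume, ml
    HR: float = 75.0               # heart rate, bpm
    systolic_fraction: float = 1.0 / 3.0
    reverse_fraction: float = 0.02 # fraction of SV returned as early-diastolic backflow
    n_samples: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic fraction must lie in (0, 1)")
        if self.SV <= 0:
            raise ValueError("stroke volume must be positive")
        if not (0 <= self.reverse_fraction < 0.5):
            raise ValueError("reverse fraction must lie in [0, 0.5)")
        if self.systolic_fraction + 0.08 >= 1.0:
            raise ValueError("no room for the backflow lobe after systole")

    @property
    def period(self) -> float:
        return 60.0 / self.HR


def synth_inflow(spec: InflowSpec = InflowSpec()) -> Waveform:
    """Half-sine systolic ejection + small backflow lobe + zero diastole.

    The cycle integral is renormalized to equal the stroke volume exactly
    (trapezoidal rule on the periodic closure).
    """
    T = spec.period
    Ts = spec.systolic_fraction * T
    Tr = 0.08 * T  # backflow lobe duration
    t = np.arange(spec.n_samples) * (T / spec.n_samples)
    v = np.zeros_like(t)
    sys_mask = t < Ts
    Qp = np.pi * spec.SV * (1.0 + spec.reverse_fraction) / (2.0 * Ts)
    v[sys_mask] = Qp * np.sin(np.pi * t[sys_mask] / Ts)
    if spec.reverse_fraction > 0:
        rev_mask = (t >= Ts) & (t < Ts + Tr)
        Qr = np.pi * spec.reverse_fraction * spec.SV / (2.0 * Tr)
        v[rev_mask] = -Qr * np.sin(np.pi * (t[rev_mask] - Ts) / Tr)
    wf = Waveform(t, v, T, units="ml/s")
    return wf.scaled(spec.SV / wf.cycle_integral())


def synth_branch_flows(
    means: dict[str, float],
    HR: float = 75.0,
    pulsatility: float = 0.35,
    n_samples: int = 800,
) -> dict[str, Waveform]:
    """Carotid-like branch waveforms with exact cycle means.

    Each branch is a scaled copy of the inflow envelope with damped
    pulsatility: Q_i(t) = mean_i * (1 + k*(s(t) - 1)), where s is the
    unit-mean inflow shape.  Linear in the requested mean.
    """
    if any(m < 0 for m in means.values()):
        raise ValueError("branch means must be non-negative")
    base = synth_inflow(InflowSpec(HR=HR, reverse_fraction=0.0, n_samples=n_samples))
    s = base.v / base.cycle_mean()
    out = {}
    for name, m in means.items():
        v = m * (1.0 + pulsatility * (s - 1.0))
        wf = Waveform(base.t, v, base.T, units="ml/s")
        if m > 0:
            wf = wf.scaled(m / wf.cycle_mean())
        out[name] = wf
    return out


def synth_area_waveform(
    P: Waveform,
    D: float,
    A0: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Waveform:
    """Cine-MRI-like lumen-area waveform from a pressure wave (Pa).

    A(t) = A0 * (1 + D*(P(t) - min P)) * (1 + ε(t)) with seeded
    multiplicative Gaussian noise of relative s.d. ``noise_sd``; the
    reference ``A0`` is the area at the pressure minimum.
    """
    if D < 0 or noise_sd < 0:
        raise ValueError("D and noise_sd must be non-negative")
    a = A0 * (1.0 + D * (P.v - P.cycle_min()))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + noise_sd * rng.standard_normal(a.shape))
    return Waveform(P.t, a, P.T, units="m^2")


# ---------------------------------------------------------------------------
# Idealized dissected-aorta geometry


@dataclass(frozen=True)
class SegmentSpec:
    length: float        # m
    diameter_mm: float
    region: str          # 'ascending' | 'descending' | 'abdominal' | 'branch'


#: Default segment table (documented literature-typical adult dimensions).
DEFAULT_SEGMENTS: dict[str, SegmentSpec] = {
    "ASC": SegmentSpec(0.12, 32.0, "ascending"),     # ascending aorta + arch
    "BCT": SegmentSpec(0.04, 12.5, "branch"),        # brachiocephalic trunk
    "RSA": SegmentSpec(0.05, 9.0, "branch"),
    "RCC": SegmentSpec(0.05, 7.0, "branch"),
    "LCC": SegmentSpec(0.06, 7.0, "branch"),
    "LSA": SegmentSpec(0.06, 9.5, "branch"),
    "DAO": SegmentSpec(0.04, 26.0, "descending"),    # descending aorta above the tear
    "TL": SegmentSpec(0.20, 14.0, "descending"),     # true lumen (narrowed)
    "FL": SegmentSpec(0.19, 20.0, "descending"),     # false lumen
    "CT": SegmentSpec(0.03, 8.0, "branch"),
    "SMA": SegmentSpec(0.03, 7.0, "branch"),
    "RRA": SegmentSpec(0.03, 6.0, "branch"),
    "LRA": SegmentSpec(0.03, 6.0, "branch"),
    "AbAo": SegmentSpec(0.10, 17.0, "abdominal"),    # abdominal aorta to iliacs
}

#: Aortic distensibility defaults (1/Pa) per region, emulating the measured
#: cross-sectional area variations (~11% ascending, ~17% abdominal over a
#: systolic–diastolic excursion of ~70 mmHg).
DEFAULT_DISTENSIBILITY: dict[str, float] = {
    "ascending": 1.18e-5,
    "descending": 1.30e-5,
    "abdominal": 1.66e-5,
}


@dataclass
class FixtureConfig:
    segments: dict[str, SegmentSpec] = field(default_factory=lambda: dict(DEFAULT_SEGMENTS))
    distensibility: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTENSIBILITY)
    )
    tear_area_mm2: float = 18.5
    tear_cd: float = 0.6
    dissected: bool = True
    p_ext_mmHg: float = 76.0
    nodes_per_segment: int | None = None  # None -> max(8, ceil(length/1 cm))
    pressure_targets: tuple[float, float] = (150.0, 80.0)  # (P_sys, P_dia) mmHg


def _pwv_diameter_law(d_mm: float) -> float:
    # local copy of the empirical PWV(d) law to avoid a circular import;
    # the public operation lives in pulsead.tuning
    return 13.3 / d_mm**0.3


def _default_wk3(name: str) -> WK3Params:
    """Placeholder outlet parameters before tuning (overwritten by the pipeline).

    Seeds R_tot from the zero-venous-reference estimate P̄/Q̄ with a
    ~113 mmHg mean arterial pressure and distributes a ~1 ml/mmHg total
    compliance by flow share.
    """
    q = TARGET_MEAN_FLOWS[name]
    r_tot = 113.0 / q
    c = 0.99 * q / sum(TARGET_MEAN_FLOWS.values())
    return WK3Params(R1=0.056 * r_tot, R2=0.944 * r_tot, C=c)


def idealized_dissected_aorta(cfg: FixtureConfig = FixtureConfig()) -> NetworkGeometry:
    """Build the idealized dissected-aorta network.

    Topology: inlet → ascending aorta/arch → {brachiocephalic trunk →
    (RSA, RCC), LCC, LSA, descending aorta} → tear junction → true lumen
    (with the false lumen fed only through the entry tear, distally closed)
    → {coeliac trunk, SMA, renal arteries, abdominal aorta}.  With
    ``dissected=False`` the false lumen and tear are omitted.
    """
    p_ext = cfg.p_ext_mmHg * MMHG_TO_PA
    rho = BLOOD_DENSITY

    def n_nodes(length: float) -> int:
        if cfg.nodes_per_segment is not None:
            return cfg.nodes_per_segment
        return max(8, int(np.ceil(length / 0.01)) + 1)

    segs: dict[str, VesselSegment1D] = {}
    for name, sp in cfg.segments.items():
        if name == "FL" and not cfg.dissected:
            continue
        A0 = np.pi * (sp.diameter_mm * 1e-3 / 2) ** 2
        if sp.region == "branch":
            pwv = _pwv_diameter_law(sp.diameter_mm)
            D = 1.0 / (rho * pwv**2)
        else:
            D = cfg.distensibility[sp.region]
        # Dissected region: distensibility refers to the combined TL+FL
        # area; the resulting combined compliance splits between the lumina
        # in proportion to their reference areas, which reduces to D*A0 each.
        C_A = D * A0
        segs[name] = VesselSegment1D(
            name=name, length=sp.length, n_nodes=n_nodes(sp.length), A0=A0, C_A=C_A, p_ext=p_ext
        )

    junctions = [
        Junction(ends=[("ASC", "dist"), ("BCT", "prox"), ("LCC", "prox"),
                       ("LSA", "prox"), ("DAO", "prox")]),
        Junction(ends=[("BCT", "dist"), ("RSA", "prox"), ("RCC", "prox")]),
        Junction(ends=[("TL", "dist"), ("CT", "prox"), ("SMA", "prox"),
                       ("RRA", "prox"), ("LRA", "prox"), ("AbAo", "prox")]),
    ]
    dissection = None
    if cfg.dissected:
        junctions.append(Junction(ends=[("DAO", "dist"), ("TL", "prox")]))
        dissection = Dissection(
            tl="TL",
            fl="FL",
            tear=TearOrifice(A_tear=cfg.tear_area_mm2 * 1e-6, Cd=cfg.tear_cd),
            tear_junction=len(junctions) - 1,
        )
    else:
        junctions.append(Junction(ends=[("DAO", "dist"), ("TL", "prox")]))

    boundaries = [
        BoundaryCondition(kind="inflow", segment="ASC", side="prox"),
        BoundaryCondition(kind="outflow", segment="RCC", side="dist"),
        BoundaryCondition(kind="outflow", segment="LCC", side="dist"),
    ]
    for name in TARGET_MEAN_FLOWS:
        boundaries.append(
            BoundaryCondition(kind="wk3", segment=name, side="dist", wk3=_default_wk3(name))
        )
    if cfg.dissected:
        boundaries.append(BoundaryCondition(kind="closed", segment="FL", side="dist"))

    geom = NetworkGeometry(
        segments=list(segs.values()),
        junctions=junctions,
        boundaries=boundaries,
        dissection=dissection,
    )
    geom.validate()
    return geom
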