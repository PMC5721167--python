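"""Run configuration, validation and the end-to-end pipeline driver.

``run_all`` binds the stages together: synthetic fixtures (or user files)
→ Windkessel tuning → compliant simulation → clinical indices, writing a
reproducible artifact directory (``report.json``, the result store,
``indices.json`` and an append-only ``run.log``).  A single seed governs
all stochastic fixture generation; the solvers themselves are
deterministic.
"""

from __future__ import annotations

import json
import logging
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fixtures import (
    CAROTID_MEAN_FLOWS,
    FixtureConfig,
    InflowSpec,
    TARGET_MEAN_FLOWS,
    idealized_dissected_aorta,
    synth_branch_flows,
    synth_inflow,
)
from .indices import (
    delta_area_pct,
    foot_to_foot_pwv,
    stored_volume,
    tawss_osi,
    transmural_pressure,
)
from .network import read_geometry_yaml
from .store import save_result
from .tuning import TuneOptions, TuningTargets, tune_pipeline
from .units import MMHG_TO_PA
from .waveform import read_waveform_csv

_KNOWN_KEYS = {
    "geometry", "inflow", "targets", "dt", "cycles", "rigid", "cfl",
    "seed", "out_dir", "verbosity", "r1_fraction", "compare_rigid",
    "result_format",
}


@dataclass
class RunConfig:
    geometry: str | None = None     # YAML path; None -> built-in fixture
    inflow: str | None = None       # CSV path; None -> synthetic inflow
    targets: str | None = None      # YAML path; None -> standard targets
    dt: float = 1e-3                # s
    cycles: int = 12
    rigid: bool = False
    cfl: float = 0.9
    seed: int = 0
    out_dir: str = "pulsead_out"
    verbosity: int = 1
    r1_fraction: float = 0.056
    compare_rigid: bool = False
    result_format: str = "h5"       # 'h5' | 'csv'
    applied_defaults: list[str] = field(default_factory=list)


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping; unknown keys are aggregated errors.

    Quantities entering the solvers are normalized (pressures to Pa via
    the single 133.322 conversion, times in s); applied defaults are
    recorded in the returned config.
    """
    errors = [f"unknown config key: {k!r}" for k in raw if k not in _KNOWN_KEYS]
    cfg = RunConfig()
    for k, v in raw.items():
        if k in _KNOWN_KEYS:
            setattr(cfg, k, v)
    if cfg.dt <= 0:
        errors.append(f"dt must be positive, got {cfg.dt}")
    if cfg.result_format not in ("h5", "csv"):
        errors.append(f"result_format must be h5 or csv, got {cfg.result_format!r}")
    for path_key in ("geometry", "inflow", "targets"):
        p = getattr(cfg, path_key)
        if p is not None and not Path(p).exists():
            errors.append(f"{path_key} file not found: {p}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    for k in _KNOWN_KEYS - set(raw):
        cfg.applied_defaults.append(f"{k} = {getattr(cfg, k)!r} (default)")
    if cfg.rigid and cfg.compare_rigid:
        logging.getLogger("pulsead").warning(
            "rigid run requested together with a rigid comparison; "
            "the comparison is redundant"
        )
    return cfg


def load_targets_yaml(path) -> TuningTargets:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return TuningTargets(
        P_sys=float(d["P_sys_mmHg"]),
        P_dia=float(d["P_dia_mmHg"]),
        mean_flows={k: float(v) for k, v in d["mean_flows_ml_s"].items()},
        r1_fraction=float(d.get("r1_fraction", 0.056)),
    )


def default_targets(r1_fraction: float = 0.056) -> TuningTargets:
    return TuningTargets(
        P_sys=150.0, P_dia=80.0, mean_flows=dict(TARGET_MEAN_FLOWS), r1_fraction=r1_fraction
    )


def _setup_log(out: Path, verbosity: int) -> logging.Logger:
    log = logging.getLogger("pulsead.run")
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fh = logging.FileHandler(out / "run.log", mode="a")  # append-only
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if verbosity > 0:
        sh = logging.StreamHandler(sys.stderr)
        sh.setLevel(logging.INFO if verbosity == 1 else logging.DEBUG)
        log.addHandler(sh)
    return log


def run_all(cfg: RunConfig) -> Path:
    """Execute fixtures → tune → simulate → indices; returns the out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _setup_log(out, cfg.verbosity)
    t0 = _time.perf_counter()
    log.info("pulsead %s | seed=%d | resolved config: %s", __version__, cfg.seed,
             {k: getattr(cfg, k) for k in sorted(_KNOWN_KEYS)})
    for d in cfg.applied_defaults:
        log.debug("default applied: %s", d)

    geom = (
        read_geometry_yaml(cfg.geometry)
        if cfg.geometry
        else idealized_dissected_aorta(FixtureConfig())
    )
    inflow = (
        read_waveform_csv(cfg.inflow)
        if cfg.inflow
        else synth_inflow(InflowSpec(seed=cfg.seed))
    )
    targets = (
        load_targets_yaml(cfg.targets)
        if cfg.targets
        else default_targets(cfg.r1_fraction)
    )
    HR = 60.0 / inflow.T
    outflows = synth_branch_flows(dict(CAROTID_MEAN_FLOWS), HR=HR, n_samples=inflow.n)

    try:
        report = tune_pipeline(
            geom,
            inflow,
            targets,
            TuneOptions(
                dt=cfg.dt,
                rigid_only=cfg.rigid,
                outflow_waveforms=outflows,
                n_cycles_1d=cfg.cycles,
            ),
        )
    except RuntimeError as exc:
        log.error("pipeline failed: %s", exc)
        raise
    report.save_json(out / "report.json")
    log.info("tuning report written; C_sys=%.3f C_aorta=%.3f ml/mmHg",
             report.C_sys, report.C_aorta)

    indices: dict = {}
    if not cfg.rigid and report.sim_result is not None:
        res = report.sim_result
        save_result(res, out / ("result.h5" if cfg.result_format == "h5" else "result_csv"))
        indices = compute_indices(geom, res, inflow, outflows)
        if cfg.compare_rigid and report.rigid_result is not None:
            indices["rigid_comparison"] = rigid_comparison(report.rigid_result, res)
    (out / "indices.json").write_text(json.dumps(indices, indent=2))
    log.info("done in %.1f s; artifacts in %s", _time.perf_counter() - t0, out)
    return out


def compute_indices(geom, res, inflow, outflows) -> dict:
    """Standard index block for the idealized aorta: PWV, ΔA%, TAWSS/OSI, TMP, volume."""

    def q(value, units):
        return {"value": value, "units": units}

    out: dict = {}
    # aortic path inlet -> abdominal outlet
    path = [s for s in ("ASC", "DAO", "TL", "AbAo") if any(g.name == s for g in geom.segments)]
    if path:
        dist = sum(geom.segment(s).length for s in path[:-1]) + geom.segment(path[-1]).length
        try:
            pwv = foot_to_foot_pwv(
                res.waveform("P", path[0], node=0),
                res.waveform("P", path[-1], node=-1),
                dist,
            )
            out["PWV_foot_to_foot"] = q(pwv, "m/s")
        except ValueError as exc:
            out["PWV_foot_to_foot"] = q(None, f"unresolved: {exc}")
    da = {}
    for s in ("ASC", "AbAo"):
        if any(g.name == s for g in geom.segments):
            da[s] = float(np.max(delta_area_pct(res.waveform("A", s, s=0.5)).v))
    out["delta_area_peak_pct"] = {k: q(v, "%") for k, v in da.items()}
    tawss, osi = {}, {}
    for name in res.P:
        t, o = tawss_osi(res.waveform("tau_w", name, s=0.5))
        tawss[name] = q(t, "Pa")
        osi[name] = q(o, "-")
    out["TAWSS"] = tawss
    out["OSI"] = osi
    if geom.dissection is not None:
        tl = res.waveform("P", geom.dissection.tl, s=0.5)
        fl = res.waveform("P", geom.dissection.fl, s=0.5)
        tmp = transmural_pressure(tl, fl)
        out["TMP"] = {
            "max": q(tmp.cycle_max() / MMHG_TO_PA, "mmHg"),
            "min": q(tmp.cycle_min() / MMHG_TO_PA, "mmHg"),
        }
    q_outs = [res.waveform("Q", b.segment, node=-1).scaled(1e6)
              for b in geom.boundaries if b.kind == "wk3"]
    q_outs += [outflows[b.segment] for b in geom.boundaries
               if b.kind == "outflow" and b.segment in outflows]
    out["stored_volume_systole"] = q(stored_volume(inflow, q_outs), "ml")
    return out


def rigid_comparison(rigid_res, comp_res) -> dict:
    """Systolic/diastolic flow split at the outlets, rigid vs compliant."""

    def split(res, seg):
        wf = res.waveform("Q", seg, node=-1)
        half = wf.n // 3  # systole ~ first third of the cycle for these fixtures
        return {
            "systolic_mean_ml_s": float(np.mean(wf.v[:half])) * 1e6,
            "diastolic_mean_ml_s": float(np.mean(wf.v[half:])) * 1e6,
            "peak_ml_s": wf.cycle_max() * 1e6,
        }

    segs = sorted(set(rigid_res.Q) & set(comp_res.Q))
    return {
        s: {"rigid": split(rigid_res, s), "compliant": split(comp_res, s)} for s in segs
    }
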