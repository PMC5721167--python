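"""Result persistence: HDF5 hierarchical store with a CSV fallback.

Layout of the HDF5 file: one group per segment with datasets ``P`` (Pa),
``Q`` (m³/s), ``A`` (m²), ``tau_w`` (Pa) of shape (n_time, n_nodes), a
shared ``time`` dataset, and run metadata in root attributes; every
dataset carries a ``units`` attribute.  The CSV fallback writes one file
per segment/field pair into a directory, with a ``meta.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pulsewave import SimResult

_FIELDS = {"P": "Pa", "Q": "m^3/s", "A": "m^2", "tau_w": "Pa"}


def save_result(res: SimResult, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(res, path)
    else:
        _save_csv_dir(res, path)


def load_result(path) -> SimResult:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_h5(path)
    return _load_csv_dir(path)


def _meta(res: SimResult) -> dict:
    return {
        "T": res.T,
        "dt": res.dt,
        "cycles_run": res.cycles_run,
        "converged": bool(res.converged),
        "residual": res.residual,
        "rigid": bool(res.rigid),
        "volume_error": res.volume_error,
    }


def _save_h5(res: SimResult, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for k, v in _meta(res).items():
            fh.attrs[k] = v
        d = fh.create_dataset("time", data=res.time)
        d.attrs["units"] = "s"
        for name in res.P:
            g = fh.create_group(name)
            for field, units in _FIELDS.items():
                d = g.create_dataset(field, data=getattr(res, field if field != "tau_w" else "tau_w")[name])
                d.attrs["units"] = units


def _load_h5(path: Path) -> SimResult:
    import h5py

    with h5py.File(path, "r") as fh:
        meta = dict(fh.attrs)
        time = fh["time"][()]
        P, Q, A, tau = {}, {}, {}, {}
        for name in fh:
            if name == "time":
                continue
            g = fh[name]
            P[name] = g["P"][()]
            Q[name] = g["Q"][()]
            A[name] = g["A"][()]
            tau[name] = g["tau_w"][()]
    return SimResult(
        time=time,
        T=float(meta["T"]),
        dt=float(meta["dt"]),
        P=P,
        Q=Q,
        A=A,
        tau_w=tau,
        cycles_run=int(meta["cycles_run"]),
        converged=bool(meta["converged"]),
        residual=float(meta["residual"]),
        rigid=bool(meta["rigid"]),
        volume_error=float(meta["volume_error"]),
    )


def _save_csv_dir(res: SimResult, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(json.dumps({**_meta(res), "units": _FIELDS}, indent=2))
    for name in res.P:
        for field in _FIELDS:
            arr = getattr(res, field)[name]
            df = pd.DataFrame(arr, columns=[f"node{j}" for j in range(arr.shape[1])])
            df.insert(0, "time_s", res.time)
            df.to_csv(path / f"{name}_{field}.csv", index=False, float_format="%.10g")


def _load_csv_dir(path: Path) -> SimResult:
    meta = json.loads((path / "meta.json").read_text())
    P, Q, A, tau = {}, {}, {}, {}
    time = None
    for f in sorted(path.glob("*_*.csv")):
        name, field = f.stem.rsplit("_", 1) if not f.stem.endswith("tau_w") else (
            f.stem[: -len("_tau_w")],
            "tau_w",
        )
        df = pd.read_csv(f)
        time = df["time_s"].to_numpy()
        arr = df.drop(columns=["time_s"]).to_numpy()
        {"P": P, "Q": Q, "A": A, "tau": tau, "tau_w": tau}[field][name] = arr
    return SimResult(
        time=time,
        T=float(meta["T"]),
        dt=float(meta["dt"]),
        P=P,
        Q=Q,
        A=A,
        tau_w=tau,
        cycles_run=int(meta["cycles_run"]),
        converged=bool(meta["converged"]),
        residual=float(meta["residual"]),
        rigid=bool(meta["rigid"]),
        volume_error=float(meta["volume_error"]),
    )
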