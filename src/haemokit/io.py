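"""File formats: waveform CSV, field-ensemble CSV + JSON manifest, network JSON.

Interchange units are clinical (mmHg, mL/s); SI-tagged waveform files
(``Pa``, ``m^3/s``) are converted on read. Waveform CSV carries ``#``-prefixed
header lines with the quantity kind, unit and period, then ``time_s,value``
rows. Field ensembles are one CSV per frame (``x_m,y_m,u_mps,v_mps,valid``)
plus a ``manifest.json`` describing the acquisition; an HDF5 mirror of the
same schema is available when h5py is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .flowfield import CycleEnsemble, VelocityField2D
from .waveforms import FlowWaveform, PressureWaveform
from .windkessel import AorticNetwork, BranchSpec, WindkesselParams

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_field_ensemble",
    "write_field_ensemble",
    "read_field_ensemble_hdf5",
    "write_field_ensemble_hdf5",
    "read_network_json",
    "write_network_json",
    "read_targets_json",
    "write_targets_json",
]

_FLOW_UNITS = {"mL/s": 1.0, "m^3/s": 1e6}
_PRESSURE_UNITS = {"mmHg": 1.0, "Pa": 1.0 / 133.322387415}
_FMT = "%.10g"  # >= 9 significant digits round-trip


def write_waveform_csv(w: Union[FlowWaveform, PressureWaveform], path) -> None:
    path = Path(path)
    if isinstance(w, FlowWaveform):
        kind, unit, values = "flow", "mL/s", w.flow
    else:
        kind, unit, values = "pressure", "mmHg", w.pressure
    with path.open("w", newline="") as fh:
        fh.write(f"# kind: {kind}\n# unit: {unit}\n# period_s: {w.period!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(w.time, values):
            fh.write(f"{_FMT % t},{_FMT % v}\n")


def read_waveform_csv(path) -> Union[FlowWaveform, PressureWaveform]:
    path = Path(path)
    header: Dict[str, str] = {}
    with path.open("r", newline="") as fh:
        lines = fh.read().splitlines()
    n_head = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        n_head = i + 1
        body = line[1:].strip()
        if ":" not in body:
            raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        key, _, val = body.partition(":")
        header[key.strip()] = val.strip()
    for required in ("kind", "unit", "period_s"):
        if required not in header:
            raise FormatError(f"{path}: missing required header '{required}'")
    kind = header["kind"]
    unit = header["unit"]
    try:
        period = float(header["period_s"])
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable period_s header") from exc
    df = pd.read_csv(path, skiprows=n_head)
    if list(df.columns) != ["time_s", "value"]:
        raise FormatError(f"{path}: expected columns time_s,value, found {list(df.columns)}")
    time = df["time_s"].to_numpy(float)
    values = df["value"].to_numpy(float)
    if kind == "flow":
        if unit not in _FLOW_UNITS:
            raise FormatError(f"{path}: unknown flow unit {unit!r}")
        return FlowWaveform(time=time, period=period, flow=values * _FLOW_UNITS[unit])
    if kind == "pressure":
        if unit not in _PRESSURE_UNITS:
            raise FormatError(f"{path}: unknown pressure unit {unit!r}")
        return PressureWaveform(
            time=time, period=period, pressure=values * _PRESSURE_UNITS[unit]
        )
    raise FormatError(f"{path}: unknown waveform kind {kind!r}")


def write_field_ensemble(ensemble: CycleEnsemble, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, fr in enumerate(ensemble.frames):
        name = f"frame_{i:04d}.csv"
        names.append(name)
        xx, yy = np.meshgrid(fr.x, fr.y)
        df = pd.DataFrame(
            {
                "x_m": xx.ravel(),
                "y_m": yy.ravel(),
                "u_mps": fr.u.ravel(),
                "v_mps": fr.v.ravel(),
                "valid": fr.valid.ravel().astype(int),
            }
        )
        df.to_csv(directory / name, index=False, float_format=_FMT)
    manifest = {
        "frame_rate_hz": ensemble.frame_rate,
        "period_s": ensemble.period,
        "frames_per_cycle": ensemble.frames_per_cycle,
        "n_cycles": ensemble.n_cycles,
        "grid_shape": [len(ensemble.frames[0].y), len(ensemble.frames[0].x)],
        "frames": names,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_field_ensemble(manifest_path) -> CycleEnsemble:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path}: invalid JSON") from exc
    for key in ("frame_rate_hz", "period_s", "frames_per_cycle", "n_cycles", "grid_shape", "frames"):
        if key not in manifest:
            raise FormatError(f"{manifest_path}: manifest missing key {key!r}")
    expected = manifest["frames_per_cycle"] * manifest["n_cycles"]
    if len(manifest["frames"]) != expected:
        raise FormatError(
            f"{manifest_path}: expected {expected} frames "
            f"({manifest['frames_per_cycle']}/cycle x {manifest['n_cycles']}), "
            f"found {len(manifest['frames'])}"
        )
    ny, nx = manifest["grid_shape"]
    fpc = manifest["frames_per_cycle"]
    frames = []
    for i, name in enumerate(manifest["frames"]):
        df = pd.read_csv(manifest_path.parent / name)
        x = np.unique(df["x_m"].to_numpy(float))
        y = np.unique(df["y_m"].to_numpy(float))
        if len(x) != nx or len(y) != ny:
            raise FormatError(f"{name}: grid does not match the manifest shape")
        shape = (ny, nx)
        frames.append(
            VelocityField2D(
                x=x,
                y=y,
                u=df["u_mps"].to_numpy(float).reshape(shape),
                v=df["v_mps"].to_numpy(float).reshape(shape),
                valid=df["valid"].to_numpy(int).reshape(shape).astype(bool),
                phase=i % fpc,
                cycle=i // fpc,
            )
        )
    return CycleEnsemble(
        frames=frames,
        frame_rate=manifest["frame_rate_hz"],
        period=manifest["period_s"],
        n_cycles=manifest["n_cycles"],
    )


def write_field_ensemble_hdf5(ensemble: CycleEnsemble, path) -> None:
    import h5py

    f0 = ensemble.frames[0]
    with h5py.File(path, "w") as h5:
        h5.attrs["frame_rate_hz"] = ensemble.frame_rate
        h5.attrs["period_s"] = ensemble.period
        h5.attrs["n_cycles"] = ensemble.n_cycles
        h5.create_dataset("x", data=f0.x)
        h5.create_dataset("y", data=f0.y)
        h5.create_dataset("u", data=np.stack([fr.u for fr in ensemble.frames]))
        h5.create_dataset("v", data=np.stack([fr.v for fr in ensemble.frames]))
        h5.create_dataset("valid", data=np.stack([fr.valid for fr in ensemble.frames]))


def read_field_ensemble_hdf5(path) -> CycleEnsemble:
    import h5py

    with h5py.File(path, "r") as h5:
        frame_rate = float(h5.attrs["frame_rate_hz"])
        period = float(h5.attrs["period_s"])
        n_cycles = int(h5.attrs["n_cycles"])
        x = h5["x"][:]
        y = h5["y"][:]
        u = h5["u"][:]
        v = h5["v"][:]
        valid = h5["valid"][:].astype(bool)
    fpc = int(round(period * frame_rate))
    frames = [
        VelocityField2D(
            x=x, y=y, u=u[i], v=v[i], valid=valid[i], phase=i % fpc, cycle=i // fpc
        )
        for i in range(u.shape[0])
    ]
    return CycleEnsemble(frames=frames, frame_rate=frame_rate, period=period, n_cycles=n_cycles)


def write_network_json(network: AorticNetwork, path) -> None:
    doc = {
        "venous_pressure_mmHg": network.venous_pressure,
        "branches": [
            {
                "label": b.label,
                "R1_mmHg_s_per_mL": b.wk.r1,
                "R2_mmHg_s_per_mL": b.wk.r2,
                "C_mL_per_mmHg": b.wk.c,
                "R_series_mmHg_s_per_mL": b.r_series,
            }
            for b in network.branches
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network_json(path) -> AorticNetwork:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON") from exc
    if "branches" not in doc or not isinstance(doc["branches"], list):
        raise FormatError(f"{path}: network document must list branches")
    branches = []
    for i, b in enumerate(doc["branches"]):
        try:
            branches.append(
                BranchSpec(
                    label=b["label"],
                    wk=WindkesselParams(
                        r1=float(b["R1_mmHg_s_per_mL"]),
                        r2=float(b["R2_mmHg_s_per_mL"]),
                        c=float(b["C_mL_per_mmHg"]),
                    ),
                    r_series=float(b.get("R_series_mmHg_s_per_mL", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed branch entry {i}: {exc}") from exc
    return AorticNetwork(
        branches=branches, venous_pressure=float(doc.get("venous_pressure_mmHg", 0.0))
    )


def write_targets_json(targets, path) -> None:
    doc = {
        "P_sys_mmHg": targets.p_sys,
        "P_dia_mmHg": targets.p_dia,
        "Q_inlet_mL_per_s": targets.q_inlet,
        "branch_flows_mL_per_s": dict(targets.branch_flows),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_targets_json(path):
    from .personalise import TargetSet

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON") from exc
    try:
        return TargetSet(
            p_sys=float(doc["P_sys_mmHg"]),
            p_dia=float(doc["P_dia_mmHg"]),
            q_inlet=float(doc["Q_inlet_mL_per_s"]),
            branch_flows={k: float(v) for k, v in doc["branch_flows_mL_per_s"].items()},
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed target document: {exc}") from exc
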