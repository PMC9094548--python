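"""Config parsing and run-bundle serialization (YAML config, CSV and HDF5).

A run bundle holds everything one simulation produced — the sampled
waveform, the per-breath table, the alarm log — together with a config
snapshot sufficient to reproduce the run bit-identically and provenance
(tool version, seed).  HDF5 is the authoritative format (exact numeric
round-trip); CSV is written for interoperability with 12 significant
digits (relative round-trip error <= 1e-9).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alarms import AlarmRule, AlarmType, Priority, alarms_to_frame
from .controller import PIDGains, VentSettings
from .engine import EventSpec, SimConfig, SimResult, run_simulation
from .lung import CircuitParams, LungParams, SensorModel
from .metrics import WaveformRecord, breaths_to_frame

__all__ = [
    "RunBundle",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "bundle_from_result",
    "write_bundle",
    "read_bundle",
    "resimulate",
]

WAVEFORM_COLUMNS = [
    "time_s",
    "pressure_cmH2O",
    "flow_in_Lpm",
    "flow_out_Lpm",
    "volume_mL",
    "phase",
    "valve_drive",
    "exp_valve_open",
    "alarm_mask",
]


@dataclass
class RunBundle:
    """Serializable snapshot of one run."""

    config: dict
    waveform: WaveformRecord
    breaths: pd.DataFrame
    alarms: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------------------
# Config <-> dict <-> YAML
# ---------------------------------------------------------------------------


def config_to_dict(config: SimConfig) -> dict:
    """SimConfig as a plain (YAML/JSON-safe) dict."""
    settings = asdict(config.settings)
    settings.pop("strict", None)
    out = {
        "ventilator": settings,
        "lung": asdict(config.lung),
        "circuit": asdict(config.circuit),
        "sensors": asdict(config.sensors),
        "gains": asdict(config.gains),
        "sim": {
            "dt_physics": config.dt_physics,
            "dt_control": config.dt_control,
            "duration": config.duration,
            "n_cycles": config.n_cycles,
            "seed": config.seed,
            "fio2_supply": config.fio2_supply,
        },
        "events": [asdict(e) for e in config.events],
    }
    if config.alarm_rules is not None:
        out["alarms"] = {
            "rules": [
                {
                    "type": r.alarm_type.value,
                    "priority": r.priority.name,
                    "threshold": r.threshold,
                    "persistence": r.persistence,
                }
                for r in config.alarm_rules
            ]
        }
    return out


def config_from_dict(data: dict, strict: bool = True) -> SimConfig:
    """Inverse of config_to_dict; unknown keys are rejected."""
    known = {"ventilator", "lung", "circuit", "sensors", "gains", "sim", "events", "alarms"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    vent = dict(data.get("ventilator", {}))
    vent.setdefault("strict", strict)
    sim = dict(data.get("sim", {}))
    rules = None
    if "alarms" in data and data["alarms"] and data["alarms"].get("rules"):
        rules = tuple(
            AlarmRule(
                alarm_type=AlarmType(r["type"]),
                priority=Priority[r["priority"]],
                threshold=float(r["threshold"]),
                persistence=int(r.get("persistence", 1)),
            )
            for r in data["alarms"]["rules"]
        )
    return SimConfig(
        settings=VentSettings(**vent),
        lung=LungParams(**data.get("lung", {"compliance": 20.0, "resistance": 20.0})),
        circuit=CircuitParams(**data.get("circuit", {})),
        sensors=SensorModel(**data.get("sensors", {})),
        gains=PIDGains(**data.get("gains", {})),
        dt_physics=float(sim.get("dt_physics", 0.001)),
        dt_control=float(sim.get("dt_control", 0.005)),
        duration=sim.get("duration"),
        n_cycles=sim.get("n_cycles"),
        seed=int(sim.get("seed", 0)),
        fio2_supply=float(sim.get("fio2_supply", 0.21)),
        events=tuple(EventSpec(**e) for e in data.get("events", [])),
        alarm_rules=rules,
    )


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


def bundle_from_result(result: SimResult) -> RunBundle:
    return RunBundle(
        config=config_to_dict(result.config),
        waveform=result.waveform,
        breaths=breaths_to_frame(result.breaths),
        alarms=alarms_to_frame(result.alarms),
        provenance={
            "tool": "pvpsim",
            "version": __version__,
            "seed": result.config.seed,
        },
    )


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'hdf5'")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_bundle(bundle: RunBundle, path, format: str | None = None) -> Path:
    """Write a bundle; HDF5 to a single file, CSV to a directory containing
    waveform.csv, breaths.csv, alarms.csv and config.yaml."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("waveform")
            frame = bundle.waveform.to_dataframe()
            for col in WAVEFORM_COLUMNS:
                grp.create_dataset(col, data=frame[col].to_numpy())
            for name, table in (("breaths", bundle.breaths), ("alarms", bundle.alarms)):
                grp2 = fh.create_group(name)
                for col in table.columns:
                    data = table[col].to_numpy()
                    if data.dtype.kind in ("O", "U"):
                        strings = np.array([str(x) for x in data], dtype=object)
                        grp2.create_dataset(col, data=strings, dtype=h5py.string_dtype())
                    else:
                        grp2.create_dataset(col, data=data)
            fh.attrs["config_json"] = json.dumps(bundle.config)
            fh.attrs["provenance_json"] = json.dumps(bundle.provenance)
        return path
    path.mkdir(parents=True, exist_ok=True)
    frame = bundle.waveform.to_dataframe()
    frame.to_csv(path / "waveform.csv", index=False, float_format="%.12g")
    bundle.breaths.to_csv(path / "breaths.csv", index=False, float_format="%.12g")
    bundle.alarms.to_csv(path / "alarms.csv", index=False, float_format="%.12g")
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"config": bundle.config, "provenance": bundle.provenance},
            fh,
            sort_keys=False,
        )
    return path


def _waveform_from_frame(frame: pd.DataFrame) -> WaveformRecord:
    missing = set(WAVEFORM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"waveform table missing columns: {sorted(missing)}")
    return WaveformRecord(
        time=frame["time_s"].to_numpy(dtype=float),
        pressure=frame["pressure_cmH2O"].to_numpy(dtype=float),
        flow_in=frame["flow_in_Lpm"].to_numpy(dtype=float),
        flow_out=frame["flow_out_Lpm"].to_numpy(dtype=float),
        volume=frame["volume_mL"].to_numpy(dtype=float),
        phase=frame["phase"].to_numpy(dtype=np.int8),
        valve_drive=frame["valve_drive"].to_numpy(dtype=float),
        expiratory_valve_open=frame["exp_valve_open"].to_numpy(dtype=bool),
        alarm_mask=frame["alarm_mask"].to_numpy(dtype=np.uint16),
    )


def read_bundle(path) -> RunBundle:
    """Inverse of write_bundle; format auto-detected (HDF5 file vs CSV
    directory)."""
    path = Path(path)
    if path.is_file():
        with h5py.File(path, "r") as fh:
            if "waveform" not in fh:
                raise ValueError(f"{path}: missing /waveform group")
            wgrp = fh["waveform"]
            missing = [c for c in WAVEFORM_COLUMNS if c not in wgrp]
            if missing:
                raise ValueError(f"{path}: /waveform missing datasets {missing}")
            frame = pd.DataFrame({c: wgrp[c][...] for c in WAVEFORM_COLUMNS})
            waveform = _waveform_from_frame(frame)

            def _group_frame(name: str) -> pd.DataFrame:
                if name not in fh:
                    raise ValueError(f"{path}: missing /{name} group")
                grp = fh[name]
                cols = {}
                for col in grp:
                    data = grp[col][...]
                    if data.dtype.kind in ("S", "O"):
                        data = np.array([d.decode() if isinstance(d, bytes) else d for d in data])
                    cols[col] = data
                return pd.DataFrame(cols)

            breaths = _group_frame("breaths")
            alarms = _group_frame("alarms")
            config = json.loads(fh.attrs["config_json"])
            provenance = json.loads(fh.attrs.get("provenance_json", "{}"))
        return RunBundle(config, waveform, breaths, alarms, provenance)

    if not path.is_dir():
        raise FileNotFoundError(f"no bundle at {path}")
    try:
        frame = pd.read_csv(path / "waveform.csv")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"{path}/waveform.csv: malformed CSV: {exc}") from exc
    waveform = _waveform_from_frame(frame)
    breaths = pd.read_csv(path / "breaths.csv")
    alarms = pd.read_csv(path / "alarms.csv")
    with open(path / "config.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    return RunBundle(
        meta.get("config", {}), waveform, breaths, alarms, meta.get("provenance", {})
    )


def resimulate(bundle: RunBundle) -> SimResult:
    """Re-run the simulation from a bundle's embedded config snapshot."""
    return run_simulation(config_from_dict(bundle.config))
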