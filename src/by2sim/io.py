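"""CSV/YAML readers and writers for datasets, parameters, designs and reports.

One tidy long-format CSV dialect is used for datasets (columns: label,
response, time_h, value_gL, value_mM), with an uncertainty sidecar
(response, u0, u_prop) and a design sidecar in YAML.  Every file written here
embeds a reproducibility header: package version, seed and a hash of the
generating configuration.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import TimeSeriesDataset
from .crossval import CVReport
from .kinetics import (
    DEFAULT_MOLAR_MASSES,
    NUTRIENT_SYMBOLS,
    KineticParameters,
    KineticParametersImproved,
    KineticParametersInitial,
    MediumComposition,
    MolarMassTable,
    ProcessState,
)
from .mco import ParetoPoint
from .process_sim import ExperimentDesign, FeedPolicy, Trajectory
from .synthetic_data import NoiseSpec

__all__ = [
    "SchemaError",
    "read_dataset", "write_dataset",
    "read_params", "write_params", "reference_params_path",
    "read_design", "write_design",
    "write_trajectory", "write_front", "write_cv_report",
]


class SchemaError(ValueError):
    """A file does not conform to the expected schema."""


_PARAM_CLASSES = {"initial": KineticParametersInitial,
                  "improved": KineticParametersImproved}


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _header(seed=None, config: Mapping | None = None, **extra) -> str:
    lines = [f"# by2sim {__version__}",
             f"# seed: {seed if seed is not None else 'none'}",
             f"# config_hash: {_config_hash(config)}"]
    lines += [f"# {k}: {v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"


def _write_csv(frame: pd.DataFrame, path: Path, seed=None, config=None, **extra):
    buf = _io.StringIO()
    buf.write(_header(seed=seed, config=config, **extra))
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def _read_commented_csv(path: Path) -> pd.DataFrame:
    # only leading '#' lines are header comments; data fields may legally
    # contain '#' (experiment labels are '#1', '#2', ...)
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
    try:
        # round_trip parsing keeps write->read lossless at the last ulp
        return pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc


def _header_meta(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    path = Path(path)
    return (path.with_suffix(".uncertainty.csv"), path.with_suffix(".design.yaml"))


def write_dataset(ds: TimeSeriesDataset, path, seed=None,
                  mm: MolarMassTable = DEFAULT_MOLAR_MASSES) -> Path:
    """Write a dataset as tidy CSV plus uncertainty and design sidecars."""
    path = Path(path)
    rows = []
    for r in ds.responses:
        for t, v in zip(ds.times[r], ds.values[r]):
            v_mM = mm.to_reported(v, r) if r in NUTRIENT_SYMBOLS else np.nan
            rows.append(dict(label=ds.label, response=r, time_h=t,
                             value_gL=v, value_mM=v_mM))
    _write_csv(pd.DataFrame(rows), path, seed=seed,
               config=dict(label=ds.label), label=ds.label)
    unc_path, design_path = _sidecar_paths(path)
    if ds.noise is not None:
        urows = [dict(response=r,
                      u0=getattr(ds.noise, "u0", {}).get(r, 0.0),
                      u_prop=getattr(ds.noise, "u_prop", {}).get(r, 0.0))
                 for r in ds.responses]
        _write_csv(pd.DataFrame(urows), unc_path, seed=seed)
    if ds.design is not None:
        write_design(ds.design, design_path, seed=seed)
    return path


def read_dataset(path) -> TimeSeriesDataset:
    """Read a tidy dataset CSV; sidecars are picked up automatically."""
    path = Path(path)
    frame = _read_commented_csv(path)
    required = {"label", "response", "time_h", "value_gL"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if frame.empty:
        raise SchemaError(f"{path}: empty dataset")
    bad = frame[~frame["response"].isin(("X",) + NUTRIENT_SYMBOLS)]
    if len(bad):
        raise SchemaError(f"{path}: row {bad.index[0] + 1}: unknown response "
                          f"{bad['response'].iloc[0]!r}")
    times, values = {}, {}
    for r, sub in frame.groupby("response", sort=False):
        sub = sub.sort_values("time_h")
        times[r] = sub["time_h"].to_numpy(dtype=float)
        values[r] = sub["value_gL"].to_numpy(dtype=float)

    unc_path, design_path = _sidecar_paths(path)
    noise = None
    if unc_path.exists():
        unc = _read_commented_csv(unc_path)
        if not {"response", "u0", "u_prop"} <= set(unc.columns):
            raise SchemaError(f"{unc_path}: malformed uncertainty sidecar")
        noise = NoiseSpec(u0=dict(zip(unc["response"], unc["u0"].astype(float))),
                          u_prop=dict(zip(unc["response"], unc["u_prop"].astype(float))))
    design = read_design(design_path) if design_path.exists() else None
    return TimeSeriesDataset(label=str(frame["label"].iloc[0]), design=design,
                             times=times, values=values, noise=noise)


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def write_params(params: KineticParameters, path, seed=None,
                 ci: pd.DataFrame | None = None) -> Path:
    """Parameter table CSV: parameter, value, min, max (+ CI columns)."""
    path = Path(path)
    rows = []
    for name in params.NAMES:
        lo, hi = params.BOUNDS[name]
        row = dict(parameter=name, value=getattr(params, name), min=lo, max=hi)
        if ci is not None and name in ci.index:
            row["ci_low"] = ci.loc[name, "ci_low"]
            row["ci_high"] = ci.loc[name, "ci_high"]
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, seed=seed,
               config={"variant": params.variant}, variant=params.variant)
    return path


def read_params(path) -> KineticParameters:
    """Read a parameter table; the variant comes from the header."""
    path = Path(path)
    meta = _header_meta(path)
    variant = meta.get("variant")
    frame = _read_commented_csv(path)
    if not {"parameter", "value"} <= set(frame.columns):
        raise SchemaError(f"{path}: needs 'parameter' and 'value' columns")
    table = dict(zip(frame["parameter"], frame["value"].astype(float)))
    if variant is None:  # infer from the parameter names
        variant = "improved" if "alpha" in table else "initial"
    try:
        cls = _PARAM_CLASSES[variant]
    except KeyError:
        raise SchemaError(f"{path}: unknown variant {variant!r}") from None
    unknown = set(table) - set(cls.NAMES)
    if unknown:
        raise SchemaError(f"{path}: unknown parameters {sorted(unknown)}")
    return cls(**table)


def reference_params_path(variant: str) -> Path:
    """Path of the packaged reference calibration table for a model variant."""
    if variant not in _PARAM_CLASSES:
        raise KeyError(f"unknown variant {variant!r}")
    return Path(str(resources.files("by2sim").joinpath(
        f"data/params_{variant}_reference.csv")))


# --------------------------------------------------------------------------
# designs
# --------------------------------------------------------------------------

def write_design(design: ExperimentDesign, path, seed=None) -> Path:
    path = Path(path)
    pol = design.feed
    doc = dict(
        label=design.label, variant=design.variant, duration=float(design.duration),
        initial={k: float(getattr(design.initial, k))
                 for k in ("V", "Xa", "Xd", "S", "F", "G", "A", "N", "P")},
        feed=dict(mode=pol.mode, trigger_fm=pol.trigger_fm,
                  fm_per_dm=pol.fm_per_dm, drain_interval=pol.drain_interval,
                  v_max=pol.v_max, v_start=pol.v_start,
                  feed_medium={s: float(getattr(pol.feed_medium, s))
                               for s in NUTRIENT_SYMBOLS}),
        sampling_times=[float(t) for t in design.sampling_times],
    )
    text = _header(seed=seed, config=doc) + yaml.safe_dump(doc, sort_keys=False)
    path.write_text(text)
    return path


def read_design(path) -> ExperimentDesign:
    path = Path(path)
    try:
        doc = yaml.safe_load("\n".join(
            ln for ln in path.read_text().splitlines() if not ln.startswith("#")))
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: invalid YAML ({exc})") from exc
    try:
        feed = doc.get("feed", {})
        medium = MediumComposition(**feed.get("feed_medium", {}))
        pol = FeedPolicy(mode=feed.get("mode", "batch_only"),
                         trigger_fm=feed.get("trigger_fm", 100.0),
                         fm_per_dm=feed.get("fm_per_dm", 20.0),
                         drain_interval=feed.get("drain_interval", 24.0),
                         feed_medium=medium, v_max=feed.get("v_max"),
                         v_start=feed.get("v_start"))
        initial = ProcessState(t=0.0, **doc["initial"])
        return ExperimentDesign(
            label=doc["label"], variant=doc["variant"], initial=initial,
            duration=float(doc["duration"]), feed=pol,
            sampling_times=np.asarray(doc.get("sampling_times", []), dtype=float))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed design ({exc})") from exc


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, seed=None,
                     mm: MolarMassTable = DEFAULT_MOLAR_MASSES) -> Path:
    _write_csv(traj.to_frame(mm), Path(path), seed=seed,
               events=";".join(f"{t:.3f}:{k}" for t, k in traj.events) or "none")
    return Path(path)


def write_front(points: Sequence[ParetoPoint], path, seed=None) -> Path:
    frame = pd.DataFrame([dict(X0_gL=p.x0, S0_mM=p.s0_mM, t_star_h=p.t_star,
                               Ya_star=p.ya_star, method=p.method)
                          for p in points])
    _write_csv(frame, Path(path), seed=seed)
    return Path(path)


def read_front(path) -> list[ParetoPoint]:
    frame = _read_commented_csv(Path(path))
    return [ParetoPoint(r.X0_gL, r.S0_mM, r.t_star_h, r.Ya_star, r.method)
            for r in frame.itertuples()]


def write_cv_report(report: CVReport, path, seed=None) -> Path:
    _write_csv(report.to_frame(), Path(path), seed=seed,
               folds=",".join(report.fold_labels))
    return Path(path)
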