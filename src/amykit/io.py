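"""Delimited-text readers/writers, configuration and workflow orchestration.

All exchange formats are plain text: two-column (time, value) traces, wide
plate tables (time plus one column per well) with a layout sidecar, NMR peak
tables, and YAML manifests/configs.  The delimiter (comma or tab) is sniffed
and can be overridden.  Time columns may be declared in s, min or h; the
internal unit is hours for kinetics and seconds for the fast biophysical
traces.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .global_fitting import Condition, DoseSeries
from .kinetic_models import KineticParameters
from .tht_screening import Plate

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "read_plate",
    "write_plate",
    "read_peak_table",
    "read_kinetic_parameters",
    "write_kinetic_parameters",
    "read_manifest",
    "load_dose_series",
    "provenance",
    "write_results_table",
    "run_workflow",
]

log = logging.getLogger(__name__)

TIME_FACTORS_TO_H = {"h": 1.0, "hr": 1.0, "hours": 1.0, "min": 1.0 / 60.0,
                     "s": 1.0 / 3600.0, "sec": 1.0 / 3600.0}


class ParseError(ValueError):
    """A malformed input file, reported with file name and line number."""


def _read_delimited(path, sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    try:
        if sep is None:
            df = pd.read_csv(path, sep=None, engine="python", comment="#")
        else:
            df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pandas raises many flavors
        raise ParseError(f"{path}: cannot parse delimited text: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 columns, found {df.shape[1]}")
    return df


def _check_monotone_time(path, t: np.ndarray) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +3: header line, 0- vs 1-based, and the offense is at the second
        # element of the first non-increasing pair
        raise ParseError(
            f"{path}: time is not strictly increasing at data row {bad[0] + 3}"
        )


def read_trace(path, sep: Optional[str] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time, value) trace; validates monotone time."""
    df = _read_delimited(path, sep)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    _check_monotone_time(path, t)
    return t, y


def write_trace(path, times, values, header: Tuple[str, str] = ("time", "value"),
                sep: str = ",") -> None:
    pd.DataFrame({header[0]: times, header[1]: values}).to_csv(path, sep=sep,
                                                               index=False)


def read_plate(data_path, layout_path, sep: Optional[str] = None,
               time_unit: str = "h") -> Plate:
    """Read a wide plate table (first column time) and its layout sidecar."""
    df = _read_delimited(data_path, sep)
    t = df.iloc[:, 0].to_numpy(dtype=float) * _time_factor(time_unit)
    _check_monotone_time(data_path, t)
    data = df.iloc[:, 1:].astype(float)
    data.index = t
    layout = _read_delimited(layout_path, sep)
    if "well" not in layout.columns or "role" not in layout.columns:
        raise ParseError(f"{layout_path}: layout needs 'well' and 'role' columns")
    if "condition" not in layout.columns:
        layout["condition"] = layout.get("compound", "sample")
    layout = layout.set_index("well")
    return Plate(times=t, data=data, layout=layout)


def write_plate(plate: Plate, data_path, layout_path, sep: str = ",") -> None:
    out = plate.data.copy()
    out.insert(0, "time", plate.times)
    out.to_csv(data_path, sep=sep, index=False)
    plate.layout.reset_index().to_csv(layout_path, sep=sep, index=False)


def read_peak_table(path, sep: Optional[str] = None) -> pd.DataFrame:
    """Read an NMR peak table with residue, dH, dN, intensity columns."""
    df = _read_delimited(path, sep)
    missing = {"residue", "dH", "dN", "intensity"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: peak table lacks columns {sorted(missing)}")
    return df


def _time_factor(unit: str) -> float:
    try:
        return TIME_FACTORS_TO_H[unit]
    except KeyError:
        raise ParseError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_FACTORS_TO_H)}"
        ) from None


# --- configuration ----------------------------------------------------------


def read_kinetic_parameters(path) -> KineticParameters:
    """Read a flat YAML mapping into KineticParameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a flat key-value mapping")
    return KineticParameters(**raw)


def write_kinetic_parameters(p: KineticParameters, path) -> None:
    data = {k: v for k, v in asdict(p).items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_manifest(path) -> Dict:
    """Read and validate a dataset manifest (YAML)."""
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "kind" not in manifest:
        raise ParseError(f"{path}: manifest must be a mapping with a 'kind' key")
    for entry in manifest.get("files", []):
        fpath = (path.parent / entry["path"]).resolve()
        if not fpath.exists():
            raise ParseError(f"{path}: referenced file does not exist: {entry['path']}")
    paths = [e.get("path") for e in manifest.get("files", [])]
    if len(paths) != len(set(paths)):
        raise ParseError(f"{path}: file paths must be unique")
    # replicates share a label but must agree on condition metadata
    seen: Dict[str, Tuple] = {}
    for e in manifest.get("files", []):
        key = (e.get("concentration"), e.get("m0"))
        prev = seen.setdefault(e.get("label"), key)
        if prev != key:
            raise ParseError(
                f"{path}: condition {e.get('label')!r} has inconsistent metadata"
            )
    scenario = manifest.get("options", {}).get("scenario")
    if scenario is not None:
        from .global_fitting import SCENARIOS

        if scenario not in SCENARIOS:
            raise ParseError(
                f"{path}: unknown scenario {scenario!r}; expected one of "
                f"{sorted(SCENARIOS)}"
            )
    return manifest


def load_dose_series(manifest: Dict, base_dir) -> DoseSeries:
    """Assemble a DoseSeries from a manifest's per-condition trace files."""
    base = Path(base_dir)
    unit = manifest.get("time_unit", "h")
    factor = _time_factor(unit)
    by_label: Dict[str, Dict] = {}
    for entry in manifest.get("files", []):
        label = entry["label"]
        t, y = read_trace(base / entry["path"])
        rec = by_label.setdefault(
            label,
            {
                "times": t * factor,
                "curves": [],
                "concentration": float(entry.get("concentration", 0.0)),
                "m0": float(entry.get("m0", manifest.get("m0", 10.0))),
            },
        )
        if not np.array_equal(rec["times"], t * factor):
            raise ParseError(
                f"condition {label!r}: replicate time grids differ ({entry['path']})"
            )
        rec["curves"].append(y)
    conditions = [
        Condition(label=label, concentration=rec["concentration"], m0=rec["m0"],
                  times=rec["times"], curves=np.vstack(rec["curves"]))
        for label, rec in by_label.items()
    ]
    conditions.sort(key=lambda c: c.concentration)
    return DoseSeries(conditions, metadata={"manifest_kind": manifest.get("kind")})


# --- results and provenance -------------------------------------------------


def provenance(seed: Optional[int], config: Dict) -> Dict[str, object]:
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"amykit_version": __version__, "seed": seed, "config_hash": digest}


def write_results_table(df: pd.DataFrame, path, seed: Optional[int],
                        config: Dict, sep: str = "\t") -> None:
    """Write a tidy results table with a provenance comment header."""
    prov = provenance(seed, config)
    with open(path, "w") as fh:
        for key, val in prov.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep=sep, index=False)


# --- workflow ---------------------------------------------------------------


def run_workflow(manifest_path, out_dir, seed: int = 0,
                 n_starts: int = 16) -> Dict[str, object]:
    """Run the dose-series analysis sequence described by a manifest.

    Stages: load → scenario comparison (AICc) → per-condition λ/κ
    extraction.  Stage failures are isolated; downstream stages are skipped
    with a recorded reason.  Returns a result summary dict; result tables
    and a log land in ``out_dir``.
    """
    from .global_fitting import compare_scenarios, extract_macroscopic

    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)
    summary: Dict[str, object] = {"stages": {}, "failed": False}
    series = None
    try:
        series = load_dose_series(manifest, manifest_path.parent)
        summary["stages"]["load"] = "ok"
    except ParseError as exc:
        summary["stages"]["load"] = f"failed: {exc}"
        summary["failed"] = True

    if series is not None:
        options = manifest.get("options", {})
        theta = float(options.get("theta", 0.323))
        try:
            fits = compare_scenarios(series, theta=theta, seed=seed,
                                     n_starts=n_starts)
            rows = []
            for f in fits:
                row = {"scenario": f.scenario, "rss": f.rss, "n_obs": f.n_obs,
                       "k_params": f.k_params, "aicc": f.aicc,
                       "delta_aicc": f.delta_aicc, "r2": f.r2,
                       "success": f.success}
                rows.append(row)
            table = pd.DataFrame(rows)
            write_results_table(table, out / "scenario_comparison.tsv", seed, manifest)
            summary["stages"]["fit"] = "ok"
            summary["best_scenario"] = fits[0].scenario
        except Exception as exc:  # fit failures must not mask the report
            summary["stages"]["fit"] = f"failed: {exc}"
            summary["failed"] = True
        try:
            macro = extract_macroscopic(series, theta=theta, seed=seed)
            table = pd.DataFrame(
                {
                    "condition": macro.labels,
                    "concentration": macro.concentrations,
                    "lambda": macro.lam,
                    "lambda_err": macro.lam_err,
                    "kappa": macro.kappa,
                    "kappa_err": macro.kappa_err,
                }
            )
            write_results_table(table, out / "macroscopic_rates.tsv", seed, manifest)
            summary["stages"]["extract"] = "ok"
        except Exception as exc:
            summary["stages"]["extract"] = f"failed: {exc}"
            summary["failed"] = True
    else:
        summary["stages"]["fit"] = "skipped: load failed"
        summary["stages"]["extract"] = "skipped: load failed"

    with open(out / "workflow_log.json", "w") as fh:
        json.dump({**summary, **provenance(seed, manifest)}, fh, indent=2)
    return summary
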