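"""Readers and writers for the pipeline's delimited-text and JSON artifacts.

All CSV output is UTF-8, comma-separated, '.'-decimal with a header row;
structured results are JSON.  Schema validation is strict and errors carry
the offending row or field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import params_from_mapping, setup_from_mapping
from .equilibrium import DoseResponseCurve, HookMetrics, Trajectory
from .fitting import CohortSummary, FitResult, ObservedDoseResponse
from .model import BindingParameters, ExperimentSetup, SPECIES
from .scans import ScanResult

__all__ = [
    "SchemaError",
    "DuplicateRecordError",
    "read_params",
    "read_setup",
    "read_observed_csv",
    "write_observed_csv",
    "write_curve_csv",
    "write_trajectory_csv",
    "write_scan_csv",
    "write_scan_meta",
    "write_hook_metrics",
    "write_fit_results",
    "write_fit_summary_csv",
    "file_sha256",
]

_OBSERVED_COLUMNS = ("pair_id", "dose_ug_per_ml", "readout_mfi", "readout_kind")


class SchemaError(ValueError):
    """Input file violates the expected schema."""


class DuplicateRecordError(SchemaError):
    """The same (pair_id, dose) appears more than once."""


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return doc


def read_params(path: str | Path) -> tuple[BindingParameters, dict]:
    """Read a kinetic parameter file (YAML or JSON): keys kf1..kf4, kr1..kr4."""
    return params_from_mapping(_load_structured(path))


def read_setup(path: str | Path) -> ExperimentSetup:
    """Read an experiment setup file (YAML or JSON) with unit-explicit keys."""
    return setup_from_mapping(_load_structured(path))


def read_observed_csv(path: str | Path) -> list[ObservedDoseResponse]:
    """Read observed dose-response series, one object per pair_id.

    Validates columns, numeric parses and dose positivity; reports the
    1-based data row number of the first offending cell.  Doses are sorted
    ascending within each pair.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"observed data file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, header row required") from exc
    missing = [c for c in _OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    for col in ("dose_ug_per_ml", "readout_mfi"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col!r} at data row {bad[0] + 1}")
        df[col] = parsed
    bad = df.index[df["dose_ug_per_ml"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive dose at data row {bad[0] + 1}")

    dup = df.duplicated(subset=["pair_id", "dose_ug_per_ml"])
    if dup.any():
        row = df.index[dup][0]
        raise DuplicateRecordError(
            f"{path}: duplicate (pair_id, dose) record at data row {row + 1}"
        )

    out = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        kinds = grp["readout_kind"].unique()
        if len(kinds) != 1:
            raise SchemaError(f"{path}: pair {pair_id!r} mixes readout kinds {list(kinds)}")
        out.append(
            ObservedDoseResponse(
                pair_id=str(pair_id),
                doses=grp["dose_ug_per_ml"].to_numpy(),
                readout=grp["readout_mfi"].to_numpy(),
                readout_kind=str(kinds[0]),
            )
        )
    return out


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_observed_csv(observations: list[ObservedDoseResponse], path: str | Path) -> None:
    lines = [",".join(_OBSERVED_COLUMNS)]
    for obs in observations:
        for d, r in zip(obs.doses, obs.readout):
            lines.append(f"{obs.pair_id},{_fmt(d)},{_fmt(r)},{obs.readout_kind}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_curve_csv(curve: DoseResponseCurve, path: str | Path) -> None:
    lines = ["pair_id,dose_ug_per_ml,ternary_nM,ternary_normalized"]
    norm = curve.normalized
    for d, t, n in zip(curve.doses, curve.ternary, norm):
        lines.append(f"{curve.pair_id},{_fmt(d)},{_fmt(t)},{_fmt(n)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    lines = ["time_s," + ",".join(f"{s}_nM" for s in SPECIES)]
    for t, row in zip(traj.times, traj.states):
        lines.append(_fmt(t) + "," + ",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scan_csv(scan: ScanResult, path: str | Path) -> None:
    """Long-format scan table: one row per (parameter value, dose)."""
    lines = ["parameter_value,dose_ug_per_ml,ternary_nM,ternary_normalized"]
    norm = scan.normalized
    for i, v in enumerate(scan.values):
        for j, d in enumerate(scan.doses):
            lines.append(f"{_fmt(v)},{_fmt(d)},{_fmt(scan.ternary[i, j])},{_fmt(norm[i, j])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_scan_meta(scan: ScanResult, path: str | Path, extra: dict | None = None) -> None:
    doc = {
        "parameter": scan.parameter,
        "n_param": int(scan.values.size),
        "n_dose": int(scan.doses.size),
        "parameter_range": [float(scan.values[0]), float(scan.values[-1])],
        "dose_range_ug_per_ml": [float(scan.doses[0]), float(scan.doses[-1])],
        "global_max_ternary_nM": float(scan.ternary.max()),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_hook_metrics(metrics: HookMetrics, path: str | Path) -> None:
    doc = {
        "peak_dose_ug_per_ml": metrics.peak_dose,
        "peak_ternary_nM": metrics.peak_ternary,
        "effective_window_ug_per_ml": list(metrics.effective_window),
        "hook_detected": metrics.hook_detected,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_fit_results(summary: CohortSummary, path: str | Path) -> None:
    doc = {
        "results": [r.to_dict() for r in summary.results],
        "mean_sse_initial": summary.mean_sse_initial,
        "mean_sse_fitted": summary.mean_sse_fitted,
        "outlier_pairs": list(summary.outlier_pairs),
        "failed_pairs": summary.failed_pairs,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_fit_summary_csv(summary: CohortSummary, path: str | Path) -> None:
    lines = ["pair_id,sse_initial,sse_fitted,converged,outlier"]
    for r in summary.results:
        out = "yes" if r.pair_id in summary.outlier_pairs else "no"
        lines.append(
            f"{r.pair_id},{_fmt(r.sse_initial)},{_fmt(r.sse_fitted)},"
            f"{'yes' if r.converged else 'no'},{out}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
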