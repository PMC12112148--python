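"""File formats, structured configuration and run manifests.

All formats are plain text: a two-column trace CSV per subject
(``time_s,fluorescence_au``), a cohort metadata CSV, a per-subject parameter
CSV, JSON for comparisons/ground truth/manifests, and a plain-text report
narrative.  CSVs use comma separators, ``.`` decimals, UTF-8 and a mandatory
header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    COMORBIDITY_FLAGS,
    GROUP_LABELS,
    GroupComparison,
    SubjectRecord,
)
from .parameters import PARAMETER_NAMES, FMSFParameters
from .signal_processing import BandDefinition, FMSFTrace, MeasurementProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "read_trace",
    "write_trace",
    "read_cohort_table",
    "write_cohort_table",
    "write_parameters",
    "read_parameters",
    "write_report",
    "RunManifest",
    "load_config",
    "TraceSchemaError",
]

TRACE_COLUMNS = ("time_s", "fluorescence_au")
COHORT_COLUMNS = ("subject_id", "group", "sex", "age", "bmi", "sbp", "dbp",
                  *COMORBIDITY_FLAGS)
#: Relative tolerance on sampling-interval jitter when reading traces.
SPACING_RTOL = 1e-4


class TraceSchemaError(ValueError):
    """Raised when a trace CSV violates the schema."""


def write_trace(trace: FMSFTrace, path: str | Path) -> Path:
    """Write a trace CSV with enough precision for 1e-9 round-trip fidelity."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for t, f in zip(trace.time, trace.fluorescence):
            fh.write(f"{t:.12g},{f:.12g}\n")
    return path


def read_trace(path: str | Path) -> FMSFTrace:
    """Read and validate a trace CSV, inferring the sampling rate.

    The time column must be strictly increasing and uniformly spaced within
    ``SPACING_RTOL`` relative jitter; the recorded rate is
    ``(n-1) / (t_last - t_first)`` and a canonical uniform time axis is
    reconstructed from it.  Errors name the first offending data line
    (1-based, counting the header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise TraceSchemaError(f"{path}: unreadable CSV ({exc})") from exc
    if list(df.columns) != list(TRACE_COLUMNS):
        raise TraceSchemaError(
            f"{path}: header must be {','.join(TRACE_COLUMNS)!r}, "
            f"got {','.join(map(str, df.columns))!r} on line 1")
    if len(df) < 2:
        raise TraceSchemaError(f"{path}: needs at least two samples")
    t = df["time_s"].to_numpy(dtype=float)
    f = df["fluorescence_au"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(f)):
        line = int(np.argmax(~(np.isfinite(t) & np.isfinite(f)))) + 2
        raise TraceSchemaError(f"{path}: non-finite value on line {line}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3
        raise TraceSchemaError(f"{path}: non-monotone time on line {line}")
    step = (t[-1] - t[0]) / (len(t) - 1)
    off = np.abs(dt - step) > SPACING_RTOL * step
    if np.any(off):
        line = int(np.argmax(off)) + 3
        raise TraceSchemaError(
            f"{path}: irregular sampling on line {line} "
            f"(|dt - {step:.6g}| > {SPACING_RTOL} relative)")
    rate = 1.0 / step
    time = t[0] + np.arange(len(t)) * step
    return FMSFTrace(time=time, fluorescence=f, sampling_rate=rate)


def write_cohort_table(subjects: Sequence[SubjectRecord] | pd.DataFrame,
                       path: str | Path) -> Path:
    """Write the cohort metadata CSV (booleans as 0/1)."""
    path = Path(path)
    if isinstance(subjects, pd.DataFrame):
        df = subjects.copy()
    else:
        rows = []
        for s in subjects:
            row = {"subject_id": s.subject_id, "group": s.group, "sex": s.sex,
                   "age": s.age, "bmi": s.bmi, "sbp": s.sbp, "dbp": s.dbp}
            for flag in COMORBIDITY_FLAGS:
                row[flag] = int(s.flags.get(flag, False))
            rows.append(row)
        df = pd.DataFrame(rows)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col not in COMORBIDITY_FLAGS else 0
    df = df[list(COHORT_COLUMNS)]
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read cohort metadata into :class:`SubjectRecord` stubs.

    Unknown group labels and duplicate subject ids are errors; unknown
    columns are ignored with a warning; an empty table warns and returns [].
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}",
                      stacklevel=2)
    if df.empty:
        warnings.warn(f"{path}: cohort table is empty", stacklevel=2)
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate subject_id {dupes}")
    bad = sorted(set(df["group"]) - set(GROUP_LABELS))
    if bad:
        raise ValueError(f"{path}: unknown group labels {bad}; "
                         f"expected {GROUP_LABELS}")
    subjects = []
    for _, row in df.iterrows():
        flags = {flag: bool(int(row[flag]))
                 for flag in COMORBIDITY_FLAGS
                 if flag in df.columns and not pd.isna(row[flag])}
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            sex=str(row.get("sex", "F")),
            age=float(row["age"]) if "age" in df.columns else math.nan,
            bmi=float(row["bmi"]) if "bmi" in df.columns else math.nan,
            sbp=float(row["sbp"]) if "sbp" in df.columns else math.nan,
            dbp=float(row["dbp"]) if "dbp" in df.columns else math.nan,
            flags=flags))
    return subjects


def write_parameters(subjects: Sequence[SubjectRecord],
                     path: str | Path) -> Path:
    """Per-subject parameter table; missing values serialize as empty cells."""
    rows = []
    for s in subjects:
        row: dict[str, Any] = {"subject_id": s.subject_id, "group": s.group}
        params = s.parameters.as_dict() if s.parameters else {}
        for name in PARAMETER_NAMES:
            row[name] = params.get(name, math.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.12g")
    return Path(path)


def read_parameters(path: str | Path) -> dict[str, FMSFParameters]:
    """Read a per-subject parameter table back into FMSFParameters."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        vals = {name: (float(row[name]) if not pd.isna(row[name])
                       else math.nan) for name in PARAMETER_NAMES}
        out[str(row["subject_id"])] = FMSFParameters(**vals)
    return out


# --------------------------------------------------------------------------
# Manifest and report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    stage: str
    seed: int | None = None
    config: dict = dataclasses.field(default_factory=dict)
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    record_counts: dict[str, int] = dataclasses.field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path: str | Path) -> Path:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return Path(path)


def _comparison_dict(c: GroupComparison) -> dict:
    d = dataclasses.asdict(c)
    d["significant"] = c.significant
    return {k: (None if isinstance(v, float) and math.isnan(v) else v)
            for k, v in d.items()}


def write_report(summaries: pd.DataFrame,
                 comparisons: Sequence[GroupComparison],
                 manifest: RunManifest, out_dir: str | Path) -> dict[str, Path]:
    """Emit the report bundle: summary CSV, comparisons JSON, manifest JSON
    and a plain-text narrative naming the parameters that differ at p < 0.05.

    The summary CSV has one row per parameter and one mean±SD block per group
    column (cases, pooled cases, controls), mirroring the standard
    case--control summary-table layout.  A footnote records that p-values are
    unadjusted for multiple testing.
    """
    if summaries.empty:
        raise ValueError("empty summaries")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    flat = summaries.copy()
    flat.columns = ["_".join(c) for c in flat.columns]
    paths["summary"] = out_dir / "summary.csv"
    flat.to_csv(paths["summary"], lineterminator="\n", float_format="%.10g")

    paths["comparisons"] = out_dir / "comparisons.json"
    with open(paths["comparisons"], "w", encoding="utf-8") as fh:
        json.dump([_comparison_dict(c) for c in comparisons], fh, indent=2)
        fh.write("\n")

    lines = ["FMSF case-control report", "=" * 24, ""]
    if not comparisons:
        lines.append("no comparisons performed")
    else:
        sig = [c for c in comparisons if c.significant]
        lines.append(f"{len(comparisons)} parameters compared "
                     "(cases vs controls):")
        for c in comparisons:
            mark = "*" if c.significant else " "
            lines.append(f" {mark} {c.parameter:<22s} {c.test:<12s} "
                         f"p = {c.p_value:.4g}")
        lines.append("")
        if sig:
            lines.append("significant at p < 0.05: "
                         + ", ".join(c.parameter for c in sig))
        else:
            lines.append("no parameter differs at p < 0.05")
        lines.append("")
        lines.append("note: p-values are unadjusted for multiple testing.")
    paths["narrative"] = out_dir / "report.txt"
    paths["narrative"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    for p in paths.values():
        manifest.add_output(p)
    paths["manifest"] = manifest.write(out_dir / "manifest.json")
    return paths


# --------------------------------------------------------------------------
# Structured configuration


def load_config(path: str | Path | None) -> dict:
    """Load a YAML configuration file; returns {} when no path is given."""
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level configuration must be a mapping")
    return cfg


def protocol_from_config(cfg: dict) -> MeasurementProtocol:
    return MeasurementProtocol(**cfg.get("protocol", {}))


def bands_from_config(cfg: dict) -> BandDefinition:
    return BandDefinition(**cfg.get("bands", {}))
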