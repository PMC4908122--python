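"""Readers and writers for the interchange formats.

Physio traces and event tables are tab-separated (BIDS-style); all
derived tables are headered, UTF-8, comma-separated CSV. Conductance is
written with 6 significant digits, which the round-trip tests treat as
the documented precision. Time is 0-based seconds from trace start and
"n/a" marks missing values in TSV files.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .paradigm import ParadigmConfig, PhaseName, Stimulus, TrialEvent
from .scoring import ScrTrace

__all__ = [
    "read_physio",
    "write_physio",
    "read_events",
    "write_events",
    "read_voxel_table",
    "write_voxel_table",
    "read_table",
    "write_table",
    "PipelineConfig",
    "load_pipeline_config",
    "paradigm_config_from_dict",
]

_GRID_RTOL = 1e-6
_FLOAT_FMT = "%.6g"


def write_physio(trace: ScrTrace, path: str | Path, bids: bool = False) -> Path:
    """Write a trace as two-column TSV (time_s, conductance_uS), or as a
    BIDS-style gzipped single-column physio TSV with a JSON sidecar
    declaring SamplingFrequency, StartTime and Columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bids:
        if not path.name.endswith(".tsv.gz"):
            raise FormatError(f"BIDS physio path must end in .tsv.gz: {path}")
        with gzip.open(path, "wt", encoding="utf-8", newline="\n") as fh:
            for v in trace.values:
                fh.write((_FLOAT_FMT % v) + "\n")
        sidecar = {
            "SamplingFrequency": trace.sampling_rate,
            "StartTime": trace.start_time,
            "Columns": ["conductance_uS"],
        }
        sidecar_path = path.with_name(path.name[: -len(".tsv.gz")] + ".json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")
    else:
        times = trace.times
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("time_s\tconductance_uS\n")
            for t, v in zip(times, trace.values):
                fh.write(("%.6f" % t) + "\t" + (_FLOAT_FMT % v) + "\n")
    return path


def read_physio(path: str | Path, sidecar: str | Path | None = None) -> ScrTrace:
    """Read a physio trace.

    Two-column TSV: the time grid must be uniform to a relative
    tolerance of 1e-6 of the sampling interval; jittered or non-numeric
    rows raise a format error naming the line. BIDS .tsv.gz: sampling
    frequency and start time come from the JSON sidecar (located next
    to the file if not given).
    """
    path = Path(path)
    if path.name.endswith(".tsv.gz"):
        sidecar_path = (Path(sidecar) if sidecar is not None
                        else path.with_name(path.name[: -len(".tsv.gz")] + ".json"))
        if not sidecar_path.exists():
            raise FormatError(f"missing JSON sidecar for {path}: {sidecar_path}")
        meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
        for key in ("SamplingFrequency", "StartTime"):
            if key not in meta:
                raise FormatError(f"sidecar {sidecar_path} lacks required field {key}")
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        try:
            values = np.array([float(ln.split("\t")[0]) for ln in lines])
        except ValueError as exc:
            raise FormatError(f"non-numeric sample in {path}: {exc}") from exc
        return ScrTrace(float(meta["SamplingFrequency"]), float(meta["StartTime"]), values)

    times: list[float] = []
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("time_s"):
            raise FormatError(f"{path}: line 1: expected header starting with 'time_s'")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric cell") from None
    if len(times) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = np.asarray(times)
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise FormatError(f"{path}: non-increasing time grid")
    bad = np.nonzero(np.abs(dt - dt0) > _GRID_RTOL * dt0)[0]
    if bad.size:
        row = int(bad[0]) + 3  # +2 for header+1-based, +1 for diff offset
        raise FormatError(f"{path}: line {row}: non-uniform time grid "
                          f"(dt={dt[bad[0]]:.9f}, expected {dt0:.9f})")
    return ScrTrace(sampling_rate=1.0 / dt0, start_time=float(t[0]),
                    values=np.asarray(values))


_EVENT_COLUMNS = ["onset", "duration", "trial_type", "phase", "reinforced",
                  "index_within_type"]


def write_events(events: Sequence[TrialEvent], path: str | Path) -> Path:
    """Write events as BIDS-style TSV (onset, duration, trial_type,
    phase, reinforced, index_within_type)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for ev in events:
            fh.write("\t".join([
                "%.6f" % ev.onset,
                "%.6f" % ev.duration,
                ev.stimulus.value,
                ev.phase.value,
                "1" if ev.reinforced else "0",
                str(ev.index_within_type),
            ]) + "\n")
    return path


def read_events(path: str | Path) -> list[TrialEvent]:
    """Read a BIDS-style events TSV; recomputes index_within_type from
    presentation order when the column is absent or 'n/a'."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    except Exception as exc:
        raise FormatError(f"cannot parse events TSV {path}: {exc}") from exc
    for col in ("onset", "duration", "trial_type", "phase"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events: list[TrialEvent] = []
    counters: dict[tuple[str, str], int] = {}
    for i, row in df.iterrows():
        try:
            stim = Stimulus(str(row["trial_type"]))
            phase = PhaseName(str(row["phase"]))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
        key = (phase.value, stim.value)
        counters[key] = counters.get(key, 0) + 1
        idx = row.get("index_within_type")
        if idx is None or (isinstance(idx, float) and np.isnan(idx)):
            idx = counters[key]
        reinforced = row.get("reinforced", 0)
        reinforced = False if pd.isna(reinforced) else bool(int(reinforced))
        try:
            events.append(TrialEvent(
                onset=float(row["onset"]), duration=float(row["duration"]),
                stimulus=stim, phase=phase, reinforced=reinforced,
                index_within_type=int(idx),
            ))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return events


def write_voxel_table(df: pd.DataFrame, path: str | Path) -> Path:
    return write_table(df, path, float_format="%.10g")


def read_voxel_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("fa", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                float_format: str = _FLOAT_FMT) -> Path:
    """Write a headered CSV with a fixed float format (determinism)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format, lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end pipeline settings (paths + the fixed analysis constants)."""

    data_dir: str
    out_dir: str
    baseline_window: float = 2.0
    qc_threshold: float = 0.05
    median_kernel: float = 0.5
    us_window: float = 6.0
    floor_at_zero: bool = True
    eri_numerator_mode: str = "mean_of_sqrt"
    covariates: tuple[str, ...] = ("age", "days_between_scans")
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_window <= 0:
            raise ConfigError("baseline_window must be > 0")
        if self.qc_threshold < 0:
            raise ConfigError("qc_threshold must be >= 0")
        if self.median_kernel < 0:
            raise ConfigError("median_kernel must be >= 0")
        if self.us_window <= 0:
            raise ConfigError("us_window must be > 0")
        if self.eri_numerator_mode not in ("mean_of_sqrt", "sqrt_of_mean"):
            raise ConfigError(f"unknown eri_numerator_mode {self.eri_numerator_mode!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    if "covariates" in raw and raw["covariates"] is not None:
        raw["covariates"] = tuple(raw["covariates"])
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    cfg.validate()
    return cfg


def paradigm_config_from_dict(raw: dict) -> ParadigmConfig:
    """Build a ParadigmConfig from a YAML/JSON mapping."""
    known = {f.name for f in dataclasses.fields(ParadigmConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown paradigm config fields {sorted(unknown)}")
    if "iti_range" in raw and raw["iti_range"] is not None:
        raw = dict(raw)
        raw["iti_range"] = tuple(float(v) for v in raw["iti_range"])
    try:
        cfg = ParadigmConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg
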