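"""Trace file formats, pipeline configuration and orchestration.

Two interchangeable on-disk trace dialects are supported: a delimited-text
format (two columns time_s / current_pa with '#'-prefixed metadata header
lines) and a chunked HDF5 container (one dataset per sweep with the same
metadata as attributes).  ``run_pipeline`` chains simulation (optional),
detection, mean-event fitting and cohort statistics into one run directory
with a provenance JSON, per-stage logs and deterministic output under a
fixed seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .detect import SweepTrace, qc_recording
from .kinetics import InsufficientEventsError, analyze_cell
from .simulate import CellRecording, preset, simulate_cohort
from .stats import compare, summarize

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FormatError",
    "read_trace",
    "write_trace_text",
    "write_trace_h5",
    "read_traces_h5",
    "run_pipeline",
    "cells_to_frame",
]

_META_FIELDS = {
    "sampling_rate_hz": "sampling_rate",
    "holding_mv": "holding_potential",
    "temp_c": "temperature",
    "rs_start_mohm": "rs_start",
    "rs_end_mohm": "rs_end",
}


class FormatError(ValueError):
    """Malformed or incomplete trace file."""


def write_trace_text(trace: SweepTrace, path: str | Path) -> None:
    """Write a sweep as delimited text: '#key: value' header + two columns."""
    path = Path(path)
    with path.open("w") as fh:
        for key, attr in _META_FIELDS.items():
            fh.write(f"# {key}: {getattr(trace, attr):.6f}\n")
        if trace.label:
            fh.write(f"# label: {trace.label}\n")
        fh.write("time_s\tcurrent_pa\n")
        t = trace.times()
        np.savetxt(fh, np.column_stack([t, trace.samples]), fmt="%.6f\t%.6f")


def _read_trace_text(path: Path) -> SweepTrace:
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            data_start = i + 1
        elif line.strip().startswith("time_s"):
            data_start = i + 1
        else:
            break
    if "sampling_rate_hz" not in meta:
        raise FormatError(f"{path}: header is missing sampling_rate_hz")
    arr = np.loadtxt(lines[data_start:])
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns time_s, current_pa")
    t, x = arr[:, 0], arr[:, 1]
    fs = float(meta["sampling_rate_hz"])
    dt = np.diff(t)
    if len(dt) and (np.max(dt) - np.min(dt)) > 1e-5:
        raise FormatError(f"{path}: time column is not uniformly sampled")
    kwargs = {attr: float(meta[key]) for key, attr in _META_FIELDS.items() if key in meta}
    kwargs.pop("sampling_rate", None)
    return SweepTrace(samples=x, sampling_rate=fs, label=meta.get("label", ""), **kwargs)


def write_trace_h5(traces: list[SweepTrace], path: str | Path, seed: Optional[int] = None) -> None:
    """Write sweeps into a chunked HDF5 container, one dataset per sweep."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        if seed is not None:
            grp.attrs["seed"] = int(seed)
        for i, tr in enumerate(traces):
            name = tr.label or f"sweep{i:03d}"
            ds = grp.create_dataset(name, data=tr.samples, chunks=True)
            for key, attr in _META_FIELDS.items():
                ds.attrs[key] = float(getattr(tr, attr))


def read_traces_h5(path: str | Path) -> list[SweepTrace]:
    """Read all sweeps from an HDF5 container."""
    out = []
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FormatError(f"{path}: missing 'sweeps' group")
        for name in sorted(f["sweeps"]):
            ds = f["sweeps"][name]
            if "sampling_rate_hz" not in ds.attrs:
                raise FormatError(f"{path}:{name}: missing sampling_rate_hz attribute")
            kwargs = {
                attr: float(ds.attrs[key])
                for key, attr in _META_FIELDS.items()
                if key in ds.attrs and attr != "sampling_rate"
            }
            out.append(
                SweepTrace(
                    samples=ds[()],
                    sampling_rate=float(ds.attrs["sampling_rate_hz"]),
                    label=name,
                    **kwargs,
                )
            )
    return out


def read_trace(path: str | Path) -> SweepTrace:
    """Read a single sweep, dispatching on the file extension.

    Text (.txt/.tsv/.csv/.dat) and HDF5 (.h5/.hdf5) dialects yield
    identical in-memory traces for the same data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        traces = read_traces_h5(path)
        if len(traces) != 1:
            raise FormatError(f"{path}: expected exactly one sweep, found {len(traces)}")
        return traces[0]
    return _read_trace_text(path)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through JSON."""

    preset: Optional[str] = None  # simulate this cohort when set
    traces: Optional[str] = None  # or read traces from this file/dir
    seed: int = 0
    threshold: float = -5.0
    min_duration: float = 2.0
    max_rise: float = 1.0
    alpha: float = 0.05
    area_fractions: bool = False
    min_events: int = 50
    post_ms: float = 150.0
    out_dir: str = "minikin_run"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def cells_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in summaries],
            "n_events": [c.n_events for c in summaries],
            "amp_pa": [c.amp_pa for c in summaries],
            "rise_ms": [c.rise_ms for c in summaries],
            "charge_pams": [c.charge_pams for c in summaries],
            "t70_ms": [c.t70_ms for c in summaries],
            "model": [c.model for c in summaries],
            "tau_fast": [c.tau_fast for c in summaries],
            "tau_slow": [c.tau_slow for c in summaries],
            "p1": [c.p1 for c in summaries],
            "tau_w": [c.tau_w for c in summaries],
            "f_p": [c.f_p for c in summaries],
        }
    )


def analyze_cohort(cells: list[CellRecording | SweepTrace], config: PipelineConfig):
    """Run detect -> average -> fit on every cell; returns (cells_df, exclusions)."""
    summaries = []
    exclusions = []
    for i, cell in enumerate(cells):
        trace = cell.trace if isinstance(cell, CellRecording) else cell
        cell_id = trace.label or f"cell{i:03d}"
        qc = qc_recording(trace.rs_start, trace.rs_end)
        if not qc.valid:
            exclusions.append({"cell_id": cell_id, "reason": "series_resistance_qc"})
            continue
        try:
            summaries.append(
                analyze_cell(
                    trace,
                    cell_id=cell_id,
                    alpha=config.alpha,
                    min_events=config.min_events,
                    area_fractions=config.area_fractions,
                    post_ms=config.post_ms,
                    threshold=config.threshold,
                    min_duration=config.min_duration,
                    max_rise=config.max_rise,
                )
            )
        except InsufficientEventsError:
            exclusions.append({"cell_id": cell_id, "reason": "min_events"})
    return cells_to_frame(summaries), exclusions


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline into a fresh run directory.

    Writes cells.tsv, exclusions.tsv, summary.json (group summary and,
    when simulating a preset, a one-group ANOVA-ready table) and
    provenance.json (config + versions).  Deterministic under fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.preset is not None:
        cells = simulate_cohort(preset(config.preset), seed=config.seed)
    elif config.traces is not None:
        src = Path(config.traces)
        if src.is_dir():
            files = sorted(src.iterdir())
            if not files:
                raise FileNotFoundError(f"no trace files in {src}")
            cells = [read_trace(p) for p in files]
        elif src.suffix.lower() in {".h5", ".hdf5"}:
            cells = read_traces_h5(src)
        else:
            cells = [read_trace(src)]
    else:
        raise ValueError("config must set either preset or traces")

    cells_df, exclusions = analyze_cohort(cells, config)
    cells_df.to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(exclusions, columns=["cell_id", "reason"]).to_csv(
        out / "exclusions.tsv", sep="\t", index=False
    )

    summary = {}
    if len(cells_df):
        g = summarize({"all": cells_df["tau_w"].to_numpy()})[0]
        summary = {"n_cells": g.n, "tau_w_mean_ms": g.mean, "tau_w_sd_ms": g.sd}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    provenance = {
        "config": asdict(config),
        "minikin_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "n_cells_analyzed": int(len(cells_df)),
        "n_cells_excluded": len(exclusions),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("pipeline run complete: %d cells analyzed, %d excluded", len(cells_df), len(exclusions))
    return out


def cohort_report(
    cells: pd.DataFrame,
    design: pd.DataFrame,
    metric: str = "tau_w",
    test: str = "anova_1way",
    alpha: float = 0.05,
) -> dict:
    """Group statistics for a cells table joined with a design table.

    ``design`` maps cell_id -> group; returns a JSON-serialisable report
    with per-group summaries, the omnibus test and any post hoc flags.
    """
    merged = cells.merge(design, on="cell_id")
    groups = {g: sub[metric].to_numpy() for g, sub in merged.groupby("group", sort=False)}
    res = compare(groups, design=test, alpha=alpha)
    report = {
        "metric": metric,
        "test": res.test,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "groups": [asdict(g) for g in res.groups],
    }
    if res.posthoc is not None:
        report["posthoc_newman_keuls"] = [
            {"a": a, "b": b, "significant": s} for a, b, s in res.posthoc
        ]
    return report
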