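"""Run-directory file formats: per-step log, raw stream, snapshots, config.

An experiment writes one directory containing

* ``Extensometer.csv`` — one row per step, header
  ``Step,Position (nm),Force (µN),Time (µs)`` (UTF-8, the micro signs are
  part of the format);
* ``MRXlog.csv`` — the raw acquisition stream,
  ``Time (µs),Raw (units),Position (nm)``, one row per bridge sample;
* ``Snapshots/`` — one PNG per step when a camera was enabled;
* ``config.yaml`` — the experiment configuration, status and start label,
  sufficient to reproduce the run.

CSVs are comma-separated, LF-terminated, full float precision (``repr``
round-trip), written via a temporary file and an atomic rename so a crash
never leaves a half-written log.  Readers accept ASCII aliases for the micro
sign (``uN``, ``us``) but are strict about column count and row shape.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .controller import ExperimentConfig, ExperimentLog, StepRecord
from .errors import SchemaError
from .instrument import Frame

__all__ = ["EXT_HEADER", "MRX_HEADER", "write_log", "read_log"]

EXT_HEADER = ["Step", "Position (nm)", "Force (µN)", "Time (µs)"]
MRX_HEADER = ["Time (µs)", "Raw (units)", "Position (nm)"]

#: Accepted spellings per canonical column name.
_ALIASES = {
    "Step": {"Step", "step"},
    "Position (nm)": {"Position (nm)"},
    "Force (µN)": {"Force (µN)", "Force (uN)"},
    "Time (µs)": {"Time (µs)", "Time (us)"},
}


def _format_number(x) -> str:
    """Integers as integers, floats with repr round-trip precision."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    f = float(x)
    return str(int(f)) if f.is_integer() else repr(f)


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8", newline="\n")
    os.replace(tmp, path)


def write_log(log: ExperimentLog, out_dir: str | Path,
              run_name: str | None = None) -> Path:
    """Write a complete run directory; returns its path.

    The directory is named after the run's start label (which carries the
    start timestamp for real runs) unless ``run_name`` overrides it.
    """
    root = Path(out_dir) / (run_name or log.start_label)
    root.mkdir(parents=True, exist_ok=True)

    lines = [",".join(EXT_HEADER)]
    for r in log.records:
        lines.append(",".join([
            str(r.step_index),
            _format_number(r.position_nm),
            _format_number(r.force_uN),
            str(int(r.time_us)),
        ]))
    _atomic_write_text(root / "Extensometer.csv", "\n".join(lines) + "\n")

    lines = [",".join(MRX_HEADER)]
    for t_us, raw, pos_nm in log.raw_stream:
        lines.append(f"{int(t_us)},{_format_number(raw)},{_format_number(pos_nm)}")
    _atomic_write_text(root / "MRXlog.csv", "\n".join(lines) + "\n")

    cfg = dataclasses.asdict(log.config)
    cfg["status"] = log.status
    cfg["start_label"] = log.start_label
    if log.frames:
        cfg["scale_um_per_px"] = float(log.frames[0].scale_um_per_px)
    _atomic_write_text(root / "config.yaml",
                       yaml.safe_dump(cfg, sort_keys=True))

    if log.frames:
        snap_dir = root / "Snapshots"
        snap_dir.mkdir(exist_ok=True)
        for rec, frame in zip(
                [r for r in log.records if r.snapshot_path is not None],
                log.frames):
            iio.imwrite(snap_dir / rec.snapshot_path, frame.pixels)
    return root


def _resolve_columns(header: list[str]) -> None:
    if len(header) != len(EXT_HEADER):
        raise SchemaError(
            f"expected {len(EXT_HEADER)} columns, found {len(header)}")
    for canonical, seen in zip(EXT_HEADER, header):
        if seen.strip() not in _ALIASES[canonical]:
            raise SchemaError(f"missing or misnamed column {canonical!r} "
                              f"(found {seen!r})")


def read_log(path: str | Path, load_frames: bool = False) -> ExperimentLog:
    """Read a run directory (or a bare Extensometer.csv) back into memory.

    Reconstructs the config and status from ``config.yaml`` when present;
    otherwise only the records are populated.  With ``load_frames`` the
    snapshot PNGs are reloaded using the pixel scale stored in the config.
    """
    path = Path(path)
    root = path if path.is_dir() else path.parent
    csv_path = path / "Extensometer.csv" if path.is_dir() else path
    if not csv_path.exists():
        raise SchemaError(f"no Extensometer.csv at {csv_path}")

    text = csv_path.read_text(encoding="utf-8")
    rows = [line for line in text.split("\n") if line != ""]
    if not rows:
        raise SchemaError("empty file")
    _resolve_columns(rows[0].split(","))

    config = None
    status = "completed"
    start_label = root.name
    scale = None
    cfg_path = root / "config.yaml"
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
        status = cfg.pop("status", status)
        start_label = cfg.pop("start_label", start_label)
        scale = cfg.pop("scale_um_per_px", None)
        config = ExperimentConfig(**cfg)

    records = []
    snap_dir = root / "Snapshots"
    for lineno, row in enumerate(rows[1:], start=2):
        fields = row.split(",")
        if len(fields) != len(EXT_HEADER):
            raise SchemaError(
                f"row {lineno}: expected {len(EXT_HEADER)} fields, "
                f"found {len(fields)}")
        try:
            step = int(fields[0])
            pos = float(fields[1])
            force = float(fields[2])
            t_us = int(fields[3])
        except ValueError as exc:
            raise SchemaError(f"row {lineno}: {exc}") from exc
        snap = f"{start_label}_{step:04d}.png"
        has_snap = (snap_dir / snap).exists()
        records.append(StepRecord(step_index=step, position_nm=pos,
                                  force_uN=force, time_us=t_us,
                                  snapshot_path=snap if has_snap else None))

    raw_stream: list[tuple[int, float, float]] = []
    mrx_path = root / "MRXlog.csv"
    if mrx_path.exists():
        mrx_rows = [l for l in mrx_path.read_text(encoding="utf-8").split("\n")
                    if l != ""]
        for lineno, row in enumerate(mrx_rows[1:], start=2):
            fields = row.split(",")
            if len(fields) != len(MRX_HEADER):
                raise SchemaError(f"MRXlog row {lineno}: bad field count")
            raw_stream.append((int(fields[0]), float(fields[1]),
                               float(fields[2])))

    frames: list[Frame] = []
    if load_frames and snap_dir.exists():
        for rec in records:
            if rec.snapshot_path is None:
                continue
            pixels = iio.imread(snap_dir / rec.snapshot_path)
            frames.append(Frame(pixels=np.asarray(pixels),
                                scale_um_per_px=scale or 1.0,
                                timestamp_us=rec.time_us))

    log = ExperimentLog(config=config or ExperimentConfig(),
                        records=records, frames=frames,
                        raw_stream=raw_stream, status=status,
                        start_label=start_label)
    return log
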