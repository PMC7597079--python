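"""Portable file containers for RF frames and parametric maps.

The RF container is deliberately minimal and self-describing: one
little-endian float32 matrix file (row-major, one row per sample, one column
per scan line) plus a JSON sidecar header carrying the acquisition metadata.
A plain-text CSV matrix is supported as a fallback dialect for tiny fixtures.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .simulate import LineGeometry, RFFrame

__all__ = [
    "write_rf_frame",
    "read_rf_frame",
    "write_matrix",
    "read_matrix",
    "config_hash",
]

_HEADER_KEYS = (
    "n_samples",
    "n_lines",
    "sampling_rate_hz",
    "sound_speed_mps",
    "pulse_length_mm",
    "geometry",
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_rf_frame(frame: RFFrame, path) -> Path:
    """Write a frame as float32 binary (``.rf``) or CSV (``.csv``) + JSON sidecar."""
    path = Path(path)
    payload = frame.samples.astype("<f4")
    if path.suffix == ".csv":
        np.savetxt(path, payload, delimiter=",", fmt="%.9g")
    else:
        payload.tofile(path)
    header = {
        "n_samples": frame.n_samples,
        "n_lines": frame.n_lines,
        "dtype": "<f4",
        "order": "row-major",
        "layout": "column = scan line",
        "sampling_rate_hz": frame.sampling_rate,
        "sound_speed_mps": frame.sound_speed,
        "pulse_length_mm": frame.pulse_length * 1e3,
        "geometry": {
            "type": frame.geometry.kind,
            "line_spacing_mm": frame.geometry.line_spacing * 1e3
            if frame.geometry.kind == "linear"
            else None,
            "line_spacing_rad": frame.geometry.line_spacing
            if frame.geometry.kind == "convex"
            else None,
            "probe_radius_mm": frame.geometry.probe_radius * 1e3
            if frame.geometry.probe_radius
            else None,
        },
        "subject_id": frame.subject_id,
        "scan_id": frame.scan_id,
        "grade": frame.grade,
    }
    _sidecar(path).write_text(json.dumps(header, indent=1))
    return path


def read_rf_frame(path) -> RFFrame:
    """Read a frame written by :func:`write_rf_frame`; validates the header."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    header = json.loads(sidecar.read_text())
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"sidecar header missing required keys: {missing}")
    shape = (int(header["n_samples"]), int(header["n_lines"]))
    if path.suffix == ".csv":
        samples = np.loadtxt(path, delimiter=",", dtype=np.float32, ndmin=2)
        if samples.shape != shape:
            raise ValueError(f"CSV payload shape {samples.shape} != header {shape}")
    else:
        samples = np.fromfile(path, dtype=header.get("dtype", "<f4"))
        if samples.size != shape[0] * shape[1]:
            raise ValueError(
                f"payload size {samples.size} != header shape {shape}"
            )
        samples = samples.reshape(shape)
    geo = header["geometry"]
    kind = geo.get("type", "linear")
    spacing = (
        geo["line_spacing_mm"] * 1e-3 if kind == "linear" else geo["line_spacing_rad"]
    )
    geometry = LineGeometry(
        kind=kind,
        line_spacing=spacing,
        probe_radius=(geo.get("probe_radius_mm") or None)
        and geo["probe_radius_mm"] * 1e-3,
    )
    return RFFrame(
        samples=samples.astype(float),
        sampling_rate=header["sampling_rate_hz"],
        sound_speed=header["sound_speed_mps"],
        pulse_length=header["pulse_length_mm"] * 1e-3,
        geometry=geometry,
        subject_id=header.get("subject_id", ""),
        scan_id=header.get("scan_id", ""),
        grade=header.get("grade", ""),
    )


def write_matrix(values: np.ndarray, path, meta: dict | None = None) -> Path:
    """Write a generic float32 matrix in the same binary+sidecar dialect."""
    path = Path(path)
    values = np.asarray(values, dtype="<f4")
    values.tofile(path)
    header = {
        "n_rows": values.shape[0],
        "n_cols": values.shape[1],
        "dtype": "<f4",
        "order": "row-major",
    }
    if meta:
        header.update(meta)
    _sidecar(path).write_text(json.dumps(header, indent=1))
    return path


def read_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    header = json.loads(_sidecar(path).read_text())
    values = np.fromfile(path, dtype=header.get("dtype", "<f4"))
    values = values.reshape(header["n_rows"], header["n_cols"])
    return values.astype(float), header


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable configuration (provenance)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
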