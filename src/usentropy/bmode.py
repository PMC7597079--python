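"""Envelope detection, log compression and scan conversion for B-mode display."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import hilbert

from .simulate import LineGeometry, RFFrame

__all__ = [
    "EnvelopeImage",
    "BModeImage",
    "demodulate",
    "log_compress",
    "scan_convert",
    "bmode_pipeline",
]

#: Sentinel for pixels outside the imaging sector after scan conversion;
#: excluded from any downstream statistics.
BACKGROUND = np.nan


@dataclass
class EnvelopeImage:
    """Per-line analytic-signal magnitude of an RF frame (same shape)."""

    values: np.ndarray  # (n_samples, n_lines), >= 0
    source: RFFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")


@dataclass
class BModeImage:
    """Scan-converted display image, intensities in [0, 255]."""

    pixels: np.ndarray  # (height, width); NaN = outside sector
    dynamic_range_db: float
    geometry: LineGeometry | None = None

    def __post_init__(self) -> None:
        finite = self.pixels[np.isfinite(self.pixels)]
        if finite.size and (finite.min() < 0 or finite.max() > 255):
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be positive")


def demodulate(frame: RFFrame) -> EnvelopeImage:
    """Envelope image: |Hilbert transform| of each scan line."""
    if frame.n_samples < 16:
        raise ValueError("scan lines must have at least 16 samples")
    env = np.abs(hilbert(frame.samples, axis=0))
    return EnvelopeImage(values=env, source=frame)


def log_compress(env: EnvelopeImage | np.ndarray, dynamic_range_db: float = 40.0) -> np.ndarray:
    """Log-compress an envelope to display intensities.

    I_dB = 20 log10(env / max(env)); values below -dynamic_range_db are
    clipped, then the [-DR, 0] dB interval is mapped affinely to [0, 255].
    """
    values = env.values if isinstance(env, EnvelopeImage) else np.asarray(env, dtype=float)
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    peak = values.max()
    if peak <= 0:
        raise ValueError("log compression needs a strictly positive envelope peak")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(values / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    return (db + dynamic_range_db) * (255.0 / dynamic_range_db)


def scan_convert(
    img: np.ndarray,
    geometry: LineGeometry,
    axial_spacing: float,
    out_width: int = 700,
    out_height: int = 450,
    dynamic_range_db: float = 40.0,
) -> BModeImage:
    """Resample a beam-space image onto a Cartesian display grid.

    Linear geometry: aspect-correct bilinear resample of the (depth x lateral)
    rectangle.  Convex geometry: polar-to-Cartesian resample using the probe
    radius and angular line spacing; pixels outside the sector are set to the
    background sentinel (NaN).
    """
    img = np.asarray(img, dtype=float)
    n_samples, n_lines = img.shape
    depth = n_samples * axial_spacing
    interp = RegularGridInterpolator(
        (np.arange(n_samples), np.arange(n_lines)),
        img,
        method="linear",
        bounds_error=False,
        fill_value=None,  # constant-extrapolate the half-pixel rim
    )

    if geometry.kind == "linear":
        width = n_lines * geometry.line_spacing
        # pixel centers over the physical rectangle
        z = (np.arange(out_height) + 0.5) / out_height * depth
        x = (np.arange(out_width) + 0.5) / out_width * width
        rows = z / axial_spacing - 0.5
        cols = x / geometry.line_spacing - 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        pixels = interp(np.stack([rr, cc], axis=-1))
    else:
        if geometry.probe_radius is None:
            raise ValueError("convex scan conversion requires probe_radius")
        r0 = geometry.probe_radius
        dtheta = geometry.line_spacing  # radians between lines
        half_span = (n_lines - 1) * dtheta / 2.0
        r_max = r0 + depth
        x_max = r_max * math.sin(half_span)
        z_top = r0 * math.cos(half_span) - r0  # top of sector relative to apex arc
        x = np.linspace(-x_max, x_max, out_width)
        z = np.linspace(min(z_top, 0.0), depth, out_height)
        xx, zz = np.meshgrid(x, z)
        rr = np.hypot(xx, zz + r0) - r0
        th = np.arctan2(xx, zz + r0)
        rows = rr / axial_spacing - 0.5
        cols = (th + half_span) / dtheta
        inside = (rr >= 0) & (rr <= depth) & (np.abs(th) <= half_span + dtheta / 2.0)
        pixels = np.full(xx.shape, BACKGROUND)
        pts = np.stack([rows[inside], cols[inside]], axis=-1)
        pixels[inside] = interp(pts)

    # bilinear interpolation cannot overshoot; clip fp fuzz only
    finite = np.isfinite(pixels)
    pixels[finite] = np.clip(pixels[finite], img.min(), img.max())
    return BModeImage(pixels=pixels, dynamic_range_db=dynamic_range_db, geometry=geometry)


def bmode_pipeline(
    frame: RFFrame,
    dynamic_range_db: float = 40.0,
    out_width: int = 700,
    out_height: int = 450,
) -> BModeImage:
    """RF frame -> envelope -> log compression -> scan conversion."""
    env = demodulate(frame)
    disp = log_compress(env, dynamic_range_db)
    return scan_convert(
        disp,
        frame.geometry,
        frame.axial_spacing,
        out_width=out_width,
        out_height=out_height,
        dynamic_range_db=dynamic_range_db,
    )
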