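"""ROI extraction and scalar feature reduction of entropy parametric maps.

Mirrors the clinical workflow: a fixed-size rectangular region of interest is
placed over liver parenchyma on each scan, the mean entropy inside it is the
per-scan feature, and the per-subject feature is the aggregate over that
subject's repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import EntropyMap
from .simulate import RFFrame

__all__ = ["ROISpec", "extract_roi", "mean_entropy", "subject_feature"]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in physical units.

    ``center_cm`` is (axial, lateral) in cm in beam space; ``None`` centers the
    ROI in the frame.  The clinical default size is 3.5 x 3.5 cm; the ROI must
    lie fully inside the image after conversion to pixels.
    """

    center_cm: tuple[float, float] | None = None
    width_cm: float = 3.5  # lateral
    height_cm: float = 3.5  # axial
    space: str = "beam"

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.space not in ("beam", "display"):
            raise ValueError(f"unknown coordinate space {self.space!r}")


def roi_slices(roi: ROISpec, frame: RFFrame) -> tuple[slice, slice]:
    """Pixel-space slices of the ROI; rejects out-of-bounds placements."""
    da = frame.axial_spacing  # m per sample, c/(2 fs)
    dl = frame.geometry.line_spacing  # m per line
    n_ax = int(round(roi.height_cm * 1e-2 / da))
    n_lat = int(round(roi.width_cm * 1e-2 / dl))
    if roi.center_cm is None:
        ca = frame.n_samples / 2.0
        cl = frame.n_lines / 2.0
    else:
        ca = roi.center_cm[0] * 1e-2 / da
        cl = roi.center_cm[1] * 1e-2 / dl
    a0 = int(round(ca - n_ax / 2.0))
    l0 = int(round(cl - n_lat / 2.0))
    overflow = {
        "top": max(0, -a0),
        "bottom": max(0, a0 + n_ax - frame.n_samples),
        "left": max(0, -l0),
        "right": max(0, l0 + n_lat - frame.n_lines),
    }
    if any(overflow.values()):
        raise ValueError(f"ROI exceeds image bounds by (pixels) {overflow}")
    return slice(a0, a0 + n_ax), slice(l0, l0 + n_lat)


def extract_roi(emap: EntropyMap | np.ndarray, roi: ROISpec, frame: RFFrame) -> np.ndarray:
    """Rectangular submap of the (full-resolution) entropy map.

    Operates on map values in beam space; background/sentinel pixels (NaN)
    survive extraction and are excluded by :func:`mean_entropy`.
    """
    values = emap.values() if isinstance(emap, EntropyMap) else np.asarray(emap, dtype=float)
    if values.shape != (frame.n_samples, frame.n_lines):
        raise ValueError(
            f"map shape {values.shape} does not match the frame "
            f"({frame.n_samples}, {frame.n_lines})"
        )
    sa, sl = roi_slices(roi, frame)
    return values[sa, sl]


def mean_entropy(submap: np.ndarray) -> float:
    """Arithmetic mean over valid (finite) pixels of a submap."""
    submap = np.asarray(submap, dtype=float)
    valid = np.isfinite(submap)
    if not valid.any():
        raise ValueError("submap has no valid pixels")
    return float(submap[valid].mean())


def subject_feature(per_scan_means, aggregation: str = "mean") -> float:
    """Aggregate per-scan ROI means into one per-subject feature."""
    values = np.asarray(list(per_scan_means), dtype=float)
    if values.size == 0:
        raise ValueError("at least one scan is required")
    if aggregation == "mean":
        return float(values.mean())
    if aggregation == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregation {aggregation!r}")
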