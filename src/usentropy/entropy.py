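"""Sliding-window Shannon-entropy parametric imaging of raw RF data.

The local statistic is the Shannon entropy of the amplitude histogram of a
small window of backscattered RF samples:

    H = - sum_i  w(y_i) log2 w(y_i)

where w(y_i) is the occupancy probability of histogram bin i after the window
is normalized in amplitude.  A physically square window (side = one pulse
length by default) slides over the frame with 50% overlap; the coarse map of
per-window entropies is upsampled by bilinear interpolation back to the RF
grid.  Entropy rises as scatterer density increases and the envelope
statistics move from pre-Rayleigh toward Rayleigh, which makes the map a
quantitative marker of fatty infiltration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import RFFrame

__all__ = [
    "EntropyConfig",
    "WindowGrid",
    "EntropyMap",
    "window_entropy",
    "window_geometry",
    "sliding_entropy_map",
    "resize_map",
    "render_overlay",
    "SlidingWindowEntropy",
]


@dataclass(frozen=True)
class EntropyConfig:
    """Settings of the sliding-window entropy estimator.

    window_side_pl : window side length in multiples of the pulse length.
    overlap_ratio  : fraction of window overlap between adjacent positions.
    n_bins         : histogram bins (100 is the standard choice).
    histogram_range: amplitude interval covered by the histogram after
                     normalization.
    normalization  : 'window' divides each window by its own max |amplitude|
                     (gain-invariant); 'frame' divides by the frame-wide max.
    signal         : 'rf' computes entropy on raw RF amplitudes (the default);
                     'envelope' on the demodulated envelope, for comparison.
    zero_window    : value recorded for an all-zero window ('zero' or 'nan').
    """

    window_side_pl: float = 1.0
    overlap_ratio: float = 0.5
    n_bins: int = 100
    histogram_range: tuple[float, float] = (-1.0, 1.0)
    normalization: str = "window"  # window | frame
    signal: str = "rf"  # rf | envelope
    zero_window: str = "zero"  # zero | nan

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_ratio < 1):
            raise ValueError("overlap_ratio must be in [0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.window_side_pl <= 0:
            raise ValueError("window_side_pl must be positive")
        lo, hi = self.histogram_range
        if not lo < hi:
            raise ValueError("histogram_range must be an increasing interval")
        if self.normalization not in ("window", "frame"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.signal not in ("rf", "envelope"):
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.zero_window not in ("zero", "nan"):
            raise ValueError(f"unknown zero_window policy {self.zero_window!r}")

    @property
    def max_entropy_bits(self) -> float:
        return math.log2(self.n_bins)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class WindowGrid:
    """Window tiling of a frame: sizes, steps and start indices."""

    axial_len: int
    lateral_len: int
    axial_step: int
    lateral_step: int
    axial_starts: np.ndarray
    lateral_starts: np.ndarray

    @property
    def axial_centers(self) -> np.ndarray:
        return self.axial_starts + (self.axial_len - 1) / 2.0

    @property
    def lateral_centers(self) -> np.ndarray:
        return self.lateral_starts + (self.lateral_len - 1) / 2.0

    @property
    def n_windows(self) -> int:
        return self.axial_starts.size * self.lateral_starts.size


def window_geometry(frame: RFFrame, config: EntropyConfig) -> WindowGrid:
    """Physically square window tiling of a frame.

    The window side is ``window_side_pl`` pulse lengths.  Axially that is
    ``round(side * 2 fs / c)`` samples (round half away from zero); laterally
    the number of lines spanning the same physical width (side / line
    spacing), minimum 1.  The step is ``floor(len * (1 - overlap))``, minimum
    1; tiling starts at (0, 0) and partial windows at the far edges are
    discarded.
    """
    side_m = config.window_side_pl * frame.pulse_length
    axial_len = max(
        1, _round_half_away(side_m * 2.0 * frame.sampling_rate / frame.sound_speed)
    )
    lateral_len = max(1, _round_half_away(side_m / frame.geometry.line_spacing))
    if axial_len > frame.n_samples or lateral_len > frame.n_lines:
        raise ValueError(
            f"window ({axial_len} samples x {lateral_len} lines) exceeds the "
            f"frame ({frame.n_samples} x {frame.n_lines})"
        )
    axial_step = max(1, int(axial_len * (1.0 - config.overlap_ratio)))
    lateral_step = max(1, int(lateral_len * (1.0 - config.overlap_ratio)))
    axial_starts = np.arange(0, frame.n_samples - axial_len + 1, axial_step)
    lateral_starts = np.arange(0, frame.n_lines - lateral_len + 1, lateral_step)
    return WindowGrid(
        axial_len=axial_len,
        lateral_len=lateral_len,
        axial_step=axial_step,
        lateral_step=lateral_step,
        axial_starts=axial_starts,
        lateral_starts=lateral_starts,
    )


@dataclass
class EntropyMap:
    """Coarse (per-window) and full-resolution entropy parametric maps."""

    coarse: np.ndarray  # (n_axial_windows, n_lateral_windows)
    grid: WindowGrid
    config: EntropyConfig
    full: np.ndarray | None = None  # upsampled to the RF frame shape
    source: RFFrame | None = None
    n_flagged: int = 0  # all-zero windows

    def values(self) -> np.ndarray:
        """Full map if resized, else the coarse map."""
        return self.full if self.full is not None else self.coarse


def _bin_indices(x: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Equal-width bin index of each value; the top edge falls in the last bin."""
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    # values exactly at hi (and fp fuzz just above a bin edge) -> last bin
    return np.clip(idx, 0, n_bins - 1)


def window_entropy(
    window_samples: np.ndarray,
    n_bins: int = 100,
    histogram_range: tuple[float, float] = (-1.0, 1.0),
    normalize: bool = True,
) -> float:
    """Shannon entropy (bits) of one window's amplitude histogram.

    Samples are divided by the window's max |amplitude| (if ``normalize``),
    histogrammed into ``n_bins`` equal-width bins over ``histogram_range``
    (top edge inclusive), and the occupancy probabilities w(y_i) give
    H = -sum w log2 w with 0 log2 0 = 0.  Values outside the range are
    excluded.  An all-zero window has no defined histogram and returns NaN;
    the map-level driver applies the configured policy.
    """
    x = np.asarray(window_samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("window is empty")
    if normalize:
        peak = np.abs(x).max()
        if peak == 0:
            return float("nan")
        x = x / peak
    lo, hi = histogram_range
    inside = (x >= lo) & (x <= hi)
    x = x[inside]
    if x.size == 0:
        return float("nan")
    counts = np.bincount(_bin_indices(x, lo, hi, n_bins), minlength=n_bins)
    w = counts / counts.sum()
    nz = w[w > 0]
    return float(-(nz * np.log2(nz)).sum())


def sliding_entropy_map(frame: RFFrame, config: EntropyConfig | None = None) -> EntropyMap:
    """Entropy at every window position of the sliding-window tiling.

    Vectorized: all windows are gathered with stride tricks, normalized
    per-window, binned, and reduced with one bincount.
    """
    config = config or EntropyConfig()
    data = frame.samples
    if config.signal == "envelope":
        from .bmode import demodulate

        data = demodulate(frame).values
    grid = window_geometry(frame, config)

    win = np.lib.stride_tricks.sliding_window_view(
        data, (grid.axial_len, grid.lateral_len)
    )[:: grid.axial_step, :: grid.lateral_step]
    na, nl = win.shape[:2]
    flat = win.reshape(na * nl, grid.axial_len * grid.lateral_len)

    if config.normalization == "window":
        peak = np.abs(flat).max(axis=1, keepdims=True)
    else:
        peak = np.full((flat.shape[0], 1), np.abs(data).max())
    zero = peak[:, 0] == 0
    safe_peak = np.where(peak == 0, 1.0, peak)
    norm = flat / safe_peak

    lo, hi = config.histogram_range
    n_bins = config.n_bins
    inside = (norm >= lo) & (norm <= hi)
    idx = _bin_indices(norm, lo, hi, n_bins)
    row = np.broadcast_to(np.arange(flat.shape[0])[:, None], idx.shape)
    counts = np.bincount(
        (row[inside] * n_bins + idx[inside]), minlength=flat.shape[0] * n_bins
    ).reshape(flat.shape[0], n_bins)

    total = counts.sum(axis=1, keepdims=True)
    total = np.where(total == 0, 1, total)
    w = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(w > 0, w * np.log2(w), 0.0).sum(axis=1)

    flag_value = 0.0 if config.zero_window == "zero" else np.nan
    h[zero] = flag_value
    coarse = h.reshape(na, nl)
    return EntropyMap(
        coarse=coarse,
        grid=grid,
        config=config,
        source=frame,
        n_flagged=int(zero.sum()),
    )


def resize_map(emap: EntropyMap, target_shape: tuple[int, int] | None = None) -> EntropyMap:
    """Upsample the coarse map to the RF grid by bilinear interpolation.

    Interpolation nodes sit at the window centers; sample positions beyond the
    outermost centers take the nearest-center value (constant extrapolation),
    so the full map is bounded by the coarse min/max.  Degenerate 1xN / Nx1
    coarse grids fall back to 1-D linear interpolation along the non-trivial
    axis.
    """
    if target_shape is None:
        if emap.source is None:
            raise ValueError("target_shape required when the map has no source frame")
        target_shape = emap.source.samples.shape
    coarse = emap.coarse
    rows_out = np.arange(target_shape[0], dtype=float)
    cols_out = np.arange(target_shape[1], dtype=float)
    ac = emap.grid.axial_centers
    lc = emap.grid.lateral_centers

    r = np.clip(rows_out, ac[0], ac[-1])
    c = np.clip(cols_out, lc[0], lc[-1])
    if coarse.shape[0] == 1 and coarse.shape[1] == 1:
        full = np.full(target_shape, coarse[0, 0])
    elif coarse.shape[0] == 1:
        full = np.tile(np.interp(c, lc, coarse[0]), (target_shape[0], 1))
    elif coarse.shape[1] == 1:
        full = np.tile(np.interp(r, ac, coarse[:, 0])[:, None], (1, target_shape[1]))
    else:
        # separable bilinear: interpolate axially, then laterally
        ri = np.searchsorted(ac, r, side="right") - 1
        ri = np.clip(ri, 0, ac.size - 2)
        tr = (r - ac[ri]) / (ac[ri + 1] - ac[ri])
        rows_interp = coarse[ri] * (1 - tr[:, None]) + coarse[ri + 1] * tr[:, None]
        ci = np.searchsorted(lc, c, side="right") - 1
        ci = np.clip(ci, 0, lc.size - 2)
        tc = (c - lc[ci]) / (lc[ci + 1] - lc[ci])
        full = rows_interp[:, ci] * (1 - tc[None, :]) + rows_interp[:, ci + 1] * tc[None, :]
    emap.full = full
    return emap


def render_overlay(
    emap_values: np.ndarray,
    bmode_pixels: np.ndarray,
    colormap: str = "viridis",
    alpha: float = 0.5,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Alpha-blend a pseudocolor entropy map over a grayscale B-mode image.

    Both inputs must share one shape (i.e. the map has been scan-converted with
    the same geometry as the B-mode).  Returns an (H, W, 3) float RGB image in
    [0, 1]:  out = (1 - alpha) * gray + alpha * color.
    """
    import matplotlib

    emap_values = np.asarray(emap_values, dtype=float)
    bmode_pixels = np.asarray(bmode_pixels, dtype=float)
    if emap_values.shape != bmode_pixels.shape:
        raise ValueError(
            f"shape mismatch: entropy map {emap_values.shape} vs "
            f"B-mode {bmode_pixels.shape}"
        )
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    finite = np.isfinite(emap_values)
    if value_range is None:
        vmin = emap_values[finite].min() if finite.any() else 0.0
        vmax = emap_values[finite].max() if finite.any() else 1.0
    else:
        vmin, vmax = value_range
    span = vmax - vmin if vmax > vmin else 1.0
    normed = np.clip((np.nan_to_num(emap_values, nan=vmin) - vmin) / span, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    color = cmap(normed)[..., :3]
    gray = np.nan_to_num(bmode_pixels, nan=0.0) / 255.0
    gray_rgb = np.repeat(gray[..., None], 3, axis=-1)
    return (1.0 - alpha) * gray_rgb + alpha * color


class SlidingWindowEntropy(TransformerMixin, BaseEstimator):
    """Sliding-window Shannon-entropy imaging as a scikit-learn transformer.

    Stateless in the statistical sense (``fit`` only validates parameters):
    ``transform`` maps an :class:`RFFrame` (or an iterable of frames) to an
    :class:`EntropyMap` upsampled to the RF grid.

    Parameters mirror :class:`EntropyConfig`.

    Examples
    --------
    >>> imager = SlidingWindowEntropy(n_bins=100, overlap_ratio=0.5)
    >>> emap = imager.fit_transform(frame)        # doctest: +SKIP
    >>> emap.full.shape == frame.samples.shape    # doctest: +SKIP
    True
    """

    def __init__(
        self,
        window_side_pl: float = 1.0,
        overlap_ratio: float = 0.5,
        n_bins: int = 100,
        histogram_range: tuple[float, float] = (-1.0, 1.0),
        normalization: str = "window",
        signal: str = "rf",
        zero_window: str = "zero",
        resize: bool = True,
    ):
        self.window_side_pl = window_side_pl
        self.overlap_ratio = overlap_ratio
        self.n_bins = n_bins
        self.histogram_range = histogram_range
        self.normalization = normalization
        self.signal = signal
        self.zero_window = zero_window
        self.resize = resize

    def _config(self) -> EntropyConfig:
        return EntropyConfig(
            window_side_pl=self.window_side_pl,
            overlap_ratio=self.overlap_ratio,
            n_bins=self.n_bins,
            histogram_range=tuple(self.histogram_range),
            normalization=self.normalization,
            signal=self.signal,
            zero_window=self.zero_window,
        )

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        if not hasattr(self, "config_"):
            self.fit()
        if isinstance(X, RFFrame):
            return self._transform_one(X)
        return [self._transform_one(frame) for frame in X]

    def _transform_one(self, frame: RFFrame) -> EntropyMap:
        emap = sliding_entropy_map(frame, self.config_)
        if self.resize:
            emap = resize_map(emap)
        return emap
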