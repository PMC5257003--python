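"""Slow-oscillation metrics from wide-field voltage-sensitive dye movies.

Cortical slow oscillations (< 1 Hz alternation between depolarized up states
and hyperpolarized down states) are read out here from a fractional
fluorescence change (dF/F0) trace averaged over a region of interest.  The
module provides the trace extraction, binomial smoothing for display, a
periodogram-based power spectrum with variance normalization (so that the
integral of the spectral density over all frequencies equals the trace
variance), sub-1-Hz band power, power-weighted mean frequency, power
normalization against a reference cohort, grid synchrony over 1-mm tiles, and
epoching into fixed-length recording windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import comb

__all__ = [
    "VSDMovie",
    "ROI",
    "Trace",
    "PowerSpectrum",
    "OscillationMetrics",
    "GridSynchrony",
    "compute_dff",
    "smooth_trace",
    "power_spectrum",
    "total_slow_power",
    "mean_frequency",
    "peak_frequency",
    "normalize_powers",
    "grid_synchrony",
    "epoch_movie",
    "analyze_trace",
]


@dataclass
class VSDMovie:
    """A time-ordered frame stack with physical pixel size and frame interval."""

    frames: np.ndarray
    frame_interval_s: float
    pixel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError(
                f"frames must be a (time, rows, cols) stack with >=2 frames, got {self.frames.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    @property
    def field_size_mm(self) -> tuple[float, float]:
        return (
            self.frames.shape[1] * self.pixel_size_mm,
            self.frames.shape[2] * self.pixel_size_mm,
        )


@dataclass(frozen=True)
class ROI:
    """A rectangular region of interest in pixel coordinates (row-major, 0-based)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must be non-empty")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate(self, shape: tuple[int, ...]) -> None:
        if self.row + self.height > shape[-2] or self.col + self.width > shape[-1]:
            raise ValueError(f"ROI {self} exceeds frame shape {shape[-2:]}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)


@dataclass
class Trace:
    """A dF/F0 time course in percent."""

    values: np.ndarray
    sample_interval_s: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs >=2 samples")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")


@dataclass
class PowerSpectrum:
    """One-sided spectral density: |A|^2 per frequency bin, variance-normalized."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    df_hz: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.shape != self.psd.shape:
            raise ValueError("frequency grid and psd must align")


@dataclass
class OscillationMetrics:
    """Per-epoch slow-oscillation summary for one ROI trace."""

    total_power_sub1hz: float
    mean_frequency_hz: float
    peak_frequency_hz: float
    epoch_id: int = 0
    normalized_power: float | None = None


@dataclass
class GridSynchrony:
    """Per-tile traces and their pairwise Pearson correlation structure."""

    tile_traces: list[Trace]
    tile_origins: list[tuple[int, int]]
    pairwise_corr: np.ndarray
    synchrony_index: float


def compute_dff(
    movie: VSDMovie,
    roi: ROI | None = None,
    baseline: str = "min-frame",
) -> Trace:
    """Mean dF/F0 trace (in %) within an ROI.

    trace[t] = (mean_ROI(F_t) - F0) / F0 * 100, where F0 is the ROI mean of
    the baseline frame.  ``baseline="min-frame"`` (default) takes the frame
    with the lowest mean fluorescence within the ROI (earliest such frame on
    ties), so that per-ROI power is invariant to phase offsets between ROIs;
    ``baseline="min-frame-global"`` judges the minimum over the whole image
    instead; ``baseline="sequence-mean"`` uses the temporal mean of the ROI
    trace.
    """
    if roi is None:
        roi = ROI(0, 0, movie.frames.shape[1], movie.frames.shape[2])
    roi.validate(movie.frames.shape)
    rs, cs = roi.slices()
    roi_means = movie.frames[:, rs, cs].mean(axis=(1, 2))
    if baseline == "min-frame":
        f0 = roi_means[int(np.argmin(roi_means))]
    elif baseline == "min-frame-global":
        f0 = roi_means[int(np.argmin(movie.frames.mean(axis=(1, 2))))]
    elif baseline == "sequence-mean":
        f0 = roi_means.mean()
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if f0 == 0:
        raise ValueError("degenerate baseline: F0 = 0")
    return Trace(values=(roi_means - f0) / f0 * 100.0, sample_interval_s=movie.frame_interval_s)


def smooth_trace(trace: Trace, order: int = 4) -> Trace:
    """Binomial smoothing: convolution with normalized binomial(order) weights.

    Order 0 is the identity; edges are handled by symmetric reflection so the
    length is preserved.  Intended for display only — spectral analysis runs
    on raw traces because the kernel attenuates band power.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order == 0:
        return Trace(trace.values.copy(), trace.sample_interval_s, smoothed=trace.smoothed)
    kernel = comb(order, np.arange(order + 1)) / 2.0**order
    padded = np.pad(trace.values, (order, order), mode="reflect")
    out = np.convolve(padded, kernel, mode="same")[order:-order]
    return Trace(out, trace.sample_interval_s, smoothed=True)


def power_spectrum(trace: Trace) -> PowerSpectrum:
    """Single-taper periodogram of the mean-subtracted trace.

    Variance normalization: sum(psd) * df equals the variance of the
    mean-subtracted trace (Parseval).  The DC bin is retained in the grid but
    is zero after mean subtraction.
    """
    x = trace.values
    if x.size < 8:
        raise ValueError("trace too short for spectral analysis (need >= 8 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    fs = 1.0 / trace.sample_interval_s
    freqs, psd = sps.periodogram(x, fs=fs, window="boxcar", detrend="constant", scaling="density")
    return PowerSpectrum(freqs_hz=freqs, psd=psd, df_hz=fs / x.size)


def total_slow_power(spec: PowerSpectrum, fmax_hz: float = 1.0) -> float:
    """Integrated spectral density over 0 < f < fmax_hz (the slow band)."""
    if fmax_hz >= spec.freqs_hz.max():
        raise ValueError("fmax_hz must lie inside the resolved frequency range")
    band = (spec.freqs_hz > 0) & (spec.freqs_hz < fmax_hz)
    return float(np.sum(spec.psd[band]) * spec.df_hz)


def _band_mask(spec: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (spec.freqs_hz > lo) & (spec.freqs_hz < hi)


def mean_frequency(spec: PowerSpectrum, band: tuple[float, float] = (0.0, 1.0)) -> float:
    """Power-weighted mean frequency (spectral centroid) within a band.

    Returns NaN when the band contains no power.
    """
    m = _band_mask(spec, band)
    p = spec.psd[m]
    total = p.sum()
    # numerically-zero band power (pure leakage) counts as missing
    if total <= 0 or total <= 1e-12 * spec.psd.sum():
        return float("nan")
    return float(np.sum(spec.freqs_hz[m] * p) / total)


def peak_frequency(spec: PowerSpectrum, band: tuple[float, float] = (0.0, 1.0)) -> float:
    """Frequency of the maximum spectral density bin within a band."""
    m = _band_mask(spec, band)
    if not m.any() or spec.psd[m].max() <= 0:
        return float("nan")
    idx = np.flatnonzero(m)[int(np.argmax(spec.psd[m]))]
    return float(spec.freqs_hz[idx])


def normalize_powers(
    powers: Mapping[str, float] | pd.Series,
    reference_ids: Sequence[str],
    strata: Mapping[str, str] | None = None,
) -> pd.Series:
    """Normalize band powers to the mean of a reference cohort, per stratum.

    Each power is divided by the mean power of the reference subjects within
    the same stratum (e.g. age group), so the reference stratum mean is
    exactly 1 after normalization.  Strata are explicit; with ``strata=None``
    all subjects share one stratum.
    """
    s = pd.Series(powers, dtype=float)
    ref = [r for r in reference_ids if r in s.index]
    if not ref:
        raise ValueError("reference subset is empty")
    strata_s = pd.Series({k: (strata or {}).get(k, "_all") for k in s.index})
    out = pd.Series(index=s.index, dtype=float)
    for stratum in strata_s.unique():
        ids = strata_s.index[strata_s == stratum]
        ref_ids = [r for r in ref if r in set(ids)]
        if not ref_ids:
            raise ValueError(f"stratum {stratum!r} has no reference subjects")
        ref_mean = s[ref_ids].mean()
        if ref_mean <= 0:
            raise ValueError(f"reference mean in stratum {stratum!r} is not positive")
        out[ids] = s[ids] / ref_mean
    return out


def grid_synchrony(
    movie: VSDMovie,
    tile_mm: float = 1.0,
    baseline: str = "min-frame",
) -> GridSynchrony:
    """Tile the field into ``tile_mm`` squares and correlate their dF/F traces.

    Tiles are anchored at the field origin (top-left); partial edge tiles are
    discarded.  The synchrony index is the mean of the off-diagonal Pearson
    correlations; zero-variance tiles yield NaN correlations that are ignored
    by the index.
    """
    tile_px = int(round(tile_mm / movie.pixel_size_mm))
    if tile_px < 1:
        raise ValueError("tile smaller than one pixel")
    n_rows = movie.frames.shape[1] // tile_px
    n_cols = movie.frames.shape[2] // tile_px
    if n_rows < 1 or n_cols < 1:
        raise ValueError("field smaller than one tile")
    traces: list[Trace] = []
    origins: list[tuple[int, int]] = []
    for i in range(n_rows):
        for j in range(n_cols):
            roi = ROI(i * tile_px, j * tile_px, tile_px, tile_px)
            traces.append(compute_dff(movie, roi, baseline=baseline))
            origins.append((i * tile_px, j * tile_px))
    mat = np.vstack([t.values for t in traces])
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(len(traces), dtype=bool)]
    index = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return GridSynchrony(tile_traces=traces, tile_origins=origins, pairwise_corr=corr, synchrony_index=index)


def epoch_movie(movie: VSDMovie, epoch_s: float = 50.0) -> list[VSDMovie]:
    """Split a movie into non-overlapping fixed-length epochs; remainder dropped."""
    frames_per = int(round(epoch_s / movie.frame_interval_s))
    if frames_per < 2:
        raise ValueError("epoch shorter than two frames")
    n_epochs = movie.n_frames // frames_per
    if n_epochs < 1:
        raise ValueError(
            f"movie duration {movie.duration_s:.1f} s shorter than one {epoch_s:.1f} s epoch"
        )
    return [
        VSDMovie(
            frames=movie.frames[k * frames_per : (k + 1) * frames_per],
            frame_interval_s=movie.frame_interval_s,
            pixel_size_mm=movie.pixel_size_mm,
            meta={**movie.meta, "epoch": k},
        )
        for k in range(n_epochs)
    ]


def analyze_trace(
    trace: Trace,
    band: tuple[float, float] = (0.0, 1.0),
    epoch_id: int = 0,
) -> OscillationMetrics:
    """Spectrum-level summary of one trace: band power and frequencies."""
    spec = power_spectrum(trace)
    return OscillationMetrics(
        total_power_sub1hz=total_slow_power(spec, fmax_hz=band[1]),
        mean_frequency_hz=mean_frequency(spec, band),
        peak_frequency_hz=peak_frequency(spec, band),
        epoch_id=epoch_id,
    )
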