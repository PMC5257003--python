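"""Ratiometric (FRET) calcium quantification for YC3.6 two-channel volumes.

Yellow cameleon 3.6 reports intracellular free calcium through the ratio R of
its YFP (FRET acceptor) to CFP (donor) emission.  Given in-situ calibration
constants the ratio maps to a concentration through the Hill equation

    [Ca2+] = Kd * ((R - Rmin) / (Rmax - R)) ** (1 / n)

which is strictly increasing on (Rmin, Rmax).  The module covers the full
measurement chain: background subtraction and median filtering of the raw
channels, voxelwise ratio images, per-neurite ratio and concentration
estimates, and classification of "calcium overload" — a per-neurite
dysfunction statistic defined as a ratio exceeding the wildtype mean plus two
standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps, colors
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "CalibrationParams",
    "DEFAULT_CALIBRATION",
    "RatiometricStack",
    "NeuriteMeasurement",
    "OverloadRule",
    "DEFAULT_OVERLOAD_RULE",
    "preprocess_channels",
    "ratio_image",
    "ratio_to_calcium",
    "calcium_to_ratio",
    "measure_neurites",
    "overload_threshold",
    "classify_overload",
    "overload_fraction",
    "pseudocolor_ratio",
]


@dataclass(frozen=True)
class CalibrationParams:
    """In-situ YC3.6 calibration constants defining the ratio <-> [Ca2+] map.

    Parameters
    ----------
    rmin : float
        YFP/CFP ratio at zero calcium.
    rmax : float
        Ratio at indicator saturation.
    kd_nM : float
        Apparent dissociation constant in nM; the concentration at the
        midpoint ratio when ``hill_n == 1``.
    hill_n : float
        Hill coefficient (cooperativity).
    """

    rmin: float = 1.0
    rmax: float = 2.58
    kd_nM: float = 235.0
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.rmin < self.rmax):
            raise ValueError(
                f"calibration requires 0 < rmin < rmax, got rmin={self.rmin}, rmax={self.rmax}"
            )
        if self.kd_nM <= 0:
            raise ValueError(f"kd_nM must be positive, got {self.kd_nM}")
        if self.hill_n <= 0:
            raise ValueError(f"hill_n must be positive, got {self.hill_n}")


#: Packaged default calibration.  The constants are pinned so that the
#: published overload ratio threshold 1.79 sits exactly at the midpoint of
#: (rmin, rmax) and therefore maps to exactly Kd = 235 nM.
DEFAULT_CALIBRATION = CalibrationParams()


@dataclass
class RatiometricStack:
    """A two-channel (CFP, YFP) 3-D fluorescence volume."""

    cfp: np.ndarray
    yfp: np.ndarray
    z_step_um: float = 2.0
    pixel_size_um: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        if self.cfp.shape != self.yfp.shape:
            raise ValueError(
                f"channel shapes differ: cfp {self.cfp.shape} vs yfp {self.yfp.shape}"
            )
        if self.cfp.ndim != 3:
            raise ValueError(f"expected 3-D (z, row, col) volumes, got shape {self.cfp.shape}")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("z_step_um and pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cfp.shape


@dataclass
class NeuriteMeasurement:
    """One ROI's ratio, derived concentration, and overload call."""

    roi_id: int
    mean_ratio: float
    ca_nM: float
    overloaded: bool
    saturated: bool = False
    session_id: str | None = None
    group: str | None = None


@dataclass(frozen=True)
class OverloadRule:
    """Ratio threshold above which a neurite is called calcium-overloaded.

    The reference definition is mean + 2*SD of a wildtype ratio sample; the
    packaged default threshold is 1.79.
    """

    threshold_ratio: float = 1.79
    definition: str = "reference mean + 2 SD"

    def __post_init__(self) -> None:
        if self.threshold_ratio <= 0:
            raise ValueError(f"threshold_ratio must be positive, got {self.threshold_ratio}")


DEFAULT_OVERLOAD_RULE = OverloadRule()


def _last_slice_mode(volume: np.ndarray) -> float:
    """Histogram mode of the last z-slice over integer-binned intensities.

    Ties break toward the lower bin.
    """
    last = np.asarray(volume[-1], dtype=float)
    binned = np.round(last).astype(np.int64)
    lo = binned.min()
    counts = np.bincount((binned - lo).ravel())
    return float(lo + int(np.argmax(counts)))


def preprocess_channels(stack: RatiometricStack, median_radius: int = 2) -> RatiometricStack:
    """Background-subtract and median-filter both channels.

    Per channel: subtract the modal intensity of the last z-slice (assumed to
    contain background only), clip at zero, then apply a 2-D median filter of
    the given radius slice by slice.
    """
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 z-slices (last slice is the background reference)")
    footprint = disk(median_radius)[None, :, :] if median_radius > 0 else None

    def _one(channel: np.ndarray) -> np.ndarray:
        bg = _last_slice_mode(channel)
        out = np.clip(channel - bg, 0.0, None)
        if footprint is not None:
            out = ndimage.median_filter(out, footprint=footprint, mode="reflect")
        return out

    return replace(stack, cfp=_one(stack.cfp), yfp=_one(stack.yfp))


def ratio_image(stack: RatiometricStack, cfp_floor: float = 1.0) -> np.ndarray:
    """Voxelwise YFP/CFP ratio volume; voxels with CFP below ``cfp_floor`` are NaN."""
    valid = stack.cfp >= cfp_floor
    if not valid.any():
        raise ValueError("no voxel has CFP above the floor; ratio volume would be all-invalid")
    ratio = np.full(stack.shape, np.nan)
    np.divide(stack.yfp, stack.cfp, out=ratio, where=valid)
    return ratio


def calcium_to_ratio(ca_nM, calib: CalibrationParams = DEFAULT_CALIBRATION):
    """Forward Hill map: [Ca2+] in nM -> YFP/CFP ratio in (rmin, rmax)."""
    ca = np.asarray(ca_nM, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium concentrations must be non-negative")
    x = (ca / calib.kd_nM) ** calib.hill_n
    r = (calib.rmin + calib.rmax * x) / (1.0 + x)
    return r if r.ndim else float(r)

def ratio_to_calcium(r, calib: CalibrationParams = DEFAULT_CALIBRATION):
    """Inverse Hill map: ratio -> [Ca2+] in nM.

    Ratios at or below rmin map to 0 (indicator underflow); ratios at or above
    rmax are saturated and map to NaN (the concentration is unidentifiable).
    Strictly increasing on (rmin, rmax).
    """
    rr = np.asarray(r, dtype=float)
    ca = np.full(rr.shape, np.nan)
    under = rr <= calib.rmin
    inside = (rr > calib.rmin) & (rr < calib.rmax)
    ca[under] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (rr - calib.rmin) / (calib.rmax - rr)
        ca[inside] = calib.kd_nM * frac[inside] ** (1.0 / calib.hill_n)
    return ca if ca.ndim else float(ca)


def measure_neurites(
    ratio_volume: np.ndarray,
    labels: np.ndarray,
    calib: CalibrationParams = DEFAULT_CALIBRATION,
    rule: OverloadRule = DEFAULT_OVERLOAD_RULE,
    session_id: str | None = None,
    group: str | None = None,
) -> list[NeuriteMeasurement]:
    """Mean ratio, [Ca2+], and overload call for every labelled ROI.

    ``labels`` is an integer volume (0 = background) matching the ratio
    volume's shape; invalid (NaN) ratio voxels are excluded from ROI means.
    """
    labels = np.asarray(labels)
    if labels.shape != ratio_volume.shape:
        raise ValueError("labels and ratio volume must share a shape")
    out: list[NeuriteMeasurement] = []
    for roi_id in np.unique(labels):
        if roi_id == 0:
            continue
        vals = ratio_volume[labels == roi_id]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        mean_ratio = float(vals.mean())
        saturated = mean_ratio >= calib.rmax
        ca = ratio_to_calcium(mean_ratio, calib)
        out.append(
            NeuriteMeasurement(
                roi_id=int(roi_id),
                mean_ratio=mean_ratio,
                ca_nM=ca,
                overloaded=bool(mean_ratio >= rule.threshold_ratio),
                saturated=saturated,
                session_id=session_id,
                group=group,
            )
        )
    return out


def overload_threshold(reference_ratios: Sequence[float] | None = None) -> OverloadRule:
    """Overload rule from a wildtype reference sample: mean + 2*SD (ddof=1).

    With no reference sample the packaged default threshold (1.79) is
    returned.
    """
    if reference_ratios is None:
        return DEFAULT_OVERLOAD_RULE
    ref = np.asarray(reference_ratios, dtype=float)
    if ref.size < 2:
        raise ValueError("need at least 2 reference ratios to estimate a spread")
    sd = float(ref.std(ddof=1))
    mean = float(ref.mean())
    if sd == 0.0:
        warnings.warn("reference sample has zero variance; threshold equals the mean")
        return OverloadRule(threshold_ratio=mean)
    return OverloadRule(threshold_ratio=mean + 2.0 * sd)


def overload_fraction(ratios: Sequence[float], rule: OverloadRule = DEFAULT_OVERLOAD_RULE) -> float:
    """Percentage of ratios at or above the overload threshold."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio sample")
    return float((r >= rule.threshold_ratio).mean() * 100.0)


def classify_overload(
    measurements: Iterable[NeuriteMeasurement] | pd.DataFrame,
    rule: OverloadRule = DEFAULT_OVERLOAD_RULE,
    by: Sequence[str] = ("group", "session_id"),
) -> pd.DataFrame:
    """Per-stratum overload percentages.

    Accepts a list of :class:`NeuriteMeasurement` or a DataFrame with a
    ``mean_ratio`` column plus the stratum columns in ``by``.  Returns one row
    per stratum with columns ``n``, ``n_overloaded`` and ``pct_overloaded``.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame([vars(m) for m in measurements])
    if df.empty:
        raise ValueError("no measurements to classify")
    df["overloaded"] = df["mean_ratio"] >= rule.threshold_ratio
    keys = [k for k in by if k in df.columns and df[k].notna().any()]
    if not keys:
        df["_all"] = "all"
        keys = ["_all"]
    grouped = df.groupby(keys, dropna=False)["overloaded"]
    out = grouped.agg(n="size", n_overloaded="sum").reset_index()
    out["pct_overloaded"] = out["n_overloaded"] / out["n"] * 100.0
    return out.rename(columns={"_all": "stratum"})


def pseudocolor_ratio(
    ratio_img: np.ndarray,
    intensity_img: np.ndarray,
    rlim: tuple[float, float] | None = None,
    cmap: str = "jet",
) -> np.ndarray:
    """HSV-composed rendering: ratio -> hue/saturation, intensity -> value.

    The ratio image (2-D, NaN = invalid) is mapped through the colormap over
    ``rlim`` (defaults to its finite range) to supply hue and saturation; the
    reference intensity image, normalized to its maximum, supplies value.
    Deterministic for fixed color limits.  Returns an RGB float image.
    """
    ratio_img = np.asarray(ratio_img, dtype=float)
    intensity_img = np.asarray(intensity_img, dtype=float)
    if ratio_img.shape != intensity_img.shape:
        raise ValueError("ratio and intensity images must share a shape")
    if rlim is None:
        finite = ratio_img[np.isfinite(ratio_img)]
        if finite.size == 0:
            raise ValueError("ratio image has no finite values")
        rlim = (float(finite.min()), float(finite.max()))
    norm = colors.Normalize(vmin=rlim[0], vmax=rlim[1], clip=True)
    rgba = colormaps[cmap](norm(np.nan_to_num(ratio_img, nan=rlim[0])))
    hsv = colors.rgb_to_hsv(rgba[..., :3])
    vmax = intensity_img.max()
    value = intensity_img / vmax if vmax > 0 else np.zeros_like(intensity_img)
    hsv[..., 2] = np.clip(value, 0.0, 1.0)
    return colors.hsv_to_rgb(hsv)
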