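"""Amyloid plaque morphometry on two-photon cortical volumes.

Quantification follows the standard longitudinal in-vivo protocol: a maximum
intensity projection of each z-stack, a threshold (Otsu by default) and
connected-component segmentation of the projection, exclusion of vascular
amyloid (CAA, which presents as elongated or border-touching structures),
and summary metrics — plaque count, count density per mm^3 of imaged tissue,
and burden as the percentage of projected area occupied.  Longitudinal
change compares the same registered field across imaging sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

__all__ = [
    "PlaqueStack",
    "CAARule",
    "PlaqueSegmentation",
    "PlaqueMetrics",
    "LongitudinalPair",
    "max_projection",
    "segment_plaques",
    "plaque_metrics",
    "longitudinal_change",
    "register_offset",
]


@dataclass
class PlaqueStack:
    """A single-channel 3-D volume with anisotropic physical voxel size."""

    volume: np.ndarray
    voxel_size_um: tuple[float, float, float]
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3 or self.volume.shape[0] < 1:
            raise ValueError(f"expected a (z, row, col) volume, got shape {self.volume.shape}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def volume_mm3(self) -> float:
        nz, nr, nc = self.volume.shape
        vz, vr, vc = self.voxel_size_um
        return nz * vz * nr * vr * nc * vc * 1e-9

    @property
    def pixel_area_um2(self) -> float:
        return self.voxel_size_um[1] * self.voxel_size_um[2]


@dataclass(frozen=True)
class CAARule:
    """Criterion for excluding vascular amyloid from plaque counts.

    Components touching the image border or with an elongation (major/minor
    axis ratio) above the limit are treated as CAA and removed.
    """

    exclude_border: bool = True
    max_elongation: float = 5.0


@dataclass
class PlaqueSegmentation:
    """Thresholded projection, component labels, and retained plaque areas."""

    projection: np.ndarray
    labels: np.ndarray
    plaque_areas_um2: np.ndarray
    excluded_caa: list[int] = field(default_factory=list)
    threshold: float = float("nan")


@dataclass
class PlaqueMetrics:
    """Plaque count, density per mm^3, and burden (% projected area)."""

    count: int
    density_per_mm3: float
    burden_pct: float
    volume_mm3: float


@dataclass
class LongitudinalPair:
    """Percentage change in count and burden between two sessions of one field."""

    metrics_1: PlaqueMetrics
    metrics_2: PlaqueMetrics
    pct_change_count: float
    pct_change_burden: float


def max_projection(stack: PlaqueStack | np.ndarray) -> np.ndarray:
    """Pixelwise maximum intensity projection over z."""
    vol = stack.volume if isinstance(stack, PlaqueStack) else np.asarray(stack, dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3 or vol.shape[0] < 1:
        raise ValueError("need a non-empty (z, row, col) stack")
    return vol.max(axis=0)


def _elongation(prop) -> float:
    minor = prop.axis_minor_length
    major = prop.axis_major_length
    if minor <= 0:
        return float("inf")
    return major / minor


def segment_plaques(
    projection: np.ndarray,
    pixel_area_um2: float = 4.0,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area_um2: float = 2.0,
    caa_rule: CAARule | None = CAARule(),
) -> PlaqueSegmentation:
    """Threshold and label a projected image; drop small and CAA components.

    ``method="otsu"`` picks the threshold automatically (requires a
    non-constant image); ``method="fixed"`` uses ``fixed_threshold``.
    Components are 8-connected; those smaller than ``min_area_um2`` are
    removed, and those matching the CAA rule are removed and recorded in
    ``excluded_caa``.
    """
    projection = np.asarray(projection, dtype=float)
    if method == "otsu":
        if projection.max() == projection.min():
            raise ValueError(
                "constant image: Otsu threshold undefined; use method='fixed' with a threshold"
            )
        thr = float(threshold_otsu(projection))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    mask = projection > thr
    labels = measure.label(mask, connectivity=2)
    excluded: list[int] = []
    areas: list[float] = []
    nr, nc = labels.shape
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * pixel_area_um2
        if area_um2 < min_area_um2:
            labels[labels == prop.label] = 0
            continue
        if caa_rule is not None:
            r0, c0, r1, c1 = prop.bbox
            touches = r0 == 0 or c0 == 0 or r1 == nr or c1 == nc
            if (caa_rule.exclude_border and touches) or _elongation(prop) > caa_rule.max_elongation:
                excluded.append(prop.label)
                labels[labels == prop.label] = 0
                continue
        areas.append(area_um2)
    # relabel consecutively so label ids match the retained count
    labels = measure.label(labels > 0, connectivity=2)
    return PlaqueSegmentation(
        projection=projection,
        labels=labels,
        plaque_areas_um2=np.asarray(areas, dtype=float),
        excluded_caa=excluded,
        threshold=thr,
    )


def plaque_metrics(seg: PlaqueSegmentation, stack: PlaqueStack) -> PlaqueMetrics:
    """Count, density (count per mm^3 of imaged tissue), and burden (%).

    Density divides the projected count by the full physical stack volume
    (projected area x z extent); burden is the retained foreground fraction
    of the projection in percent.
    """
    if seg.projection.shape != stack.volume.shape[1:]:
        raise ValueError("segmentation does not match the stack's in-plane shape")
    vol = stack.volume_mm3
    if vol <= 0:
        raise ValueError("zero physical volume")
    count = int(seg.labels.max())
    burden = float((seg.labels > 0).sum() / seg.labels.size * 100.0)
    return PlaqueMetrics(
        count=count,
        density_per_mm3=count / vol,
        burden_pct=burden,
        volume_mm3=vol,
    )


def longitudinal_change(m1: PlaqueMetrics, m2: PlaqueMetrics) -> LongitudinalPair:
    """Percentage change in count and burden between two sessions, (m2-m1)/m1*100.

    Count change is computed on the per-mm^3 density so that sessions with
    slightly different imaged depths remain comparable; for equal volumes it
    coincides with the raw count change.  A zero baseline yields NaN.
    """

    def _pct(a: float, b: float) -> float:
        if a == 0:
            return float("nan")
        return (b - a) / a * 100.0

    return LongitudinalPair(
        metrics_1=m1,
        metrics_2=m2,
        pct_change_count=_pct(m1.density_per_mm3, m2.density_per_mm3),
        pct_change_burden=_pct(m1.burden_pct, m2.burden_pct),
    )


def register_offset(reference: np.ndarray, moving: np.ndarray) -> tuple[int, int]:
    """Rigid integer-pixel offset of ``moving`` relative to ``reference``.

    Cross-correlation based; returns the (row, col) displacement of the
    moving image's content relative to the reference (apply the negated
    offset to align it back).  Sub-pixel registration and rotation are out of
    scope — the same field is assumed re-imaged.
    """
    shift, _, _ = phase_cross_correlation(
        np.asarray(reference, dtype=float), np.asarray(moving, dtype=float), upsample_factor=1
    )
    return int(round(-shift[0])), int(round(-shift[1]))
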