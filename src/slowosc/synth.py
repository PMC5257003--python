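"""Ground-truthed synthetic data generators.

Three forward models produce the inputs the analysis modules consume, each
with a ground-truth record of its generating parameters:

* VSD movies — wide-field frames in which each 1-mm tile of cortex follows an
  up/down-state slow oscillation (a sigmoid-edged square wave, mirroring the
  bistable depolarized/hyperpolarized membrane states) with a tile-specific
  phase.  Phase dispersion across tiles models the desynchronization seen in
  amyloid-depositing cortex; an optional optogenetic-style pulse train
  phase-locks every tile to the stimulus while it is on.
* Two-channel calcium stacks — neurite-shaped masks whose YFP/CFP ratio is
  forward-generated from a specified [Ca2+] via the Hill calibration, over a
  constant background, with the last z-slice left background-only so the
  preprocessing assumption (background = mode of the last slice) holds by
  construction.
* Plaque volumes — Poisson-placed bright Gaussian blobs at a requested
  density per mm^3, optionally with a bright superficial band mimicking
  vascular (CAA) amyloid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.special import expit

from .calcium import CalibrationParams, DEFAULT_CALIBRATION, RatiometricStack, calcium_to_ratio
from .vsd import VSDMovie

__all__ = [
    "VSDSimParams",
    "StimulusTrain",
    "CalciumSimParams",
    "PlaqueSimParams",
    "VSDGroundTruth",
    "CalciumGroundTruth",
    "PlaqueGroundTruth",
    "generate_vsd_movie",
    "generate_calcium_stack",
    "generate_plaque_volume",
]

# Edge softness of the up/down waveform, as a fraction of the sine argument;
# small values sharpen the state transitions (more harmonic content, all of
# it above the fundamental).
_EDGE_SOFTNESS = 0.15
# Rise/fall time constant (s) of the stimulated up state at pulse edges.
_PULSE_TAU_S = 0.02


@dataclass(frozen=True)
class StimulusTrain:
    """A periodic light-pulse train (onset/offset window, rate, pulse width)."""

    rate_hz: float = 1.2
    pulse_width_s: float = 0.4
    onset_s: float = 0.0
    offset_s: float = math.inf

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not (0 < self.pulse_width_s < 1.0 / self.rate_hz):
            raise ValueError("pulse_width_s must be positive and shorter than one period")
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")


@dataclass(frozen=True)
class VSDSimParams:
    """Parameters of the synthetic slow-oscillation movie.

    Defaults follow the recording conditions the analyses assume: a 3x3 mm
    field imaged every 50 ms in 50-s epochs, oscillating at 0.6 Hz.  The
    oscillation amplitude is expressed as a fractional fluorescence change
    (dF/F); its default of 0.05 is a generator choice, not a measured value.
    """

    field_size_mm: tuple[float, float] = (3.0, 3.0)
    pixel_size_mm: float = 0.1
    frame_interval_s: float = 0.05
    duration_s: float = 50.0
    osc_frequency_hz: float = 0.6
    osc_amplitude: float = 0.05
    baseline_intensity: float = 1000.0
    noise_sd: float = 0.0
    tile_phase_jitter_rad: float = 0.0
    wave_speed_mm_s: float = 0.0
    tile_mm: float = 1.0
    waveform: str = "updown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        nyquist = 1.0 / (2.0 * self.frame_interval_s)
        if self.osc_frequency_hz >= nyquist:
            raise ValueError(
                f"osc_frequency_hz={self.osc_frequency_hz} Hz is at or above the Nyquist "
                f"frequency {nyquist} Hz for a {self.frame_interval_s*1e3:.0f} ms frame interval"
            )
        if self.osc_frequency_hz <= 0:
            raise ValueError("osc_frequency_hz must be positive")
        if self.tile_phase_jitter_rad < 0:
            raise ValueError("tile_phase_jitter_rad must be >= 0")
        if self.osc_amplitude < 0:
            raise ValueError("osc_amplitude must be >= 0")
        if self.pixel_size_mm <= 0 or min(self.field_size_mm) <= 0:
            raise ValueError("field and pixel sizes must be positive")
        if self.waveform not in ("updown", "sine"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.frame_interval_s)


@dataclass
class VSDGroundTruth:
    """Generating frequency, per-tile phases, and stimulation window."""

    osc_frequency_hz: float
    osc_amplitude: float
    tile_phases_rad: np.ndarray
    tile_px: int
    stim_rate_hz: float | None = None
    stim_window_s: tuple[float, float] | None = None


def _updown(theta: np.ndarray) -> np.ndarray:
    """Sigmoid-edged square wave in [-1, 1]: up and down states with fast transitions."""
    return np.tanh(np.sin(theta) / _EDGE_SOFTNESS)


def generate_vsd_movie(
    params: VSDSimParams,
    stim: StimulusTrain | None = None,
) -> tuple[VSDMovie, VSDGroundTruth]:
    """Synthesize a slow-oscillation VSD movie, optionally entrained to a pulse train.

    Unstimulated frames follow F(t) = B * (1 + a * w(2*pi*f*t + phi_tile)),
    where w is the up/down waveform and phi_tile a per-tile phase drawn with
    dispersion ``tile_phase_jitter_rad`` (von Mises, kappa = 1/jitter^2).
    While a stimulus is on, every pixel is phase-locked to the pulse train:
    an up state lasting the pulse width at each pulse onset.  Gaussian noise
    of sd ``noise_sd`` is added to every pixel.
    """
    if stim is not None and stim.rate_hz >= params.nyquist_hz:
        raise ValueError(
            f"stimulus rate {stim.rate_hz} Hz is at or above the Nyquist frequency "
            f"{params.nyquist_hz} Hz"
        )
    rng = np.random.default_rng(params.seed)
    n_rows = int(round(params.field_size_mm[0] / params.pixel_size_mm))
    n_cols = int(round(params.field_size_mm[1] / params.pixel_size_mm))
    n_frames = int(round(params.duration_s / params.frame_interval_s))
    t = np.arange(n_frames) * params.frame_interval_s

    tile_px = max(1, int(round(params.tile_mm / params.pixel_size_mm)))
    n_tr = math.ceil(n_rows / tile_px)
    n_tc = math.ceil(n_cols / tile_px)
    if params.tile_phase_jitter_rad == 0:
        tile_phases = np.zeros((n_tr, n_tc))
    else:
        kappa = 1.0 / params.tile_phase_jitter_rad**2
        tile_phases = rng.vonmises(0.0, kappa, size=(n_tr, n_tc))

    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    phase_map = tile_phases[rows[:, None] // tile_px, cols[None, :] // tile_px]
    if params.wave_speed_mm_s > 0:
        # travelling wave along columns: phase lag proportional to distance
        lag = 2.0 * math.pi * params.osc_frequency_hz * (
            cols * params.pixel_size_mm / params.wave_speed_mm_s
        )
        phase_map = phase_map + lag[None, :]

    wave_fn = _updown if params.waveform == "updown" else np.sin
    theta = (
        2.0 * math.pi * params.osc_frequency_hz * t[:, None, None]
        + phase_map[None, :, :]
    )
    w = wave_fn(theta)

    if stim is not None:
        in_stim = (t >= stim.onset_s) & (t < stim.offset_s)
        if in_stim.any():
            s = np.mod(t[in_stim] - stim.onset_s, 1.0 / stim.rate_hz)
            up = expit(s / _PULSE_TAU_S) * expit((stim.pulse_width_s - s) / _PULSE_TAU_S)
            w[in_stim] = (2.0 * up - 1.0)[:, None, None]

    frames = params.baseline_intensity * (1.0 + params.osc_amplitude * w)
    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, size=frames.shape)

    movie = VSDMovie(
        frames=frames,
        frame_interval_s=params.frame_interval_s,
        pixel_size_mm=params.pixel_size_mm,
        meta={"synthetic": True, "seed": params.seed},
    )
    truth = VSDGroundTruth(
        osc_frequency_hz=params.osc_frequency_hz,
        osc_amplitude=params.osc_amplitude,
        tile_phases_rad=tile_phases,
        tile_px=tile_px,
        stim_rate_hz=None if stim is None else stim.rate_hz,
        stim_window_s=None if stim is None else (stim.onset_s, min(stim.offset_s, params.duration_s)),
    )
    return movie, truth


@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the synthetic two-channel (CFP/YFP) neurite stack."""

    n_neurites: int = 20
    ca_levels_nM: tuple[float, ...] = ()
    calibration: CalibrationParams = DEFAULT_CALIBRATION
    stack_shape: tuple[int, int, int] = (8, 96, 96)
    z_step_um: float = 2.0
    pixel_size_um: float = 0.5
    photon_noise_scale: float = 0.0
    background_level: float = 100.0
    cfp_level: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurites < 0:
            raise ValueError("n_neurites must be >= 0")
        if self.ca_levels_nM and len(self.ca_levels_nM) != self.n_neurites:
            raise ValueError("ca_levels_nM must have one entry per neurite")
        if any(c < 0 for c in self.ca_levels_nM):
            raise ValueError("ca_levels_nM must be non-negative")
        if self.stack_shape[0] < 2:
            raise ValueError("need >= 2 z-slices (last slice is background-only)")
        if self.background_level < 0 or self.cfp_level <= 0:
            raise ValueError("background_level must be >= 0 and cfp_level > 0")


@dataclass
class CalciumGroundTruth:
    """Per-neurite true [Ca2+], true ratios, and the label volume."""

    ca_levels_nM: np.ndarray
    true_ratios: np.ndarray
    labels: np.ndarray
    background_level: float


def _draw_neurite_mask(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    existing: np.ndarray,
) -> np.ndarray | None:
    """One neurite: a ~3-px-thick line segment within a single z-slice.

    Thickness is isotropic (disk dilation of the line) so a radius-2 median
    filter preserves the core regardless of orientation.  A 4-px exclusion
    margin keeps median-filter windows of different neurites disjoint.
    Returns a boolean volume mask, or None if no free spot was found.  The
    last z-slice is never touched (reserved for background).
    """
    from scipy import ndimage as _ndi

    nz, nr, nc = shape
    for _ in range(80):
        z = int(rng.integers(0, nz - 1))
        r0, c0 = rng.integers(6, nr - 6), rng.integers(6, nc - 6)
        angle = rng.uniform(0, math.pi)
        length = int(rng.integers(14, 28))
        rr = (r0 + np.arange(length) * math.sin(angle)).astype(int)
        cc = (c0 + np.arange(length) * math.cos(angle)).astype(int)
        keep = (rr >= 3) & (rr < nr - 3) & (cc >= 3) & (cc < nc - 3)
        rr, cc = rr[keep], cc[keep]
        if rr.size < 8:
            continue
        line = np.zeros((nr, nc), dtype=bool)
        line[rr, cc] = True
        body = _ndi.binary_dilation(line, iterations=1)  # ~3 px thick
        margin = _ndi.binary_dilation(body, iterations=4)
        if (existing[z] & margin).any():
            continue
        mask = np.zeros(shape, dtype=bool)
        mask[z] = body
        return mask
    return None


def generate_calcium_stack(
    params: CalciumSimParams,
) -> tuple[RatiometricStack, CalciumGroundTruth]:
    """Forward-generate a two-channel stack from specified [Ca2+] levels.

    Within each neurite mask, CFP is constant and YFP = ratio * CFP where the
    ratio is the Hill-forward image of the neurite's true [Ca2+]; therefore
    mean(YFP)/mean(CFP) over the mask equals that ratio exactly before noise.
    A constant background is added to both channels, and the last z-slice
    contains background only.  Noise, when enabled, is Gaussian with sd
    proportional to sqrt(signal) (photon-like).
    """
    calib = params.calibration
    if params.ca_levels_nM:
        ca = np.asarray(params.ca_levels_nM, dtype=float)
    else:
        rng0 = np.random.default_rng(params.seed)
        ca = rng0.uniform(50.0, 200.0, size=params.n_neurites)
    ratios = np.asarray([calcium_to_ratio(c, calib) for c in ca])
    if np.any(ratios >= calib.rmax):
        raise ValueError("a requested [Ca2+] maps to a ratio >= rmax (unreachable ratio)")

    rng = np.random.default_rng(params.seed)
    labels = np.zeros(params.stack_shape, dtype=np.int32)
    occupied = np.zeros(params.stack_shape, dtype=bool)
    placed = 0
    for i in range(params.n_neurites):
        mask = _draw_neurite_mask(rng, params.stack_shape, occupied)
        if mask is None:
            raise ValueError(
                f"could not place neurite {i + 1} of {params.n_neurites}; stack too crowded"
            )
        labels[mask] = i + 1
        occupied |= mask
        placed += 1

    cfp = np.zeros(params.stack_shape)
    yfp = np.zeros(params.stack_shape)
    for i in range(placed):
        m = labels == i + 1
        cfp[m] = params.cfp_level
        yfp[m] = params.cfp_level * ratios[i]
    cfp += params.background_level
    yfp += params.background_level

    if params.photon_noise_scale > 0:
        cfp = cfp + rng.normal(0.0, params.photon_noise_scale * np.sqrt(cfp))
        yfp = yfp + rng.normal(0.0, params.photon_noise_scale * np.sqrt(yfp))

    stack = RatiometricStack(
        cfp=cfp,
        yfp=yfp,
        z_step_um=params.z_step_um,
        pixel_size_um=params.pixel_size_um,
        meta={"synthetic": True, "seed": params.seed},
    )
    truth = CalciumGroundTruth(
        ca_levels_nM=ca,
        true_ratios=ratios,
        labels=labels,
        background_level=params.background_level,
    )
    return stack, truth


@dataclass(frozen=True)
class PlaqueSimParams:
    """Parameters of the synthetic amyloid plaque volume."""

    volume_shape: tuple[int, int, int] = (40, 256, 256)
    voxel_size_um: tuple[float, float, float] = (5.0, 2.0, 2.0)
    density_per_mm3: float = 48.3
    radius_range_um: tuple[float, float] = (5.0, 10.0)
    intensity_range: tuple[float, float] = (400.0, 800.0)
    background_level: float = 20.0
    noise_sd: float = 0.0
    caa_rim: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_mm3 < 0:
            raise ValueError("density_per_mm3 must be >= 0")
        lo, hi = self.radius_range_um
        extent = [n * v for n, v in zip(self.volume_shape, self.voxel_size_um)]
        if lo <= 0 or hi < lo or hi >= min(extent) / 2:
            raise ValueError("radii must be positive and smaller than the volume")

    @property
    def volume_mm3(self) -> float:
        nz, nr, nc = self.volume_shape
        vz, vr, vc = self.voxel_size_um
        return nz * vz * nr * vr * nc * vc * 1e-9


@dataclass
class PlaqueGroundTruth:
    """True plaque centers (voxel coordinates), radii (um), and count."""

    centers_vox: np.ndarray
    radii_um: np.ndarray
    intensities: np.ndarray
    count: int
    caa_mask: np.ndarray | None = None


def generate_plaque_volume(
    params: PlaqueSimParams,
) -> tuple[np.ndarray, PlaqueGroundTruth]:
    """Poisson-placed bright Gaussian blobs on a dark background.

    The plaque count is drawn Poisson(density x physical volume in mm^3) and
    centers are uniform over the volume.  Each plaque is an isotropic (in
    physical units) Gaussian profile with sigma = radius / 2.  With
    ``caa_rim``, a bright band along the first image rows of the top z-slices
    mimics superficial vascular amyloid; it touches the image border in the
    maximum projection, matching the exclusion rule used downstream.
    """
    lam = params.density_per_mm3 * params.volume_mm3
    mean_r = np.mean(params.radius_range_um)
    packing = lam * (4.0 / 3.0) * math.pi * mean_r**3 * 1e-9 / params.volume_mm3
    if packing > 0.3:
        raise ValueError(
            f"expected plaque volume fraction {packing:.2f} exceeds the packing bound (0.3); "
            "lower the density or radii"
        )
    rng = np.random.default_rng(params.seed)
    count = int(rng.poisson(lam))
    nz, nr, nc = params.volume_shape
    vz, vr, vc = params.voxel_size_um
    centers = np.column_stack(
        [rng.uniform(0, nz, count), rng.uniform(0, nr, count), rng.uniform(0, nc, count)]
    )
    radii = rng.uniform(*params.radius_range_um, size=count)
    intensities = rng.uniform(*params.intensity_range, size=count)

    volume = np.full(params.volume_shape, params.background_level, dtype=float)
    for (cz, cr, cc), rad, amp in zip(centers, radii, intensities):
        sig = rad / 2.0
        # render within +-3 sigma, in voxel units per axis
        ez, er, ec = (3 * sig / vz, 3 * sig / vr, 3 * sig / vc)
        z0, z1 = max(0, int(cz - ez)), min(nz, int(cz + ez) + 2)
        r0, r1 = max(0, int(cr - er)), min(nr, int(cr + er) + 2)
        c0, c1 = max(0, int(cc - ec)), min(nc, int(cc + ec) + 2)
        if z0 >= z1 or r0 >= r1 or c0 >= c1:
            continue
        zz = (np.arange(z0, z1) - cz) * vz
        rr = (np.arange(r0, r1) - cr) * vr
        ccv = (np.arange(c0, c1) - cc) * vc
        d2 = (
            zz[:, None, None] ** 2 + rr[None, :, None] ** 2 + ccv[None, None, :] ** 2
        )
        volume[z0:z1, r0:r1, c0:c1] += amp * np.exp(-d2 / (2.0 * sig**2))

    caa_mask = None
    if params.caa_rim:
        caa_mask = np.zeros(params.volume_shape, dtype=bool)
        band_rows = max(3, nr // 20)
        top_slices = max(1, nz // 8)
        caa_mask[:top_slices, :band_rows, :] = True
        volume[caa_mask] += params.intensity_range[1]

    if params.noise_sd > 0:
        volume = volume + rng.normal(0.0, params.noise_sd, size=volume.shape)

    truth = PlaqueGroundTruth(
        centers_vox=centers,
        radii_um=radii,
        intensities=intensities,
        count=count,
        caa_mask=caa_mask,
    )
    return volume, truth
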