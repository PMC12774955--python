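"""System geometry, scan planning, coded surfaces, and the source model.

The imaging geometry is an on-chip lensless stack: sample at a distance
``d1`` (0.2–2 mm) above a known random amplitude/phase modulator (the coded
surface), which sits a fixed ``d2`` (0.84 mm by default) above the pixel
array.  The illumination comes from a quasi-point source roughly 20 cm away;
partial spatial coherence of an LED die is modelled as a set of mutually
incoherent point-source states, each of which shifts the detector-plane
pattern by ``offset · (d1 + d2) / source_distance`` (shadow magnification of
the emitter).  During acquisition the sensor assembly — coded surface
included — steps laterally on a jittered grid with micrometre-scale steps,
which in the object frame is equivalent to shifting the object wavefield
before the coded surface.

Pixel pitch has no hardware-derived default here; tests and examples use
1.85 µm as a typical back-illuminated CMOS pitch (an assumption, documented
in the methods note, not a measured value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .gridfield import Grid

__all__ = [
    "SystemGeometry",
    "ScanPlan",
    "CodedSurface",
    "SourceModel",
    "make_scan_plan",
    "make_coded_surface",
    "make_source_model",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SystemGeometry:
    """Axial distances (µm) and the virtual-state perturbation factor.

    d1: sample to coded surface (valid 200–2000 µm in the physical device,
        not enforced so simulations can explore);
    d2: coded surface to pixel array (default 840 µm);
    a:  multiplier applied to d2 in the virtual error-bin path (default 1.1);
    source_distance: source to sample (default 2e5 µm = 20 cm folded path).
    """

    d1: float
    d2: float = 840.0
    a: float = 1.1
    source_distance: float = 200_000.0

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValidationError("d1 and d2 must be positive")
        if self.a <= 0:
            raise ValidationError("virtual-state factor a must be positive")
        if self.source_distance <= 0:
            raise ValidationError("source_distance must be positive")

    @property
    def source_blur_factor(self) -> float:
        """Detector shift per unit emitter offset: (d1 + d2) / source_distance."""
        return (self.d1 + self.d2) / self.source_distance


@dataclass(frozen=True)
class ScanPlan:
    """Ordered lateral shifts (x_i, y_i) in µm, relative to the first position."""

    positions: np.ndarray
    seed: int
    step_min: float
    step_max: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 4:
            raise ValidationError("a scan plan needs at least 4 (x, y) positions")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]


@dataclass
class CodedSurface:
    """Known complex transmission of the coded modulator, amplitude in [0, 1]."""

    grid: Grid
    values: np.ndarray
    label: str = "object_path"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValidationError("coded-surface values do not match the grid")
        amp = np.abs(self.values)
        if amp.max() > 1.0 + 1e-9 or not np.all(np.isfinite(amp)):
            raise ValidationError("coded-surface amplitude must lie in [0, 1]")
        if self.label not in ("object_path", "virtual_path"):
            raise ValidationError("label must be 'object_path' or 'virtual_path'")

    def copy(self, label: str | None = None) -> "CodedSurface":
        return CodedSurface(self.grid, self.values.copy(), label or self.label)


@dataclass(frozen=True)
class SourceModel:
    """Incoherent decomposition of the source.

    states: (n, 3) array of (offset_x_um, offset_y_um, weight) on the emitter
    plane; spectrum: (m, 2) array of (wavelength_nm, weight).  Both weight
    sets are normalised to sum to one at construction.
    """

    states: np.ndarray
    spectrum: np.ndarray

    def __post_init__(self) -> None:
        st = np.atleast_2d(np.asarray(self.states, dtype=float))
        sp = np.atleast_2d(np.asarray(self.spectrum, dtype=float))
        if st.shape[0] < 1 or st.shape[1] != 3:
            raise ValidationError("need at least one (ox, oy, w) source state")
        if sp.shape[0] < 1 or sp.shape[1] != 2:
            raise ValidationError("need at least one (wavelength, w) spectral sample")
        if np.any(st[:, 2] < 0) or np.any(sp[:, 1] < 0):
            raise ValidationError("weights must be non-negative")
        if st[:, 2].sum() <= 0 or sp[:, 1].sum() <= 0:
            raise ValidationError("weights must not all be zero")
        st = st.copy()
        sp = sp.copy()
        st[:, 2] /= st[:, 2].sum()
        sp[:, 1] /= sp[:, 1].sum()
        object.__setattr__(self, "states", st)
        object.__setattr__(self, "spectrum", sp)

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_spectral(self) -> int:
        return self.spectrum.shape[0]

    @property
    def is_coherent(self) -> bool:
        return (
            self.n_states == 1
            and self.n_spectral == 1
            and np.allclose(self.states[0, :2], 0.0)
        )

    def detector_offsets_um(self, geometry: SystemGeometry) -> np.ndarray:
        """Per-state detector-plane (x, y) shifts via the geometric blur rule."""
        return self.states[:, :2] * geometry.source_blur_factor


def make_scan_plan(n_side: int, step_min: float, step_max: float, seed: int) -> ScanPlan:
    """Jittered n_side × n_side grid of sensor shifts.

    The scan walks row by row; every move along a row and every move to the
    next row draws its length uniformly from [step_min, step_max], so
    consecutive nearest-neighbour spacings stay inside the configured range.
    Positions are returned relative to the first position and are bit-exactly
    reproducible from the seed.
    """
    if n_side < 2:
        raise ValidationError("n_side must be at least 2")
    if step_min <= 0 or step_max < step_min:
        raise ValidationError("need 0 < step_min <= step_max")
    rng = np.random.default_rng(seed)
    row_steps = rng.uniform(step_min, step_max, size=n_side - 1)
    ys = np.concatenate([[0.0], np.cumsum(row_steps)])
    positions = np.empty((n_side * n_side, 2), dtype=float)
    for i in range(n_side):
        col_steps = rng.uniform(step_min, step_max, size=n_side - 1)
        xs = np.concatenate([[0.0], np.cumsum(col_steps)])
        positions[i * n_side : (i + 1) * n_side, 0] = xs
        positions[i * n_side : (i + 1) * n_side, 1] = ys[i]
    positions -= positions[0]
    return ScanPlan(positions=positions, seed=seed, step_min=step_min, step_max=step_max)


def make_coded_surface(
    grid: Grid,
    seed: int,
    feature_size: float | None = None,
    amp_range: tuple[float, float] = (0.3, 1.0),
    phase_range: float = 2.0 * np.pi,
) -> CodedSurface:
    """Random amplitude/phase modulator, spatially correlated at feature_size.

    Amplitude and phase are independent white-noise fields low-pass filtered
    to an autocorrelation FWHM of ``feature_size`` (µm, default 4 pixels),
    then affinely rescaled so the amplitude spans exactly ``amp_range`` and
    the phase spans ``phase_range`` radians centred on zero.
    """
    if feature_size is None:
        feature_size = 4.0 * grid.pitch
    if feature_size < grid.pitch:
        raise ValidationError("feature_size must be at least one pixel pitch")
    lo, hi = amp_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError("amp_range must satisfy 0 <= lo <= hi <= 1")
    if phase_range < 0:
        raise ValidationError("phase_range must be non-negative")
    rng = np.random.default_rng(seed)
    # Gaussian-filtered white noise has a Gaussian autocorrelation of width
    # sigma*sqrt(2); choose sigma so the autocorrelation FWHM equals the
    # requested feature size.
    sigma_px = (feature_size / grid.pitch) / (2.0 * np.sqrt(np.log(2.0)) * np.sqrt(2.0))

    def correlated_noise() -> np.ndarray:
        noise = rng.standard_normal(grid.shape)
        sm = ndimage.gaussian_filter(noise, sigma_px, mode="wrap")
        span = sm.max() - sm.min()
        return (sm - sm.min()) / span if span > 0 else np.zeros_like(sm)

    amp = lo + (hi - lo) * correlated_noise() if hi > lo else np.full(grid.shape, hi)
    if phase_range > 0:
        phase = (correlated_noise() - 0.5) * phase_range
    else:
        phase = np.zeros(grid.shape)
    return CodedSurface(grid, amp * np.exp(1j * phase), "object_path")


def _disc_states(radius: float, n_states: int) -> np.ndarray:
    """Equal-weight sunflower sampling of a disc, re-centred to zero centroid."""
    k = np.arange(n_states)
    r = radius * np.sqrt((k + 0.5) / n_states)
    th = k * _GOLDEN_ANGLE
    pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    pts -= pts.mean(axis=0)
    return pts


def make_source_model(
    shape: str = "point",
    n_states: int = 1,
    bandwidth_fwhm: float = 0.0,
    n_spectral: int = 1,
    center_wavelength: float = 266.0,
    seed: int = 0,
    radius: float | None = None,
    mask: np.ndarray | None = None,
    mask_pitch: float | None = None,
) -> SourceModel:
    """Build an incoherent source decomposition.

    shape "point": a single on-axis state regardless of n_states > 1 request
    is not silently honoured — "point" requires n_states == 1.  shape "disc"
    samples an emitter disc of the given radius (µm) with equal-area
    weighting; shape "mask" draws states from a non-negative emitter image
    (pixel pitch ``mask_pitch`` µm).  Spectral samples cover ±FWHM around the
    centre wavelength with Gaussian weights; n_spectral == 1 with a point
    shape is the fully coherent laser-diode model.
    """
    if n_states < 1 or n_spectral < 1:
        raise ValidationError("n_states and n_spectral must be >= 1")
    if shape == "point":
        if n_states != 1:
            raise ValidationError("a point source has exactly one state")
        states = np.array([[0.0, 0.0, 1.0]])
    elif shape == "disc":
        if radius is None or radius <= 0:
            raise ValidationError("disc shape requires a positive radius")
        if n_states == 1:
            states = np.array([[0.0, 0.0, 1.0]])
        else:
            pts = _disc_states(radius, n_states)
            states = np.column_stack([pts, np.full(n_states, 1.0 / n_states)])
    elif shape == "mask":
        if mask is None or mask_pitch is None:
            raise ValidationError("mask shape requires a mask array and mask_pitch")
        m = np.asarray(mask, dtype=float)
        if m.ndim != 2 or np.any(m < 0) or m.sum() <= 0:
            raise ValidationError("mask must be a non-negative 2-D image with signal")
        rng = np.random.default_rng(seed)
        p = (m / m.sum()).ravel()
        idx = rng.choice(m.size, size=n_states, replace=True, p=p)
        yy, xx = np.unravel_index(idx, m.shape)
        ox = (xx - m.shape[1] // 2) * mask_pitch
        oy = (yy - m.shape[0] // 2) * mask_pitch
        states = np.column_stack([ox, oy, np.full(n_states, 1.0 / n_states)])
    else:
        raise ValidationError(f"unknown source shape {shape!r}")

    if n_spectral == 1 or bandwidth_fwhm <= 0:
        spectrum = np.array([[center_wavelength, 1.0]])
    else:
        offsets = np.linspace(-bandwidth_fwhm, bandwidth_fwhm, n_spectral)
        w = np.exp(-4.0 * np.log(2.0) * (offsets / bandwidth_fwhm) ** 2)
        spectrum = np.column_stack([center_wavelength + offsets, w])
    return SourceModel(states=states, spectrum=spectrum)
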