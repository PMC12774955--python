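"""Ground-truth cell phantoms and the forward diffraction model.

The forward model follows the physics of the coded-sensor geometry: an exit
wavefield leaves the sample (decadic absorption from protein / nucleic-acid
areal amounts, phase from topographic height), propagates ``d1`` to the
coded-surface plane, is laterally shifted per scan position (the sensor
assembly moves; in the object frame the field shifts), multiplied by the
known coded surface, propagated ``d2`` to the pixel array, and detected as
intensity.  Partially coherent illumination is an incoherent sum: spectral
samples re-evaluate all wavelength-dependent phases, and spatial source
states shift the detector-plane intensity by the geometric blur rule
``offset · (d1 + d2) / source_distance``.

Controllable artifact injection (finite spectral bandwidth, a ghost
reflection, shot/read noise, position jitter) exists so that the virtual
error-bin reconstruction can be exercised against known, quantifiable model
mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np
import tifffile

from . import _fft
from .errors import ValidationError
from .gridfield import ComplexField, Grid, transfer_function
from .instrument import CodedSurface, ScanPlan, SourceModel, SystemGeometry
from .spectra import ExtinctionTable

__all__ = [
    "Phantom",
    "DiffractionDataset",
    "SimOptions",
    "make_cell_phantom",
    "sample_exit_field",
    "simulate_dataset",
    "save_dataset",
    "load_dataset",
    "export_dataset_tiff",
]

LABEL_BACKGROUND, LABEL_CYTOPLASM, LABEL_NUCLEUS = 0, 1, 2

#: default areal amount ranges (mol/µm²); with the default extinction table
#: these give nuclear OD(266) ≈ 0.4–0.7 and cytoplasmic OD(280) ≈ 0.2–0.4,
#: typical of thin unstained cell preparations in the deep UV.
DEFAULT_AMOUNT_RANGES = {
    "pro_cyto": (4.5e-17, 9.0e-17),
    "pro_nuc": (2.0e-17, 4.0e-17),
    "nuc_nuc": (5.0e-16, 8.5e-16),
    "nuc_cyto": (2.0e-17, 6.0e-17),
}


@dataclass
class Phantom:
    """Ground truth: per-pixel areal molar amounts, height, phase contrast.

    n_pro / n_nuc are areal molar densities (mol/µm², the identifiable
    concentration×path product); height is topographic height in µm; dn is a
    scalar refractive-index contrast used for the phase term; labels mark
    {0: background, 1: cytoplasm, 2: nucleus} and cell_labels give one
    integer id per cell (0 outside cells).
    """

    grid: Grid
    n_pro: np.ndarray
    n_nuc: np.ndarray
    height: np.ndarray
    dn: float
    labels: np.ndarray
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray

    def __post_init__(self) -> None:
        for name in ("n_pro", "n_nuc", "height", "labels", "cell_labels", "nucleus_labels"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValidationError(f"{name} shape does not match the grid")
        if self.n_pro.min() < 0 or self.n_nuc.min() < 0:
            raise ValidationError("areal amounts must be non-negative")
        bg = self.labels == LABEL_BACKGROUND
        if np.any(self.n_pro[bg] != 0) or np.any(self.n_nuc[bg] != 0):
            raise ValidationError("background pixels must carry zero amounts")

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())


@dataclass
class DiffractionDataset:
    """A stack of intensity frames with its scan plan and geometry."""

    frames: np.ndarray
    scan: ScanPlan
    geometry: SystemGeometry
    wavelength: float
    background_level: float = 1.0
    true_positions: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n_frames, ny, nx) stack")
        if self.frames.shape[0] != self.scan.n_positions:
            raise ValidationError("frame count must equal scan position count")
        if self.frames.min() < 0:
            raise ValidationError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class SimOptions:
    """Artifact and noise switches for the simulator.

    ghost_amplitude / ghost_extra_path_um model a weak coherent double
    reflection inside the sensor stack (default extra path 2·d2);
    photons_per_pixel sets the shot-noise budget at the background level
    (1e4 is a plausible ~0.1 s LED exposure — an assumption, not a measured
    value); position_jitter_um perturbs the true positions while the scan
    plan keeps the nominal ones.
    """

    background_level: float = 1.0
    ghost_reflection: bool = False
    ghost_amplitude: float = 0.1
    ghost_extra_path_um: float | None = None
    shot_noise: bool = False
    photons_per_pixel: float = 1.0e4
    read_noise_sigma: float = 0.0
    position_jitter_um: float = 0.0
    seed: int = 0


def _soft_ellipse(grid_shape, cy, cx, ry, rx, angle, edge_px=1.5) -> np.ndarray:
    """Smooth-edged ellipse profile in [0, 1] (1 inside, cosine roll-off)."""
    yy, xx = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = (c * x + s * y) / rx
    v = (-s * x + c * y) / ry
    rho = np.sqrt(u**2 + v**2)
    # roll-off over ~edge_px pixels at the boundary
    edge = edge_px / max(rx, ry)
    t = np.clip((1.0 - rho) / edge, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * t)


def make_cell_phantom(
    grid: Grid,
    n_cells: int,
    seed: int,
    amount_ranges: dict | None = None,
    cell_radius_um: tuple[float, float] = (14.0, 22.0),
    nucleus_fraction: tuple[float, float] = (0.45, 0.6),
    height_range_um: tuple[float, float] = (0.3, 1.2),
    dn: float = 0.005,
    nucleus_shape: str = "round",
    margin_px: int = 24,
    max_tries: int = 200,
) -> Phantom:
    """Scatter smooth elliptical cells with nucleic-acid-rich nuclei.

    Cells are non-overlapping ellipses with protein-rich cytoplasm and a
    nucleus whose shape is either "round" (one ellipse; mononuclear-like) or
    "lobed" (three overlapping lobes along an arc; polymorphonuclear-like).
    Deterministic per seed; ``n_cells = 0`` returns an empty background
    phantom.  Raises after ``max_tries`` failed placements per cell.
    """
    if n_cells < 0:
        raise ValidationError("n_cells must be non-negative")
    if nucleus_shape not in ("round", "lobed"):
        raise ValidationError("nucleus_shape must be 'round' or 'lobed'")
    ranges = dict(DEFAULT_AMOUNT_RANGES)
    if amount_ranges:
        ranges.update(amount_ranges)
    rng = np.random.default_rng(seed)
    ny, nx = grid.shape
    n_pro = np.zeros((ny, nx))
    n_nuc = np.zeros((ny, nx))
    height = np.zeros((ny, nx))
    cell_labels = np.zeros((ny, nx), dtype=np.int32)
    nucleus_labels = np.zeros((ny, nx), dtype=np.int32)

    placed = []  # (cy, cx, r_px)
    for cid in range(1, n_cells + 1):
        r_um = rng.uniform(*cell_radius_um)
        r_px = r_um / grid.pitch
        if margin_px + r_px >= ny - margin_px - r_px or margin_px + r_px >= nx - margin_px - r_px:
            raise ValidationError(
                f"cell of radius {r_px:.0f} px cannot fit inside the margins"
            )
        for attempt in range(max_tries):
            cy = rng.uniform(margin_px + r_px, ny - margin_px - r_px)
            cx = rng.uniform(margin_px + r_px, nx - margin_px - r_px)
            if cy <= margin_px or cx <= margin_px:
                continue
            if all(np.hypot(cy - py, cx - px) > 1.15 * (r_px + pr) for py, px, pr in placed):
                break
        else:
            raise ValidationError(
                f"could not place cell {cid} after {max_tries} tries; "
                "reduce n_cells or cell size"
            )
        placed.append((cy, cx, r_px))
        aspect = rng.uniform(0.75, 1.0)
        angle = rng.uniform(0, np.pi)
        cell = _soft_ellipse((ny, nx), cy, cx, r_px * aspect, r_px, angle)

        nf = rng.uniform(*nucleus_fraction)
        if nucleus_shape == "round":
            nuc = _soft_ellipse(
                (ny, nx), cy, cx, r_px * aspect * nf, r_px * nf, angle
            )
        else:
            # three overlapping lobes along an arc; the lobe spacing is
            # bounded so the joint support stays one connected, elongated
            # component whose roundness falls well below a disc's
            nuc = np.zeros((ny, nx))
            lobe_r = 0.32 * r_px
            off = 0.35 * r_px
            th = rng.uniform(0, 2 * np.pi)
            for k in range(3):
                if k > 0:
                    # spacing bounded so adjacent lobes always overlap but
                    # never collapse into one near-circular blob
                    th += rng.uniform(1.45, 1.75)
                nuc = np.maximum(
                    nuc,
                    _soft_ellipse(
                        (ny, nx),
                        cy + off * np.sin(th),
                        cx + off * np.cos(th),
                        lobe_r * rng.uniform(0.9, 1.0),
                        lobe_r,
                        rng.uniform(0, np.pi),
                    ),
                )
            nuc = nuc * cell  # keep lobes inside the cell body

        cyto = np.clip(cell - nuc, 0.0, 1.0)
        n_pro += rng.uniform(*ranges["pro_cyto"]) * cyto
        n_pro += rng.uniform(*ranges["pro_nuc"]) * nuc
        n_nuc += rng.uniform(*ranges["nuc_nuc"]) * nuc
        n_nuc += rng.uniform(*ranges["nuc_cyto"]) * cyto
        height += rng.uniform(*height_range_um) * cell
        cell_labels[cell > 0.5] = cid
        nucleus_labels[nuc > 0.5] = cid

    labels = np.zeros((ny, nx), dtype=np.int32)
    labels[cell_labels > 0] = LABEL_CYTOPLASM
    labels[nucleus_labels > 0] = LABEL_NUCLEUS
    support = labels != LABEL_BACKGROUND
    n_pro[~support] = 0.0
    n_nuc[~support] = 0.0
    return Phantom(
        grid=grid,
        n_pro=n_pro,
        n_nuc=n_nuc,
        height=height,
        dn=dn,
        labels=labels,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
    )


def sample_exit_field(
    phantom: Phantom,
    wavelength: float,
    eps: ExtinctionTable | None = None,
    phase_wavelength: float | None = None,
) -> ComplexField:
    """Exit wavefield just after the sample.

    Amplitude per pixel is ``10^(−OD/2)`` with OD = ε_λ^pro·n_pro +
    ε_λ^nuc·n_nuc (the half because Beer–Lambert is defined on intensity);
    phase is ``2π·dn·height/λ``.  Without an extinction table the field is
    phase-only (the 405-nm channel).  ``phase_wavelength`` lets a spectral
    sample re-evaluate the phase at a detuned wavelength while the amplitude
    keeps the tabulated centre-wavelength extinction.
    """
    if phantom.n_pro.min() < 0 or phantom.n_nuc.min() < 0:
        raise ValidationError("areal amounts must be non-negative")
    if eps is not None:
        lam_key = int(round(wavelength))
        if lam_key not in eps.eps:
            raise ValidationError(
                f"wavelength {wavelength} nm not in the extinction table; "
                "omit eps for phase-only imaging"
            )
        od = eps.od(phantom.n_pro, phantom.n_nuc, lam_key)
        amplitude = np.power(10.0, -od / 2.0)
    else:
        amplitude = np.ones(phantom.grid.shape)
    lam_um = (phase_wavelength if phase_wavelength is not None else wavelength) * 1e-3
    phase = 2.0 * np.pi * phantom.dn * phantom.height / lam_um
    grid = Grid(phantom.grid.nx, phantom.grid.ny, phantom.grid.pitch, wavelength)
    return ComplexField(grid, amplitude * np.exp(1j * phase), "sample")


def simulate_dataset(
    phantom: Phantom,
    geometry: SystemGeometry,
    scan: ScanPlan,
    source: SourceModel,
    cs: CodedSurface,
    eps: ExtinctionTable | None = None,
    options: SimOptions | None = None,
) -> DiffractionDataset:
    """Run the exact forward model for every scan position.

    Per spectral sample the exit field and both propagations are recomputed
    at the detuned wavelength (finite temporal bandwidth is a genuine model
    mismatch, not an intensity blur); per spatial source state the summed
    detector intensity is shifted by the geometric blur rule.  The simulation
    always uses the true object-path model only — the virtual-state factor
    ``a`` plays no role here.
    """
    opts = options or SimOptions()
    rng = np.random.default_rng(opts.seed)
    n_det_y, n_det_x = cs.grid.shape
    if phantom.grid.ny < n_det_y or phantom.grid.nx < n_det_x:
        raise ValidationError("phantom grid must be at least the coded-surface grid")
    if abs(phantom.grid.pitch - cs.grid.pitch) > 1e-12:
        raise ValidationError("phantom and coded-surface pitch must match")
    wavelength = float(source.spectrum[source.spectrum[:, 1].argmax(), 0])

    positions = scan.positions
    true_positions = positions.copy()
    if opts.position_jitter_um > 0:
        true_positions = positions + rng.uniform(
            -opts.position_jitter_um, opts.position_jitter_um, size=positions.shape
        )
        true_positions[0] = positions[0]

    ghost_path = opts.ghost_extra_path_um
    if ghost_path is None:
        ghost_path = 2.0 * geometry.d2

    offsets_um = source.detector_offsets_um(geometry)
    weights = source.states[:, 2]
    on_axis = source.n_states == 1 and np.allclose(offsets_um, 0.0)
    state_ramps = None
    if not on_axis:
        state_ramps = [
            _fft.shift_ramp((n_det_y, n_det_x), oy / cs.grid.pitch, ox / cs.grid.pitch)
            for ox, oy in offsets_um
        ]

    frames = np.zeros((scan.n_positions, n_det_y, n_det_x))
    for lam_k, w_k in source.spectrum:
        exit_field = sample_exit_field(phantom, wavelength, eps, phase_wavelength=lam_k)
        lam_grid = Grid(phantom.grid.nx, phantom.grid.ny, phantom.grid.pitch, lam_k)
        master = transfer_function(lam_grid, geometry.d1)
        master_hat = _fft.fft2(exit_field.values) * master
        det_grid = Grid(n_det_x, n_det_y, cs.grid.pitch, lam_k)
        h2 = transfer_function(det_grid, geometry.d2)
        h_ghost = transfer_function(det_grid, ghost_path) if opts.ghost_reflection else None
        for i, (x_um, y_um) in enumerate(true_positions):
            dy = y_um / phantom.grid.pitch
            dx = x_um / phantom.grid.pitch
            shifted = _fft.ifft2(master_hat * _fft.shift_ramp(phantom.grid.shape, dy, dx))
            e_i = _fft.crop_center(shifted, n_det_y, n_det_x)
            psi = _fft.ifft2(_fft.fft2(e_i * cs.values) * h2)
            if h_ghost is not None:
                psi = psi + opts.ghost_amplitude * _fft.ifft2(_fft.fft2(psi) * h_ghost)
            if on_axis:
                frames[i] += w_k * np.abs(psi) ** 2
            else:
                # geometric source blur: each incoherent state is the same
                # detector wavefield displaced by its magnified emitter
                # offset, so every per-state intensity is an exact shift
                psi_hat = _fft.fft2(psi)
                for ramp, w_s in zip(state_ramps, weights):
                    frames[i] += (w_k * w_s) * np.abs(_fft.ifft2(psi_hat * ramp)) ** 2

    frames = frames * opts.background_level
    clipped_fraction = 0.0
    if opts.shot_noise:
        scale = opts.photons_per_pixel / max(opts.background_level, 1e-300)
        frames = rng.poisson(np.clip(frames * scale, 0, None)).astype(float) / scale
    if opts.read_noise_sigma > 0:
        frames = frames + rng.normal(0.0, opts.read_noise_sigma, size=frames.shape)
        clipped_fraction = float((frames < 0).mean())
        frames = np.clip(frames, 0.0, None)

    return DiffractionDataset(
        frames=frames,
        scan=scan,
        geometry=geometry,
        wavelength=wavelength,
        background_level=opts.background_level,
        true_positions=true_positions if opts.position_jitter_um > 0 else None,
        meta={
            "clipped_fraction": clipped_fraction,
            "n_spectral": source.n_spectral,
            "n_source_states": source.n_states,
            "options": {
                "ghost_reflection": opts.ghost_reflection,
                "ghost_amplitude": opts.ghost_amplitude,
                "ghost_extra_path_um": ghost_path,
                "shot_noise": opts.shot_noise,
                "photons_per_pixel": opts.photons_per_pixel,
                "read_noise_sigma": opts.read_noise_sigma,
                "position_jitter_um": opts.position_jitter_um,
                "seed": opts.seed,
            },
        },
    )


def save_dataset(path, dataset: DiffractionDataset) -> None:
    """Write a dataset to HDF5: frames + scan/geometry/metadata groups."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=dataset.frames)
        f.attrs["wavelength_nm"] = dataset.wavelength
        f.attrs["background_level"] = dataset.background_level
        f.attrs["pitch_um"] = 0.0  # set by callers holding the grid; see CLI
        g = f.create_group("scan")
        g.create_dataset("positions_um", data=dataset.scan.positions)
        g.attrs["seed"] = dataset.scan.seed
        g.attrs["step_min_um"] = dataset.scan.step_min
        g.attrs["step_max_um"] = dataset.scan.step_max
        gg = f.create_group("geometry")
        gg.attrs["d1_um"] = dataset.geometry.d1
        gg.attrs["d2_um"] = dataset.geometry.d2
        gg.attrs["a"] = dataset.geometry.a
        gg.attrs["source_distance_um"] = dataset.geometry.source_distance
        if dataset.true_positions is not None:
            f.create_dataset("true_positions_um", data=dataset.true_positions)
        f.attrs["meta_json"] = json.dumps(dataset.meta)


def load_dataset(path) -> DiffractionDataset:
    with h5py.File(path, "r") as f:
        scan = ScanPlan(
            positions=f["scan/positions_um"][()],
            seed=int(f["scan"].attrs["seed"]),
            step_min=float(f["scan"].attrs["step_min_um"]),
            step_max=float(f["scan"].attrs["step_max_um"]),
        )
        geometry = SystemGeometry(
            d1=float(f["geometry"].attrs["d1_um"]),
            d2=float(f["geometry"].attrs["d2_um"]),
            a=float(f["geometry"].attrs["a"]),
            source_distance=float(f["geometry"].attrs["source_distance_um"]),
        )
        true_positions = (
            f["true_positions_um"][()] if "true_positions_um" in f else None
        )
        return DiffractionDataset(
            frames=f["frames"][()],
            scan=scan,
            geometry=geometry,
            wavelength=float(f.attrs["wavelength_nm"]),
            background_level=float(f.attrs["background_level"]),
            true_positions=true_positions,
            meta=json.loads(f.attrs.get("meta_json", "{}")),
        )


def export_dataset_tiff(tiff_path, json_path, dataset: DiffractionDataset) -> None:
    """16-bit multi-page TIFF export with a JSON metadata sidecar."""
    fmax = dataset.frames.max()
    scale = 65535.0 / fmax if fmax > 0 else 1.0
    tifffile.imwrite(
        tiff_path, (dataset.frames * scale).astype(np.uint16), photometric="minisblack"
    )
    sidecar = {
        "wavelength_nm": dataset.wavelength,
        "background_level": dataset.background_level,
        "intensity_scale": scale,
        "positions_um": dataset.scan.positions.tolist(),
        "geometry": {
            "d1_um": dataset.geometry.d1,
            "d2_um": dataset.geometry.d2,
            "a": dataset.geometry.a,
            "source_distance_um": dataset.geometry.source_distance,
        },
        "meta": dataset.meta,
    }
    with open(json_path, "w") as f:
        json.dump(sidecar, f, indent=2)

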