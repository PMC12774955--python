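"""Iterative mixed-state ptychographic reconstruction with a virtual error bin.

The measurement model: the unknown object wavefield ``E`` at the
coded-surface plane is shifted per scan position, multiplied by the known
coded surface ``CS``, propagated ``d2`` to the pixel array, and detected as
an incoherent sum of intensities over source states.  A second, deliberately
perturbed path — the virtual error bin — runs the same pipeline with its own
wavefield ``E_virtual`` and a propagation distance ``d2·a`` (``a ≠ 1``):
because its forward model is inconsistent with the accurate object path,
signal that the accurate model cannot explain (finite source bandwidth,
stray reflections, other systematics) drains into the virtual field instead
of corrupting the object estimate.  The measured intensity constrains the
sum of both paths:

    I_i = Σ_s |OS_s|² + Σ_s |VS_s|²

Per frame the engine projects the state mixture onto the measured intensity
(shared-magnitude projection: every state is scaled by
``sqrt(I_meas / I_model)``, which reproduces the measurement exactly),
back-propagates the corrections, and applies an rPIE-style regularised
inverse-modulation update of ``E`` (and ``E_virtual``) through the conjugate
of the coded surface.  Spatially incoherent source states enter as shifted
replicas of the single master detector wavefield, with fixed geometric
offsets ``offset·(d1+d2)/source_distance`` and weights from the source
model — one unknown field, many incoherent intensities.  Scan positions can
be refined in-loop by scoring small trial shifts of the forward model
against each measured frame.  A multi-resolution schedule (half sampling
first, then full) accelerates convergence on large frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from . import _fft
from .errors import ReconstructionError, ValidationError
from .gridfield import ComplexField, Grid, propagate, transfer_function
from .instrument import CodedSurface, SourceModel, SystemGeometry
from .simulate import DiffractionDataset

__all__ = [
    "ReconOptions",
    "ReconState",
    "reconstruct",
    "forward_states",
    "project_intensity",
    "refine_positions",
    "recon_error",
    "sample_plane_field",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class ReconOptions:
    """Knobs of the iterative engine.

    n_iter: total epochs over all resolution levels; use_virtual switches
    the error-bin path on; a: virtual-path distance factor (must differ from
    1 when the virtual path is on, otherwise the two paths are degenerate
    duplicates and cannot absorb mismatch); n_modes: source states included
    in the model (None = all states of the source model, 1 = coherent);
    multires_levels: 1 = single resolution, 2 = half then full (30%/70%
    iteration split); update_step: rPIE relaxation in (0, 1], 1 = plain
    inverse modulation; refine_positions_every: 0 disables in-loop position
    refinement; fov_margin_px: padding of the master field beyond the scan
    extent (None = automatic).
    """

    n_iter: int = 100
    use_virtual: bool = False
    a: float = 1.1
    n_modes: int | None = None
    multires_levels: int = 2
    update_step: float = 0.9
    refine_positions_every: int = 0
    refine_start_iter: int = 2
    refine_max_step_px: float = 1.0
    seed: int = 0
    fov_margin_px: int | None = None
    eps_floor_frac: float = 1e-12
    virtual_init_amplitude: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if self.use_virtual and self.a == 1.0:
            raise ValidationError("virtual path requires a != 1")
        if not (0.0 < self.update_step <= 1.0):
            raise ValidationError("update_step must lie in (0, 1]")
        if self.multires_levels not in (1, 2):
            raise ValidationError("multires_levels must be 1 or 2")


@dataclass
class ReconState:
    """The unknowns of the inverse problem plus diagnostics.

    E / E_virtual live at the coded-surface plane on the synthesized field
    of view (detector grid plus margin); positions are the refined per-frame
    (x, y) shifts in µm; history is the per-epoch intensity-fidelity error.
    """

    E: ComplexField
    E_virtual: ComplexField | None
    cs: CodedSurface
    cs_virtual: CodedSurface
    positions: np.ndarray
    geometry: SystemGeometry
    source: SourceModel
    opts: ReconOptions
    history: list = dc_field(default_factory=list)

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.cs.grid.shape

    def model_source(self) -> tuple[np.ndarray, np.ndarray]:
        """(offsets_px (n,2) as (dy, dx), weights) of the modelled states."""
        offsets_um = self.source.detector_offsets_um(self.geometry)
        weights = self.source.states[:, 2].copy()
        n = self.opts.n_modes
        if n is not None and n < len(weights):
            order = np.argsort(weights)[::-1][:n]
            offsets_um = offsets_um[order]
            weights = weights[order]
            weights = weights / weights.sum()
        pitch = self.cs.grid.pitch
        offsets_px = np.stack(
            [offsets_um[:, 1] / pitch, offsets_um[:, 0] / pitch], axis=1
        )
        return offsets_px, weights


def _shift_stack(psi: np.ndarray, offsets_px: np.ndarray) -> np.ndarray:
    """Stack of sub-pixel shifted replicas of one detector wavefield."""
    if len(offsets_px) == 1 and np.allclose(offsets_px[0], 0.0):
        return psi[None]
    hat = _fft.fft2(psi)
    out = np.empty((len(offsets_px),) + psi.shape, dtype=np.complex128)
    for k, (dy, dx) in enumerate(offsets_px):
        if dy == 0.0 and dx == 0.0:
            out[k] = psi
        else:
            out[k] = _fft.ifft2(hat * _fft.shift_ramp(psi.shape, dy, dx))
    return out


def _unshift_sum(delta: np.ndarray, offsets_px: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Adjoint of the shifted-replica broadcast: weighted un-shifted sum."""
    if len(offsets_px) == 1 and np.allclose(offsets_px[0], 0.0):
        return weights[0] * delta[0]
    acc = np.zeros(delta.shape[1:], dtype=np.complex128)
    for k, (dy, dx) in enumerate(offsets_px):
        if dy == 0.0 and dx == 0.0:
            acc += weights[k] * delta[k]
        else:
            acc += weights[k] * _fft.ifft2(
                _fft.fft2(delta[k]) * _fft.shift_ramp(delta.shape[1:], -dy, -dx)
            )
    return acc


def project_intensity(
    state_wavefields: np.ndarray,
    weights: np.ndarray,
    measured: np.ndarray,
    eps_floor_frac: float = 1e-12,
) -> np.ndarray:
    """Shared-magnitude projection of an incoherent mixture onto a measurement.

    Every state is scaled pixel-wise by ``sqrt(measured / model)`` where
    ``model = Σ_k w_k |ψ_k|²``; where the model intensity is below the floor
    (``eps_floor_frac`` × frame mean) each state is replaced by
    ``sqrt(measured)`` times its own phase.  The updated mixture reproduces
    the measured intensity exactly.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.min() < 0:
        raise ValidationError("measured intensities must be non-negative")
    psi = np.asarray(state_wavefields, dtype=np.complex128)
    if psi.ndim == 2:
        psi = psi[None]
    w = np.asarray(weights, dtype=float).reshape(-1, 1, 1)
    model = np.sum(w * np.abs(psi) ** 2, axis=0)
    floor = eps_floor_frac * max(measured.mean(), np.finfo(float).tiny)
    ok = model > floor
    factor = np.where(ok, np.sqrt(measured / np.where(ok, model, 1.0)), 0.0)
    updated = psi * factor
    if not ok.all():
        bad = ~ok
        mag = np.sqrt(measured[bad])
        for k in range(psi.shape[0]):
            amp = np.abs(psi[k][bad])
            ph = np.where(amp > 0, psi[k][bad] / np.maximum(amp, np.finfo(float).tiny), 1.0)
            updated[k][bad] = mag * ph
    return updated


def _level_setup(frames, positions_um, cs_values, pitch, wavelength, geometry, opts):
    """Precompute transfer functions and update denominators for one level."""
    n_y, n_x = frames.shape[1:]
    grid = Grid(n_x, n_y, pitch, wavelength)
    h2 = transfer_function(grid, geometry.d2)
    h2b = transfer_function(grid, -geometry.d2)
    abs2 = np.abs(cs_values) ** 2
    beta = 1.0 - opts.update_step
    denom = (1.0 - beta) * abs2 + beta * abs2.max()
    hv = hvb = None
    if opts.use_virtual:
        hv = transfer_function(grid, geometry.d2 * opts.a)
        hvb = transfer_function(grid, -geometry.d2 * opts.a)
    return h2, h2b, hv, hvb, denom


def _frame_forward(E_hat, shape_fov, pos_px, n_y, n_x, cs_values, h2):
    """Exit-window wavefield and detector wavefield for one frame."""
    dy, dx = pos_px
    shifted = _fft.ifft2(E_hat * _fft.shift_ramp(shape_fov, dy, dx))
    e_i = _fft.crop_center(shifted, n_y, n_x)
    psi = _fft.ifft2(_fft.fft2(e_i * cs_values) * h2)
    return e_i, psi


def _frame_update(E_hat, shape_fov, pos_px, chi, cs_conj, denom, h2b):
    """Back-propagate a detector correction and scatter it into the master field."""
    phi = _fft.ifft2(_fft.fft2(chi) * h2b)
    d_e = cs_conj * phi / denom
    pad = _fft.pad_center(d_e, *shape_fov)
    E_hat += _fft.fft2(pad) * _fft.shift_ramp(shape_fov, -pos_px[0], -pos_px[1])


def _bin2(frames: np.ndarray) -> np.ndarray:
    """2×2 mean binning of an intensity stack (optical pixel binning)."""
    p, ny, nx = frames.shape
    return frames.reshape(p, ny // 2, 2, nx // 2, 2).mean(axis=(2, 4))


def _resize_field_values(values: np.ndarray, new_shape) -> np.ndarray:
    """Value-preserving band-limited resize (for CS / E between levels)."""
    return _fft.fourier_resize(values, tuple(new_shape), preserve="values")


def reconstruct(
    dataset: DiffractionDataset,
    cs: CodedSurface,
    geometry: SystemGeometry,
    source: SourceModel,
    opts: ReconOptions | None = None,
    cs_virtual: CodedSurface | None = None,
    init: ReconState | None = None,
) -> ReconState:
    """Run the iterative reconstruction; returns the final state with history.

    E starts at unity (a transparent guess), E_virtual at small seeded
    complex noise; the coded surface is known and fixed, and the virtual
    path's coded surface defaults to the same map.  Frames are visited in a
    freshly randomised order each epoch (seeded).  With
    ``multires_levels=2`` the first 30% of the epochs run at half sampling,
    after which the fields are upsampled and refinement continues at full
    resolution.  Diverging (non-finite) states abort with a diagnostic
    error.
    """
    opts = opts or ReconOptions()
    n_y, n_x = dataset.frame_shape
    if (n_y, n_x) != cs.grid.shape:
        raise ValidationError("dataset frames and coded surface grids differ")
    if abs(cs.grid.wavelength - dataset.wavelength) > 1e-9:
        raise ValidationError("coded-surface grid wavelength must match the dataset")
    rng = np.random.default_rng(opts.seed)
    positions = dataset.scan.positions.copy()
    pitch = cs.grid.pitch

    margin = opts.fov_margin_px
    if margin is None:
        margin = int(np.ceil(np.abs(positions).max() / pitch)) + 8
    margin += margin % 2  # keep the synthesized FOV even for binning
    fov = (n_y + 2 * margin, n_x + 2 * margin)

    csv_obj = cs_virtual or cs.copy(label="virtual_path")

    if init is not None:
        E = init.E.values.copy()
        Ev = init.E_virtual.values.copy() if init.E_virtual is not None else None
        fov = E.shape
        positions = init.positions.copy()
    else:
        E = np.ones(fov, dtype=np.complex128)
        Ev = None
    if opts.use_virtual and Ev is None:
        Ev = opts.virtual_init_amplitude * (
            rng.standard_normal(fov) + 1j * rng.standard_normal(fov)
        )
    history: list[float] = []

    # multi-resolution schedule: (binning factor, epochs)
    if opts.multires_levels == 2 and n_y % 2 == 0 and n_x % 2 == 0 and opts.n_iter >= 10:
        n_coarse = max(int(round(0.3 * opts.n_iter)), 1)
        schedule = [(2, n_coarse), (1, opts.n_iter - n_coarse)]
    else:
        schedule = [(1, opts.n_iter)]

    state_source = ReconState(
        E=ComplexField(Grid(fov[1], fov[0], pitch, dataset.wavelength), E, "coded_surface"),
        E_virtual=None,
        cs=cs,
        cs_virtual=csv_obj,
        positions=positions,
        geometry=geometry,
        source=source,
        opts=opts,
    )
    offsets_px_full, weights = state_source.model_source()

    for bin_f, n_epochs in schedule:
        if n_epochs < 1:
            continue
        if bin_f > 1:
            frames = _bin2(dataset.frames)
            cs_vals = _resize_field_values(cs.values, (n_y // 2, n_x // 2))
            csv_vals = (
                _resize_field_values(csv_obj.values, (n_y // 2, n_x // 2))
                if opts.use_virtual
                else None
            )
            lv_fov = (fov[0] // 2, fov[1] // 2)
            E_lv = _resize_field_values(E, lv_fov)
            Ev_lv = _resize_field_values(Ev, lv_fov) if Ev is not None else None
            lv_pitch = pitch * 2.0
            offsets_px = offsets_px_full / 2.0
        else:
            frames = dataset.frames
            cs_vals = cs.values
            csv_vals = csv_obj.values if opts.use_virtual else None
            lv_fov = fov
            E_lv, Ev_lv = E, Ev
            lv_pitch = pitch
            offsets_px = offsets_px_full

        positions, E_lv, Ev_lv, hist = _run_level(
            frames,
            positions,
            cs_vals,
            csv_vals,
            lv_pitch,
            dataset.wavelength,
            geometry,
            offsets_px,
            weights,
            opts,
            E_lv,
            Ev_lv,
            n_epochs,
            rng,
            allow_refine=True,
        )
        history.extend(hist)
        if bin_f > 1:
            E = _resize_field_values(E_lv, fov)
            Ev = _resize_field_values(Ev_lv, fov) if Ev_lv is not None else None
        else:
            E, Ev = E_lv, Ev_lv

    grid_fov = Grid(fov[1], fov[0], pitch, dataset.wavelength)
    return ReconState(
        E=ComplexField(grid_fov, E, "coded_surface"),
        E_virtual=ComplexField(grid_fov, Ev, "coded_surface") if Ev is not None else None,
        cs=cs,
        cs_virtual=csv_obj,
        positions=positions,
        geometry=geometry,
        source=source,
        opts=opts,
        history=history,
    )


def _run_level(
    frames,
    positions_um,
    cs_vals,
    csv_vals,
    pitch,
    wavelength,
    geometry,
    offsets_px,
    weights,
    opts,
    E,
    Ev,
    n_epochs,
    rng,
    allow_refine=True,
):
    n_p, n_y, n_x = frames.shape
    fov = E.shape
    h2, h2b, hv, hvb, denom = _level_setup(
        frames, positions_um, cs_vals, pitch, wavelength, geometry, opts
    )
    cs_conj = np.conj(cs_vals)
    use_virtual = opts.use_virtual and Ev is not None and csv_vals is not None
    if use_virtual:
        abs2v = np.abs(csv_vals) ** 2
        beta = 1.0 - opts.update_step
        denom_v = (1.0 - beta) * abs2v + beta * max(abs2v.max(), 1e-12)
        csv_conj = np.conj(csv_vals)
    positions = positions_um.copy()

    E_hat = _fft.fft2(E)
    Ev_hat = _fft.fft2(Ev) if use_virtual else None
    history = []
    n_states = len(weights)
    w_col = weights.reshape(-1, 1, 1)

    for epoch in range(n_epochs):
        order = rng.permutation(n_p)
        err_acc = 0.0
        for i in order:
            pos_px = (positions[i, 1] / pitch, positions[i, 0] / pitch)
            e_i, psi0 = _frame_forward(E_hat, fov, pos_px, n_y, n_x, cs_vals, h2)
            psi = _shift_stack(psi0, offsets_px)
            if use_virtual:
                _, psiv0 = _frame_forward(Ev_hat, fov, pos_px, n_y, n_x, csv_vals, hv)
                psiv = _shift_stack(psiv0, offsets_px)
                all_states = np.concatenate([psi, psiv], axis=0)
                all_w = np.concatenate([weights, weights])
            else:
                all_states = psi
                all_w = weights
            model = np.sum(
                all_w.reshape(-1, 1, 1) * np.abs(all_states) ** 2, axis=0
            )
            meas = frames[i]
            denom_i = meas.sum()
            if denom_i > 0:
                err_acc += float(
                    np.sum((np.sqrt(model) - np.sqrt(meas)) ** 2) / denom_i
                )
            updated = project_intensity(all_states, all_w, meas, opts.eps_floor_frac)
            delta = updated - all_states
            chi = _unshift_sum(delta[:n_states], offsets_px, weights)
            _frame_update(E_hat, fov, pos_px, chi, cs_conj, denom, h2b)
            if use_virtual:
                chiv = _unshift_sum(delta[n_states:], offsets_px, weights)
                _frame_update(Ev_hat, fov, pos_px, chiv, csv_conj, denom_v, hvb)
        history.append(err_acc / n_p)
        if not np.isfinite(history[-1]):
            raise ReconstructionError(
                f"reconstruction diverged at epoch {epoch} (non-finite error)"
            )
        if (
            allow_refine
            and opts.refine_positions_every > 0
            and epoch >= opts.refine_start_iter
            and (epoch - opts.refine_start_iter) % opts.refine_positions_every == 0
        ):
            positions = _refine_positions_pass(
                E_hat,
                fov,
                positions,
                pitch,
                frames,
                cs_vals,
                h2,
                offsets_px,
                weights,
                opts,
                virtual=(Ev_hat, csv_vals, hv) if use_virtual else None,
            )

    E_out = _fft.ifft2(E_hat)
    Ev_out = _fft.ifft2(Ev_hat) if use_virtual else Ev
    return positions, E_out, Ev_out, history


def _model_intensity_at(E_hat, fov, pos_px, n_y, n_x, cs_vals, h2, offsets_px, weights, virtual):
    _, psi0 = _frame_forward(E_hat, fov, pos_px, n_y, n_x, cs_vals, h2)
    psi = _shift_stack(psi0, offsets_px)
    model = np.sum(weights.reshape(-1, 1, 1) * np.abs(psi) ** 2, axis=0)
    if virtual is not None:
        Ev_hat, csv_vals, hv = virtual
        _, psiv0 = _frame_forward(Ev_hat, fov, pos_px, n_y, n_x, csv_vals, hv)
        psiv = _shift_stack(psiv0, offsets_px)
        model = model + np.sum(weights.reshape(-1, 1, 1) * np.abs(psiv) ** 2, axis=0)
    return model


def _quad_peak(scores: np.ndarray) -> tuple[float, float]:
    """Sub-pixel (dy, dx) of the maximum of a 3×3 score patch."""
    k = int(np.argmax(scores))
    ky, kx = divmod(k, 3)

    def refine(sm, s0, sp):
        d = sm - 2 * s0 + sp
        if d >= 0:
            return 0.0
        return float(np.clip(0.5 * (sm - sp) / d, -0.5, 0.5))

    dy = (ky - 1) + (refine(scores[ky - 1, kx], scores[ky, kx], scores[ky + 1, kx])
                     if 0 < ky < 2 else 0.0)
    dx = (kx - 1) + (refine(scores[ky, kx - 1], scores[ky, kx], scores[ky, kx + 1])
                     if 0 < kx < 2 else 0.0)
    return dy, dx


def _refine_positions_pass(
    E_hat, fov, positions, pitch, frames, cs_vals, h2, offsets_px, weights, opts, virtual
):
    """Trial-shift position correction, one bounded step per frame.

    For each frame (frame 0 stays pinned as the gauge reference) the forward
    model is evaluated on a 3×3 grid of 1-px trial shifts around the current
    position; the amplitude agreement score is interpolated to sub-pixel by
    a parabola fit and the position moves by at most
    ``refine_max_step_px`` per pass.  Flat frames leave the position
    unchanged.
    """
    n_p, n_y, n_x = frames.shape
    new_positions = positions.copy()
    for i in range(1, n_p):
        meas_amp = np.sqrt(frames[i])
        if meas_amp.max() <= 0:
            continue
        scores = np.empty((3, 3))
        for ty in (-1, 0, 1):
            for tx in (-1, 0, 1):
                pos_px = (
                    (positions[i, 1]) / pitch + ty,
                    (positions[i, 0]) / pitch + tx,
                )
                model = _model_intensity_at(
                    E_hat, fov, pos_px, n_y, n_x, cs_vals, h2, offsets_px, weights, virtual
                )
                scores[ty + 1, tx + 1] = -float(
                    np.sum((np.sqrt(model) - meas_amp) ** 2)
                )
        dy, dx = _quad_peak(scores)
        step = opts.refine_max_step_px
        dy = float(np.clip(dy, -step, step))
        dx = float(np.clip(dx, -step, step))
        new_positions[i, 0] += dx * pitch
        new_positions[i, 1] += dy * pitch
    return new_positions


def forward_states(state: ReconState, position_index: int):
    """Per-state detector wavefields and the model intensity for one frame.

    Returns ``(states, weights, model_intensity)`` where ``states`` stacks
    the object-path states first and (when the virtual path is on) the
    virtual-path states after them.
    """
    n_y, n_x = state.detector_shape
    if not (0 <= position_index < len(state.positions)):
        raise ValidationError("position index out of range")
    pitch = state.cs.grid.pitch
    pos = state.positions[position_index]
    pos_px = (pos[1] / pitch, pos[0] / pitch)
    offsets_px, weights = state.model_source()
    fov = state.E.values.shape
    E_hat = _fft.fft2(state.E.values)
    h2 = transfer_function(state.cs.grid, state.geometry.d2)
    _, psi0 = _frame_forward(E_hat, fov, pos_px, n_y, n_x, state.cs.values, h2)
    psi = _shift_stack(psi0, offsets_px)
    all_states, all_w = psi, weights
    if state.opts.use_virtual and state.E_virtual is not None:
        hv = transfer_function(state.cs.grid, state.geometry.d2 * state.opts.a)
        Ev_hat = _fft.fft2(state.E_virtual.values)
        _, psiv0 = _frame_forward(
            Ev_hat, fov, pos_px, n_y, n_x, state.cs_virtual.values, hv
        )
        psiv = _shift_stack(psiv0, offsets_px)
        all_states = np.concatenate([psi, psiv], axis=0)
        all_w = np.concatenate([weights, weights])
    model = np.sum(all_w.reshape(-1, 1, 1) * np.abs(all_states) ** 2, axis=0)
    return all_states, all_w, model


def refine_positions(state: ReconState, dataset: DiffractionDataset) -> np.ndarray:
    """One stand-alone trial-shift refinement pass over all frames."""
    offsets_px, weights = state.model_source()
    h2 = transfer_function(state.cs.grid, state.geometry.d2)
    E_hat = _fft.fft2(state.E.values)
    virtual = None
    if state.opts.use_virtual and state.E_virtual is not None:
        hv = transfer_function(state.cs.grid, state.geometry.d2 * state.opts.a)
        virtual = (_fft.fft2(state.E_virtual.values), state.cs_virtual.values, hv)
    return _refine_positions_pass(
        E_hat,
        state.E.values.shape,
        state.positions,
        state.cs.grid.pitch,
        dataset.frames,
        state.cs.values,
        h2,
        offsets_px,
        weights,
        state.opts,
        virtual,
    )


def recon_error(state: ReconState, dataset: DiffractionDataset) -> float:
    """Mean over frames of Σ(√model − √measured)² / Σ measured.

    Zero iff the model intensities equal the measurements; equals 1 when the
    model is identically zero against a positive measurement.
    """
    total = 0.0
    for i in range(dataset.n_frames):
        _, _, model = forward_states(state, i)
        meas = dataset.frames[i]
        s = meas.sum()
        if s > 0:
            total += float(np.sum((np.sqrt(model) - np.sqrt(meas)) ** 2) / s)
    return total / dataset.n_frames


def sample_plane_field(state: ReconState, d1: float | None = None) -> ComplexField:
    """Back-propagate the recovered master field to the sample plane."""
    d = d1 if d1 is not None else state.geometry.d1
    return propagate(state.E, -d, plane="sample")


def save_state(path, state: ReconState) -> None:
    with h5py.File(path, "w") as f:
        for name, fld in (("E", state.E), ("E_virtual", state.E_virtual)):
            if fld is None:
                continue
            g = f.create_group(name)
            g.create_dataset("real", data=fld.values.real)
            g.create_dataset("imag", data=fld.values.imag)
            g.attrs["pitch_um"] = fld.grid.pitch
            g.attrs["wavelength_nm"] = fld.grid.wavelength
        f.create_dataset("positions_um", data=state.positions)
        f.create_dataset("history", data=np.asarray(state.history))
        f.attrs["d1_um"] = state.geometry.d1
        f.attrs["d2_um"] = state.geometry.d2
        f.attrs["a"] = state.geometry.a


def load_state(path) -> dict:
    """Load the serialized arrays of a saved state (fields, positions, history)."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        for name in ("E", "E_virtual"):
            if name in f:
                g = f[name]
                vals = g["real"][()] + 1j * g["imag"][()]
                grid = Grid(
                    vals.shape[1], vals.shape[0],
                    float(g.attrs["pitch_um"]), float(g.attrs["wavelength_nm"]),
                )
                out[name] = ComplexField(grid, vals, "coded_surface")
        out["positions_um"] = f["positions_um"][()]
        out["history"] = list(f["history"][()])
        out["geometry"] = SystemGeometry(
            d1=float(f.attrs["d1_um"]), d2=float(f.attrs["d2_um"]), a=float(f.attrs["a"])
        )
    return out

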