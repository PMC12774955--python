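"""Brenner-gradient focus scoring, axial search, and tile-wise height maps.

A reconstructed wavefield at the coded-surface plane can be digitally
back-propagated to any axial plane; the plane of best focus maximises the
Brenner gradient — the sum of squared finite differences at a fixed pixel
offset — computed here on the refocused intensity (the classic spacing-2
form; both spacing and amplitude-vs-intensity are configurable since
conventions vary).  Scanning the metric over a grid of distances and
refining the argmax with a parabolic fit recovers the sample-to-surface
distance per region; doing this per overlapping tile yields a topographic
height map of an extended sample.  Heights are reported as refocus distance
z relative to the coded surface; a display height is ``z_ref − z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
import tifffile
from scipy import ndimage

from .errors import ValidationError
from .gridfield import ComplexField, Grid, propagate

__all__ = ["HeightMap", "brenner", "autofocus_field", "height_map"]


@dataclass
class HeightMap:
    """Per-tile best refocus distance with the search metadata."""

    z_values: np.ndarray           # (ty, tx) best z per tile, µm
    valid: np.ndarray              # (ty, tx) bool: tile had enough contrast
    score_surface: np.ndarray      # (ty, tx, nz) Brenner score vs z
    z_grid: np.ndarray             # (nz,) search distances, µm
    tile_px: int
    overlap_px: int
    tile_centers: np.ndarray       # (ty, tx, 2) pixel centres (y, x)

    def export_tiff(self, tiff_path, json_path) -> None:
        tifffile.imwrite(tiff_path, self.z_values.astype(np.float32))
        with open(json_path, "w") as f:
            json.dump(
                {
                    "z_min_um": float(self.z_grid[0]),
                    "z_max_um": float(self.z_grid[-1]),
                    "z_step_um": float(self.z_grid[1] - self.z_grid[0]) if len(self.z_grid) > 1 else 0.0,
                    "tile_px": self.tile_px,
                    "overlap_px": self.overlap_px,
                    "valid_fraction": float(self.valid.mean()),
                },
                f,
                indent=2,
            )


def brenner(image: np.ndarray, spacing: int = 2) -> float:
    """Brenner gradient: mean of squared finite differences at ``spacing``.

    Non-negative; zero iff the image is constant; invariant to additive
    offsets and quadratic in multiplicative gain.  Normalised by the pixel
    count so scores are comparable across tile sizes.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValidationError("image must be 2-D and at least 8 px per side")
    if spacing < 1 or spacing >= min(img.shape):
        raise ValidationError("spacing must be >= 1 and smaller than the image")
    dx = img[:, spacing:] - img[:, :-spacing]
    dy = img[spacing:, :] - img[:-spacing, :]
    return float((np.sum(dx**2) + np.sum(dy**2)) / img.size)


def _parabolic_refine(z: np.ndarray, s: np.ndarray, k: int) -> float:
    """Sub-step refinement of an argmax by a 3-point parabola fit."""
    if k == 0 or k == len(z) - 1:
        return float(z[k])
    denom = s[k - 1] - 2.0 * s[k] + s[k + 1]
    if denom >= 0:  # not a local maximum of the parabola
        return float(z[k])
    delta = 0.5 * (s[k - 1] - s[k + 1]) / denom
    step = z[k + 1] - z[k]
    return float(z[k] + np.clip(delta, -0.5, 0.5) * step)


def autofocus_field(
    field: ComplexField,
    z_min: float,
    z_max: float,
    z_step: float,
    spacing: int = 2,
    use_intensity: bool = True,
):
    """Search the refocus distance maximising the Brenner score.

    Evaluates ``brenner(|propagate(field, −z)|²)`` over ``z`` in
    ``[z_min, z_max]`` at ``z_step`` intervals (back-propagation toward the
    sample uses negative distances) and returns ``(z_best, (z_grid,
    scores))`` with a parabolic sub-step refinement of the peak.
    """
    if not (z_min < z_max) or z_step <= 0:
        raise ValidationError("need z_min < z_max and z_step > 0")
    z_grid = np.arange(z_min, z_max + 0.5 * z_step, z_step)
    scores = np.empty(len(z_grid))
    for k, z in enumerate(z_grid):
        refocused = propagate(field, -z)
        img = refocused.intensity if use_intensity else refocused.amplitude
        scores[k] = brenner(img, spacing=spacing)
    k = int(np.argmax(scores))
    return _parabolic_refine(z_grid, scores, k), (z_grid, scores)


def height_map(
    field: ComplexField,
    tile_px: int,
    overlap_px: int,
    z_min: float,
    z_max: float,
    z_step: float,
    contrast_floor: float = 0.05,
    prominence_floor: float = 0.03,
    score_rel_floor: float = 0.1,
    pad_px: int | None = None,
    spacing: int = 2,
) -> HeightMap:
    """Tile-wise autofocus over an extended field.

    Tiles of ``tile_px`` pixels advance by ``tile_px − overlap_px``.  Each
    tile is refocused inside a larger context window (``pad_px`` extra
    pixels per side, default tile_px/2, so the diffraction fringes that
    belong to the tile's content are not cut away) and scored on the central
    tile only.  A tile is invalid — and filled from its nearest valid
    neighbour — when the refocused tile lacks amplitude contrast
    (``contrast_floor`` × the global amplitude std), its score curve has no
    clear interior peak (relative prominence below ``prominence_floor``),
    or its peak score is below ``score_rel_floor`` of the strongest tile
    (stray fringes from content elsewhere).
    """
    if tile_px < 32:
        raise ValidationError("tile_px must be at least 32")
    if not (0 <= overlap_px < tile_px):
        raise ValidationError("overlap must be in [0, tile_px)")
    ny, nx = field.grid.shape
    if pad_px is None:
        pad_px = tile_px // 2
    win = tile_px + 2 * pad_px
    if win > min(ny, nx):
        pad_px = (min(ny, nx) - tile_px) // 2
        win = tile_px + 2 * pad_px
    step = tile_px - overlap_px
    y0s = list(range(0, max(ny - tile_px, 0) + 1, step))
    x0s = list(range(0, max(nx - tile_px, 0) + 1, step))
    if not y0s or not x0s:
        raise ValidationError("field smaller than one tile")

    z_grid = np.arange(z_min, z_max + 0.5 * z_step, z_step)
    global_std = float(field.amplitude.std())
    z_vals = np.zeros((len(y0s), len(x0s)))
    valid = np.zeros_like(z_vals, dtype=bool)
    centers = np.zeros((len(y0s), len(x0s), 2))
    surface = np.zeros((len(y0s), len(x0s), len(z_grid)))
    win_grid = Grid(win, win, field.grid.pitch, field.grid.wavelength)
    for iy, y0 in enumerate(y0s):
        for ix, x0 in enumerate(x0s):
            # context window kept inside the field; tile may sit off-centre
            wy = min(max(y0 - pad_px, 0), ny - win)
            wx = min(max(x0 - pad_px, 0), nx - win)
            sub = ComplexField(win_grid, field.values[wy : wy + win, wx : wx + win].copy(), field.plane)
            oy, ox = y0 - wy, x0 - wx
            scores = np.empty(len(z_grid))
            best_tile_std = 0.0
            for k, z in enumerate(z_grid):
                amp = np.abs(propagate(sub, -z).values[oy : oy + tile_px, ox : ox + tile_px])
                scores[k] = brenner(amp**2, spacing=spacing)
                best_tile_std = max(best_tile_std, float(amp.std()))
            k = int(np.argmax(scores))
            surface[iy, ix] = scores
            z_vals[iy, ix] = _parabolic_refine(z_grid, scores, k)
            smax = scores.max()
            prominence = (smax - np.median(scores)) / smax if smax > 0 else 0.0
            valid[iy, ix] = (
                global_std > 0
                and best_tile_std >= contrast_floor * global_std
                and prominence >= prominence_floor
                and 0 < k < len(z_grid) - 1
            )
            centers[iy, ix] = (y0 + tile_px / 2.0, x0 + tile_px / 2.0)
    # second pass: a tile whose peak score is tiny next to the strongest
    # tile carries stray fringes from elsewhere, not its own content
    peak_scores = surface.max(axis=2)
    valid &= peak_scores >= score_rel_floor * peak_scores.max()
    if not valid.any():
        raise ValidationError("no tile has enough contrast for autofocus")
    if not valid.all():
        idx = ndimage.distance_transform_edt(
            ~valid, return_distances=False, return_indices=True
        )
        z_vals = z_vals[tuple(idx)]
    return HeightMap(
        z_values=z_vals,
        valid=valid,
        score_surface=surface,
        z_grid=z_grid,
        tile_px=tile_px,
        overlap_px=overlap_px,
        tile_centers=centers,
    )
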