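"""Unitary FFT helpers and Fourier-domain shift / resize primitives.

All FFTs in the package are orthonormal (``norm="ortho"``) so that
``sum(|values|**2)`` is preserved by the transform and energy accounting in
propagation is direct.  Shifts follow the convention ``shift(f, dy, dx)(y, x)
= f(y - dy, x - dx)``: positive offsets move content toward larger indices.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _sfft


def fft2(a: np.ndarray) -> np.ndarray:
    return _sfft.fft2(a, norm="ortho")


def ifft2(a: np.ndarray) -> np.ndarray:
    return _sfft.ifft2(a, norm="ortho")


def freq_grids(ny: int, nx: int, pitch: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Spatial-frequency grids (cycles per unit of ``pitch``), fy and fx."""
    fy = _sfft.fftfreq(ny, d=pitch)[:, None]
    fx = _sfft.fftfreq(nx, d=pitch)[None, :]
    return fy, fx


def shift_ramp(shape: tuple[int, int], dy_px: float, dx_px: float) -> np.ndarray:
    """Fourier-domain phase ramp implementing a (dy, dx) pixel translation."""
    fy, fx = freq_grids(*shape)
    return np.exp(-2j * np.pi * (fy * dy_px + fx * dx_px))


def fourier_shift(values: np.ndarray, dy_px: float, dx_px: float) -> np.ndarray:
    """Sub-pixel circular shift of a complex array via the shift theorem."""
    if dy_px == 0.0 and dx_px == 0.0:
        return values.copy()
    return ifft2(fft2(values) * shift_ramp(values.shape, dy_px, dx_px))


def fourier_shift_real(values: np.ndarray, dy_px: float, dx_px: float) -> np.ndarray:
    """Sub-pixel shift of a real array (e.g. an intensity image)."""
    return fourier_shift(values.astype(np.complex128), dy_px, dx_px).real


def crop_center(values: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Central (ny, nx) window of a 2-D array."""
    oy = (values.shape[0] - ny) // 2
    ox = (values.shape[1] - nx) // 2
    if oy < 0 or ox < 0:
        raise ValueError("crop size exceeds array size")
    return values[oy : oy + ny, ox : ox + nx]


def pad_center(values: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Zero-pad a 2-D array to (ny, nx), original content centred."""
    oy = (ny - values.shape[0]) // 2
    ox = (nx - values.shape[1]) // 2
    if oy < 0 or ox < 0:
        raise ValueError("pad size smaller than array size")
    out = np.zeros((ny, nx), dtype=values.dtype)
    out[oy : oy + values.shape[0], ox : ox + values.shape[1]] = values
    return out


def fourier_resize(
    values: np.ndarray, new_shape: tuple[int, int], preserve: str = "energy"
) -> np.ndarray:
    """Band-limited resize by centred crop/pad of the Fourier spectrum.

    preserve="energy" keeps sum(|values|**2) of the retained band (unitary
    crop/pad); preserve="values" keeps the sample values of the underlying
    band-limited function (a constant field stays at the same level), which is
    what field resampling inside the reconstruction engine needs.
    """
    ny, nx = values.shape
    my, mx = new_shape
    spec = _sfft.fftshift(fft2(values))
    if my <= ny and mx <= nx:
        spec = crop_center(spec, my, mx)
    elif my >= ny and mx >= nx:
        spec = pad_center(spec, my, mx)
    else:
        raise ValueError("mixed grow/shrink resize is not supported")
    if preserve == "values":
        spec = spec * np.sqrt((my * mx) / (ny * nx))
    elif preserve != "energy":
        raise ValueError(f"unknown preserve mode {preserve!r}")
    return ifft2(_sfft.ifftshift(spec))
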