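"""Independent brute-force oracles used by the test suite.

These are deliberately naive O(N^4) implementations with no FFT calls, so
they share no code path with the package's operators.
"""

from __future__ import annotations

import numpy as np


def direct_diffraction_sum(
    values: np.ndarray, pitch: float, wavelength_um: float, distance: float
) -> np.ndarray:
    """Free-space propagation by direct summation over plane-wave components.

    Decomposes the input into discrete plane waves by an explicit
    double-loop DFT, advances each by the exact scalar free-space phase
    exp(i 2π d sqrt(1/λ² − fx² − fy²)) (evanescent terms dropped), and
    resums with an explicit inverse loop.  O(N^4); use on small grids only.
    """
    ny, nx = values.shape
    fy = np.fft.fftfreq(ny, pitch)
    fx = np.fft.fftfreq(nx, pitch)
    ys = np.arange(ny) * pitch
    xs = np.arange(nx) * pitch

    coeffs = np.zeros((ny, nx), dtype=complex)
    for m in range(ny):
        for n in range(nx):
            phase = np.exp(
                -2j * np.pi * (fy[m] * ys[:, None] + fx[n] * xs[None, :])
            )
            coeffs[m, n] = np.sum(values * phase)
    coeffs /= np.sqrt(nx * ny)

    arg = 1.0 / wavelength_um**2 - fy[:, None] ** 2 - fx[None, :] ** 2
    kernel = np.where(
        arg > 0, np.exp(2j * np.pi * distance * np.sqrt(np.maximum(arg, 0.0))), 0.0
    )
    coeffs = coeffs * kernel

    out = np.zeros((ny, nx), dtype=complex)
    for p in range(ny):
        for q in range(nx):
            phase = np.exp(
                2j * np.pi * (fy[:, None] * ys[p] + fx[None, :] * xs[q])
            )
            out[p, q] = np.sum(coeffs * phase)
    return out / np.sqrt(nx * ny)


def bandlimit_field(values: np.ndarray, pitch: float, f_max: float) -> np.ndarray:
    """Hard low-pass a complex field to |f| <= f_max per axis (cycles/µm)."""
    ny, nx = values.shape
    spec = np.fft.fft2(values)
    fy = np.fft.fftfreq(ny, pitch)[:, None]
    fx = np.fft.fftfreq(nx, pitch)[None, :]
    spec[(np.abs(fy) > f_max) | (np.abs(fx) > f_max)] = 0.0
    return np.fft.ifft2(spec)


def mass_unit_conversion(n_mol_per_um2: float, pixel_um: float, molar_mass: float) -> float:
    """Dimensional-analysis oracle: areal molar density -> fg per pixel.

    n [mol/µm²] × area [µm²] = mol; mol × M [g/mol] = g; 1 g = 1e15 fg.
    Computed step by step so the unit chain is explicit.
    """
    moles_per_pixel = n_mol_per_um2 * (pixel_um * pixel_um)
    grams_per_pixel = moles_per_pixel * molar_mass
    femtograms_per_pixel = grams_per_pixel * 1.0e15
    return femtograms_per_pixel
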