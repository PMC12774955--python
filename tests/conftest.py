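import numpy as np
import pytest

from duvpty import (
    Grid,
    SystemGeometry,
    default_extinction_table,
    make_cell_phantom,
    make_coded_surface,
    make_scan_plan,
    make_source_model,
)

PITCH_UM = 1.85  # typical back-illuminated CMOS pitch assumed throughout


@pytest.fixture(scope="session")
def eps_table():
    return default_extinction_table()


@pytest.fixture(scope="session")
def geometry():
    return SystemGeometry(d1=800.0)


@pytest.fixture(scope="session")
def small_grid():
    return Grid(64, 64, PITCH_UM, 266.0)


@pytest.fixture(scope="session")
def bench128():
    """Shared 128-px noiseless coherent benchmark pieces."""
    n_det, margin = 128, 20
    n_fov = n_det + 2 * margin
    geometry = SystemGeometry(d1=800.0)
    scan = make_scan_plan(6, 5.0, 6.5, seed=1)
    phantom = make_cell_phantom(
        Grid(n_fov, n_fov, PITCH_UM, 266.0), 3, seed=2, margin_px=40
    )
    cs = make_coded_surface(Grid(n_det, n_det, PITCH_UM, 266.0), seed=3)
    source = make_source_model("point", 1, center_wavelength=266.0)
    return {
        "n_det": n_det,
        "margin": margin,
        "geometry": geometry,
        "scan": scan,
        "phantom": phantom,
        "cs": cs,
        "source": source,
    }


def bandlimited_field(grid, seed, f_frac=0.6):
    """Random complex field band-limited to f_frac of Nyquist on ``grid``."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
    spec = np.fft.fft2(v)
    fy = np.fft.fftfreq(grid.ny, grid.pitch)[:, None]
    fx = np.fft.fftfreq(grid.nx, grid.pitch)[None, :]
    f_max = f_frac * 0.5 / grid.pitch
    spec[(np.abs(fy) > f_max) | (np.abs(fx) > f_max)] = 0.0
    return np.fft.ifft2(spec)
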