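"""Phantom generation and the forward diffraction model."""

import numpy as np
import pytest
from scipy import ndimage

from duvpty import (
    Grid,
    SimOptions,
    ValidationError,
    make_cell_phantom,
    make_coded_surface,
    make_scan_plan,
    make_source_model,
    sample_exit_field,
    simulate_dataset,
)
from duvpty.instrument import ScanPlan
from duvpty.simulate import (
    DEFAULT_AMOUNT_RANGES,
    LABEL_BACKGROUND,
    export_dataset_tiff,
    load_dataset,
    save_dataset,
)

from .conftest import PITCH_UM


def fov_grid(n=128, wavelength=266.0):
    return Grid(n, n, PITCH_UM, wavelength)


class TestCellPhantom:
    def test_empty_phantom(self):
        ph = make_cell_phantom(fov_grid(), 0, seed=0)
        assert ph.n_pro.max() == 0 and ph.n_nuc.max() == 0
        assert ph.n_cells == 0

    def test_cell_count_matches_nuclear_components(self):
        ph = make_cell_phantom(fov_grid(256), 5, seed=4, margin_px=20)
        n_components = ndimage.label(ph.nucleus_labels > 0)[1]
        assert n_components == 5
        assert ph.n_cells == 5

    def test_amounts_within_ranges_and_background_zero(self):
        ph = make_cell_phantom(fov_grid(), 2, seed=1, margin_px=24)
        bg = ph.labels == LABEL_BACKGROUND
        assert np.all(ph.n_pro[bg] == 0) and np.all(ph.n_nuc[bg] == 0)
        # any interior nucleus pixel carries at least the minimum nuclear
        # amount scaled by its (smooth) edge profile; the hard bound is the
        # global maximum of the configured ranges
        hi = DEFAULT_AMOUNT_RANGES["nuc_nuc"][1] + DEFAULT_AMOUNT_RANGES["nuc_cyto"][1]
        assert ph.n_nuc.max() <= hi * (1 + 1e-9)

    def test_deterministic_per_seed(self):
        a = make_cell_phantom(fov_grid(), 3, seed=9, margin_px=24)
        b = make_cell_phantom(fov_grid(), 3, seed=9, margin_px=24)
        np.testing.assert_array_equal(a.n_pro, b.n_pro)
        np.testing.assert_array_equal(a.cell_labels, b.cell_labels)

    def test_impossible_placement_raises(self):
        with pytest.raises(ValidationError):
            make_cell_phantom(
                fov_grid(64), 30, seed=0, cell_radius_um=(30.0, 40.0), max_tries=5
            )


class TestExitField:
    def test_empty_phantom_gives_unit_field(self, eps_table):
        ph = make_cell_phantom(fov_grid(), 0, seed=0)
        f = sample_exit_field(ph, 266.0, eps_table)
        np.testing.assert_allclose(f.values, 1.0 + 0.0j)

    def test_single_pixel_od_one_transmits_ten_percent(self, eps_table):
        ph = make_cell_phantom(fov_grid(), 0, seed=0)
        # craft one pixel with total decadic OD exactly 1 at 266 nm
        ph.labels[64, 64] = 1
        ph.n_pro[64, 64] = 1.0 / eps_table.eps[266]["pro"]
        f = sample_exit_field(ph, 266.0, eps_table)
        assert np.abs(f.values[64, 64]) ** 2 == pytest.approx(0.1, rel=1e-12)

    def test_od_round_trip_identity(self, eps_table):
        ph = make_cell_phantom(fov_grid(), 3, seed=2, margin_px=24)
        f = sample_exit_field(ph, 266.0, eps_table)
        od = eps_table.od(ph.n_pro, ph.n_nuc, 266)
        np.testing.assert_allclose(-np.log10(np.abs(f.values) ** 2), od, atol=1e-12)

    def test_phase_only_without_table(self):
        ph = make_cell_phantom(fov_grid(n=128, wavelength=405.0), 2, seed=3, margin_px=24)
        f = sample_exit_field(ph, 405.0, None)
        np.testing.assert_allclose(np.abs(f.values), 1.0)
        assert np.abs(f.phase).max() > 0

    def test_unknown_wavelength_rejected(self, eps_table):
        ph = make_cell_phantom(fov_grid(), 0, seed=0)
        with pytest.raises(ValidationError):
            sample_exit_field(ph, 310.0, eps_table)


def small_setup(eps_table, n_det=64, margin=16, seed=0):
    n_fov = n_det + 2 * margin
    geometry_grid = Grid(n_fov, n_fov, PITCH_UM, 266.0)
    phantom = make_cell_phantom(
        geometry_grid, 1, seed=seed, margin_px=20, cell_radius_um=(10.0, 14.0)
    )
    cs = make_coded_surface(Grid(n_det, n_det, PITCH_UM, 266.0), seed=seed + 1)
    scan = make_scan_plan(2, 2 * PITCH_UM, 3 * PITCH_UM, seed=seed + 2)
    source = make_source_model("point", 1, center_wavelength=266.0)
    return phantom, cs, scan, source


class TestSimulateDataset:
    def test_transparent_system_conserves_background(self, eps_table, geometry):
        n_det, margin = 64, 16
        grid = Grid(n_det + 2 * margin, n_det + 2 * margin, PITCH_UM, 266.0)
        phantom = make_cell_phantom(grid, 0, seed=0)
        cs = make_coded_surface(
            Grid(n_det, n_det, PITCH_UM, 266.0), seed=1,
            amp_range=(1.0, 1.0), phase_range=0.0,
        )
        scan = make_scan_plan(2, 2 * PITCH_UM, 3 * PITCH_UM, seed=2)
        source = make_source_model("point", 1, center_wavelength=266.0)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table,
                              SimOptions(background_level=2.5))
        np.testing.assert_allclose(ds.frames, 2.5, rtol=1e-9)

    def test_deterministic_with_seed(self, eps_table, geometry):
        phantom, cs, scan, source = small_setup(eps_table)
        opts = SimOptions(shot_noise=True, read_noise_sigma=0.01, seed=42)
        a = simulate_dataset(phantom, geometry, scan, source, cs, eps_table, opts)
        b = simulate_dataset(phantom, geometry, scan, source, cs, eps_table, opts)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_shift_model_consistency(self, eps_table, geometry):
        """A scan shift equals pre-shifting the phantom (shift theorem)."""
        phantom, cs, _, source = small_setup(eps_table)
        shift_px = 3
        shift_um = shift_px * PITCH_UM
        scan = ScanPlan(
            positions=np.array(
                [[0.0, 0.0], [shift_um, 0.0], [0.0, shift_um], [shift_um, shift_um]]
            ),
            seed=0, step_min=shift_um, step_max=shift_um,
        )
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        rolled = make_cell_phantom(phantom.grid, 0, seed=0)
        # E(x - x_i): content moves by +shift when the plan says +shift
        rolled.n_pro = np.roll(phantom.n_pro, shift_px, axis=1)
        rolled.n_nuc = np.roll(phantom.n_nuc, shift_px, axis=1)
        rolled.height = np.roll(phantom.height, shift_px, axis=1)
        rolled.labels = np.roll(phantom.labels, shift_px, axis=1)
        rolled.dn = phantom.dn
        zero_scan = ScanPlan(
            positions=np.zeros((4, 2)), seed=0, step_min=1.0, step_max=1.0
        )
        ds0 = simulate_dataset(rolled, geometry, zero_scan, source, cs, eps_table)
        err = np.abs(ds.frames[1] - ds0.frames[0]).max() / ds.frames[1].max()
        assert err < 1e-6

    def test_incoherent_summation_linearity(self, eps_table, geometry):
        """An n-state simulation equals the weighted sum of per-state runs."""
        phantom, cs, scan, _ = small_setup(eps_table)
        source = make_source_model("disc", 3, radius=400.0, center_wavelength=266.0)
        full = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        acc = np.zeros_like(full.frames)
        for ox, oy, w in source.states:
            single = type(source)(states=[[ox, oy, 1.0]], spectrum=source.spectrum)
            part = simulate_dataset(phantom, geometry, scan, single, cs, eps_table)
            acc += w * part.frames
        np.testing.assert_allclose(full.frames, np.clip(acc, 0, None), atol=1e-12)

    def test_per_frame_energy_constant_with_phase_only_cs(self, eps_table, geometry):
        # phantom grid equals the detector grid (the full circularly
        # shifted field is captured) and the grid is large enough that the
        # band limit of the d2 transfer sits beyond Nyquist: nothing leaves
        n_det = 128
        grid = Grid(n_det, n_det, PITCH_UM, 266.0)
        phantom = make_cell_phantom(grid, 1, seed=5, margin_px=24,
                                    cell_radius_um=(8.0, 10.0))
        cs = make_coded_surface(
            Grid(n_det, n_det, PITCH_UM, 266.0), seed=1, amp_range=(1.0, 1.0)
        )
        scan = make_scan_plan(2, 2 * PITCH_UM, 3 * PITCH_UM, seed=2)
        source = make_source_model("point", 1, center_wavelength=266.0)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        sums = ds.frames.sum(axis=(1, 2))
        assert np.ptp(sums) / sums.mean() < 1e-9

    def test_noise_keeps_frames_nonnegative_and_reports_clipping(
        self, eps_table, geometry
    ):
        phantom, cs, scan, source = small_setup(eps_table)
        opts = SimOptions(shot_noise=True, photons_per_pixel=100.0,
                          read_noise_sigma=0.1, seed=3)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table, opts)
        assert ds.frames.min() >= 0
        assert "clipped_fraction" in ds.meta

    def test_position_jitter_records_nominal_and_true(self, eps_table, geometry):
        phantom, cs, scan, source = small_setup(eps_table)
        opts = SimOptions(position_jitter_um=2.0, seed=7)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table, opts)
        assert ds.true_positions is not None
        assert not np.array_equal(ds.true_positions, ds.scan.positions)
        np.testing.assert_array_equal(ds.true_positions[0], ds.scan.positions[0])

    def test_ghost_reflection_changes_frames(self, eps_table, geometry):
        phantom, cs, scan, source = small_setup(eps_table)
        clean = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        ghost = simulate_dataset(phantom, geometry, scan, source, cs, eps_table,
                                 SimOptions(ghost_reflection=True))
        assert np.abs(ghost.frames - clean.frames).max() > 1e-3 * clean.frames.max()


class TestDatasetIO:
    def test_hdf5_round_trip(self, eps_table, geometry, tmp_path):
        phantom, cs, scan, source = small_setup(eps_table)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        path = tmp_path / "ds.h5"
        save_dataset(path, ds)
        back = load_dataset(path)
        np.testing.assert_array_equal(back.frames, ds.frames)
        np.testing.assert_array_equal(back.scan.positions, ds.scan.positions)
        assert back.geometry.d2 == ds.geometry.d2
        assert back.wavelength == ds.wavelength

    def test_tiff_export_with_sidecar(self, eps_table, geometry, tmp_path):
        import json

        import tifffile

        phantom, cs, scan, source = small_setup(eps_table)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps_table)
        tp, jp = tmp_path / "ds.tif", tmp_path / "ds.json"
        export_dataset_tiff(tp, jp, ds)
        frames = tifffile.imread(tp)
        assert frames.shape == ds.frames.shape
        assert frames.dtype == np.uint16
        meta = json.loads(jp.read_text())
        assert meta["wavelength_nm"] == ds.wavelength
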