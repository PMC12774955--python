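"""Config-driven orchestration: simulate → reconstruct → analyse in one call.

These functions back the command-line interface but are plain library code:
each takes a validated :class:`RunConfig` and an output directory, runs the
corresponding stage(s), writes artifacts (HDF5 datasets, TIFFs, CSV, JSON
manifests carrying the config hash and all seeds), and returns the key
results in memory.  The full demo chains every capability on a synthetic
specimen and emits a metrics report (reconstruction NRMSE, autofocus error,
per-cell mass-recovery error) against the known ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._fft import crop_center
from .autofocus import height_map
from .cytometry import cell_features, segment_cells, write_features_csv
from .errors import ValidationError
from .gridfield import Grid, export_amplitude_phase_tiff, nrmse
from .instrument import (
    SystemGeometry,
    make_coded_surface,
    make_scan_plan,
    make_source_model,
)
from .reconstruct import ReconOptions, reconstruct, sample_plane_field, save_state
from .simulate import (
    SimOptions,
    make_cell_phantom,
    sample_exit_field,
    save_dataset,
    simulate_dataset,
)
from .spectra import ExtinctionTable, default_extinction_table, duv_mass_pipeline
from .stain import default_palette, export_rgb, load_palette, render_fluorescence, render_he

__all__ = [
    "RunConfig",
    "load_config",
    "run_simulate",
    "run_reconstruct",
    "run_full_demo",
    "validate_report",
    "REPORT_KEYS",
]

_ALLOWED = {
    "": {
        "seed", "pitch_um", "wavelengths_nm", "detector_px", "fov_margin_px",
        "geometry", "scan", "source", "coded_surface", "phantom", "simulate",
        "reconstruct", "focus", "eps_table", "palette", "output_dir",
    },
    "geometry": {"d1_um", "d2_um", "a", "source_distance_um"},
    "scan": {"n_side", "step_min_um", "step_max_um", "seed"},
    "source": {"shape", "n_states", "bandwidth_fwhm_nm", "n_spectral", "radius_um"},
    "coded_surface": {"seed", "feature_size_um", "amp_min", "amp_max", "phase_range_rad"},
    "phantom": {"n_cells", "seed", "margin_px", "nucleus_shape"},
    "simulate": {
        "background_level", "ghost_reflection", "ghost_amplitude",
        "ghost_extra_path_um", "shot_noise", "photons_per_pixel",
        "read_noise_sigma", "position_jitter_um", "seed",
    },
    "reconstruct": {
        "n_iter", "use_virtual", "a", "n_modes", "multires_levels",
        "update_step", "refine_positions_every", "seed",
    },
    "focus": {"z_min_um", "z_max_um", "z_step_um", "tile_px", "overlap_px"},
}


@dataclass
class RunConfig:
    """Validated run configuration (schema-checked, unknown keys rejected)."""

    seed: int = 0
    pitch_um: float = 1.85
    wavelengths_nm: tuple = (266.0, 280.0, 405.0)
    detector_px: int = 128
    fov_margin_px: int = 20
    geometry: dict = dc_field(default_factory=lambda: {
        "d1_um": 800.0, "d2_um": 840.0, "a": 1.1, "source_distance_um": 200000.0,
    })
    scan: dict = dc_field(default_factory=lambda: {
        "n_side": 6, "step_min_um": 5.0, "step_max_um": 6.5, "seed": 1,
    })
    source: dict = dc_field(default_factory=lambda: {
        "shape": "point", "n_states": 1, "bandwidth_fwhm_nm": 0.0,
        "n_spectral": 1, "radius_um": None,
    })
    coded_surface: dict = dc_field(default_factory=lambda: {
        "seed": 3, "feature_size_um": None, "amp_min": 0.3, "amp_max": 1.0,
        "phase_range_rad": float(2.0 * np.pi),
    })
    phantom: dict = dc_field(default_factory=lambda: {
        "n_cells": 3, "seed": 2, "margin_px": 36, "nucleus_shape": "round",
    })
    simulate: dict = dc_field(default_factory=dict)
    reconstruct: dict = dc_field(default_factory=lambda: {"n_iter": 60})
    focus: dict = dc_field(default_factory=lambda: {
        "z_min_um": 400.0, "z_max_um": 1200.0, "z_step_um": 20.0,
        "tile_px": 64, "overlap_px": 16,
    })
    eps_table: str | None = None
    palette: str | None = None
    output_dir: str = "duvpty_out"

    def __post_init__(self) -> None:
        recon = {"n_iter": 60, **self.reconstruct}
        opts_a = recon.get("a", self.geometry.get("a", 1.1))
        if recon.get("use_virtual", False) and opts_a == 1.0:
            raise ValidationError("config invalid: use_virtual requires a != 1")
        self.reconstruct = recon
        if self.detector_px < 8:
            raise ValidationError("detector_px must be at least 8")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def make_geometry(self) -> SystemGeometry:
        g = self.geometry
        return SystemGeometry(
            d1=g.get("d1_um", 800.0),
            d2=g.get("d2_um", 840.0),
            a=g.get("a", 1.1),
            source_distance=g.get("source_distance_um", 200000.0),
        )

    def make_scan(self):
        s = self.scan
        return make_scan_plan(
            s.get("n_side", 6), s.get("step_min_um", 5.0),
            s.get("step_max_um", 6.5), s.get("seed", 1),
        )

    def make_source(self, wavelength: float):
        s = self.source
        return make_source_model(
            shape=s.get("shape", "point"),
            n_states=s.get("n_states", 1),
            bandwidth_fwhm=s.get("bandwidth_fwhm_nm", 0.0),
            n_spectral=s.get("n_spectral", 1),
            center_wavelength=wavelength,
            seed=self.seed,
            radius=s.get("radius_um"),
        )

    def make_cs(self, wavelength: float):
        c = self.coded_surface
        grid = Grid(self.detector_px, self.detector_px, self.pitch_um, wavelength)
        return make_coded_surface(
            grid,
            seed=c.get("seed", 3),
            feature_size=c.get("feature_size_um"),
            amp_range=(c.get("amp_min", 0.3), c.get("amp_max", 1.0)),
            phase_range=c.get("phase_range_rad", 2.0 * np.pi),
        )

    def make_phantom(self, wavelength: float):
        p = self.phantom
        n_fov = self.detector_px + 2 * self.fov_margin_px
        grid = Grid(n_fov, n_fov, self.pitch_um, wavelength)
        return make_cell_phantom(
            grid,
            n_cells=p.get("n_cells", 3),
            seed=p.get("seed", 2),
            margin_px=p.get("margin_px", 36),
            nucleus_shape=p.get("nucleus_shape", "round"),
        )

    def make_sim_options(self) -> SimOptions:
        return SimOptions(**self.simulate)

    def make_recon_options(self, use_virtual: bool | None = None) -> ReconOptions:
        r = dict(self.reconstruct)
        if use_virtual is not None:
            r["use_virtual"] = use_virtual
        r.setdefault("seed", self.seed)
        r.setdefault("fov_margin_px", self.fov_margin_px)
        return ReconOptions(**r)

    def load_eps(self) -> ExtinctionTable:
        if self.eps_table:
            return ExtinctionTable.from_csv(self.eps_table)
        return default_extinction_table()

    def load_palette(self):
        if self.palette:
            return load_palette(self.palette)
        return default_palette()


def load_config(path_or_dict) -> RunConfig:
    """Load and schema-validate a YAML/JSON config; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as f:
            data = yaml.safe_load(f) or {}
    unknown = set(data) - _ALLOWED[""]
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _ALLOWED.items():
        if not section or section not in data or data[section] is None:
            continue
        bad = set(data[section]) - allowed
        if bad:
            raise ValidationError(f"unknown keys in '{section}': {sorted(bad)}")
    if "wavelengths_nm" in data:
        data["wavelengths_nm"] = tuple(float(w) for w in data["wavelengths_nm"])
    return RunConfig(**data)


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "config": asdict(config),
        **extra,
    }


def run_simulate(config: RunConfig, outdir) -> dict:
    """Simulate one dataset per configured wavelength; write HDF5 + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eps = config.load_eps()
    geometry = config.make_geometry()
    scan = config.make_scan()
    sim_opts = config.make_sim_options()
    files = {}
    for lam in config.wavelengths_nm:
        phantom = config.make_phantom(lam)
        cs = config.make_cs(lam)
        source = config.make_source(lam)
        table = eps if int(round(lam)) in eps.eps else None
        ds = simulate_dataset(phantom, geometry, scan, source, cs, table, sim_opts)
        fname = outdir / f"dataset_{int(round(lam))}nm.h5"
        save_dataset(fname, ds)
        files[str(int(round(lam)))] = {
            "path": fname.name,
            "n_frames": ds.n_frames,
            "frame_shape": list(ds.frame_shape),
        }
    manifest = _manifest(config, {"stage": "simulate", "datasets": files})
    with open(outdir / "manifest_simulate.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def run_reconstruct(config: RunConfig, dataset, cs, outdir, tag: str = "recon") -> dict:
    """Reconstruct one dataset and write state HDF5 + amplitude/phase TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry = config.make_geometry()
    source = config.make_source(dataset.wavelength)
    opts = config.make_recon_options()
    state = reconstruct(dataset, cs, geometry, source, opts)
    save_state(outdir / f"{tag}_state.h5", state)
    sample = sample_plane_field(state)
    export_amplitude_phase_tiff(
        outdir / f"{tag}_amplitude.tif", outdir / f"{tag}_phase.tif", sample
    )
    log = _manifest(config, {
        "stage": "reconstruct",
        "tag": tag,
        "wavelength_nm": dataset.wavelength,
        "final_error": state.history[-1] if state.history else None,
        "n_epochs": len(state.history),
    })
    with open(outdir / f"{tag}_log.json", "w") as f:
        json.dump(log, f, indent=2)
    return {"state": state, "log": log}


REPORT_KEYS = {
    "package_version": str,
    "config_hash": str,
    "amplitude_nrmse": dict,
    "autofocus": dict,
    "mass_recovery": dict,
    "cytometry": dict,
    "stages_completed": list,
}


def validate_report(report: dict) -> None:
    """Check the full-demo report against the shipped schema (types + keys)."""
    for key, typ in REPORT_KEYS.items():
        if key not in report:
            raise ValidationError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValidationError(f"report key {key!r} has wrong type")


def run_full_demo(config: RunConfig, outdir) -> dict:
    """Chain simulate → reconstruct → focus → unmix → stain → cytometry.

    Uses the two deep-UV wavelengths for molecular mass recovery and writes
    every artifact plus a JSON metrics report comparing against the phantom
    ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    eps = config.load_eps()
    geometry = config.make_geometry()
    scan = config.make_scan()
    sim_opts = config.make_sim_options()
    duv = [lam for lam in config.wavelengths_nm if int(round(lam)) in eps.eps]
    if len(duv) < 2:
        raise ValidationError("full demo needs both deep-UV wavelengths configured")
    duv = sorted(duv)[:2]

    recons = {}
    phantom = None
    for lam in duv:
        phantom = config.make_phantom(lam) if phantom is None else phantom
        cs = config.make_cs(lam)
        source = config.make_source(lam)
        ds = simulate_dataset(phantom, geometry, scan, source, cs, eps, sim_opts)
        save_dataset(outdir / f"dataset_{int(round(lam))}nm.h5", ds)
        out = run_reconstruct(config, ds, cs, outdir, tag=f"recon_{int(round(lam))}nm")
        recons[int(round(lam))] = out["state"]
    stages.append("simulate")
    stages.append("reconstruct")

    lam266, lam280 = int(round(duv[0])), int(round(duv[1]))
    n_fov = phantom.grid.nx
    crop = min(n_fov - 2 * config.phantom.get("margin_px", 36), config.detector_px)
    crop = min(max(crop, 64), config.detector_px)  # segmentation needs >= 64 px
    crop -= crop % 2

    amp = {}
    amp_nrmse = {}
    for lam, state in recons.items():
        sample = sample_plane_field(state)
        a_rec = crop_center(np.abs(sample.values), crop, crop)
        truth = sample_exit_field(phantom, float(lam), eps)
        a_true = crop_center(np.abs(truth.values), crop, crop)
        amp[lam] = (a_rec, a_true)
        amp_nrmse[str(lam)] = nrmse(a_rec, a_true, fit_scale=True)

    # autofocus on the reconstructed coded-surface field
    fc = config.focus
    state266 = recons[lam266]
    recon_fov = crop_center(state266.E.values, crop, crop)
    recon_field = type(state266.E)(
        Grid(crop, crop, config.pitch_um, state266.E.grid.wavelength),
        recon_fov, "coded_surface",
    )
    hm = height_map(
        recon_field,  # central, well-covered part of the recovered field
        tile_px=fc.get("tile_px", 64),
        overlap_px=fc.get("overlap_px", 16),
        z_min=fc.get("z_min_um", 400.0),
        z_max=fc.get("z_max_um", 1200.0),
        z_step=fc.get("z_step_um", 20.0),
    )
    hm.export_tiff(outdir / "height_map.tif", outdir / "height_map.json")
    focus_err = float(np.abs(hm.z_values[hm.valid] - geometry.d1).mean()) if hm.valid.any() else None
    stages.append("focus")

    # registration-free gauge: both recons share the scan, so shift ≈ 0
    bg_w = max(crop // 8, 8)
    roi = (slice(0, bg_w), slice(0, bg_w))
    mass = duv_mass_pipeline(amp[lam266][0], amp[lam280][0], roi, eps, config.pitch_um)
    stages.append("unmix")

    # per-cell integrated mass-recovery error against ground truth
    labels = crop_center(phantom.cell_labels, crop, crop)
    mass_err = {"pro": [], "nuc": []}
    from .spectra import amounts_to_mass

    m_pro_true = amounts_to_mass(
        crop_center(phantom.n_pro, crop, crop), config.pitch_um, eps.molar_mass["pro"]
    )
    m_nuc_true = amounts_to_mass(
        crop_center(phantom.n_nuc, crop, crop), config.pitch_um, eps.molar_mass["nuc"]
    )
    for cid in range(1, int(labels.max()) + 1):
        sel = labels == cid
        if not sel.any():
            continue
        m_pro_raw = amounts_to_mass(mass.n_pro_raw, config.pitch_um, eps.molar_mass["pro"])
        m_nuc_raw = amounts_to_mass(mass.n_nuc_raw, config.pitch_um, eps.molar_mass["nuc"])
        for key, m_true, m_rec in (
            ("pro", m_pro_true, m_pro_raw),
            ("nuc", m_nuc_true, m_nuc_raw),
        ):
            t = m_true[sel].sum()
            if t > 0:
                mass_err[key].append(abs(m_rec[sel].sum() - t) / t)

    palette = config.load_palette()
    export_rgb(outdir / "stain_fluorescence.png", render_fluorescence(mass, palette), palette)
    export_rgb(outdir / "stain_he.png", render_he(mass, palette), palette)
    stages.append("stain")

    cell_labels, nuc_labels = segment_cells(mass.m_pro + mass.m_nuc, mass.m_nuc)
    records = cell_features(cell_labels, nuc_labels, config.pitch_um)
    write_features_csv(outdir / "cells.csv", records)
    stages.append("cytometry")

    report = _manifest(config, {
        "amplitude_nrmse": amp_nrmse,
        "autofocus": {
            "mean_abs_error_um": focus_err,
            "d1_true_um": geometry.d1,
            "valid_tiles": int(hm.valid.sum()),
        },
        "mass_recovery": {
            "max_rel_error_pro": max(mass_err["pro"]) if mass_err["pro"] else None,
            "max_rel_error_nuc": max(mass_err["nuc"]) if mass_err["nuc"] else None,
            "negatives_clipped_fraction": mass.negatives_clipped_fraction,
        },
        "cytometry": {"n_cells_found": len(records), "n_cells_true": phantom.n_cells},
        "stages_completed": stages,
    })
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2)
    validate_report(report)
    return report
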