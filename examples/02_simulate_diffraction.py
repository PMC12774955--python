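"""Simulating a coded-surface diffraction dataset.

The forward model: sample exit field → free-space propagation to the coded
surface → lateral shift per scan position → modulation by the known random
coded surface → propagation to the pixel array → intensity.
"""

from duvpty import (
    Grid,
    SystemGeometry,
    default_extinction_table,
    make_cell_phantom,
    make_coded_surface,
    make_scan_plan,
    make_source_model,
    simulate_dataset,
)

pitch = 1.85  # µm/pixel, typical back-illuminated CMOS
geometry = SystemGeometry(d1=800.0)  # sample 0.8 mm above the coded surface
scan = make_scan_plan(6, 5.0, 6.5, seed=1)  # 36 jittered ~3 px steps
phantom = make_cell_phantom(Grid(168, 168, pitch, 266.0), 3, seed=2, margin_px=40)
cs = make_coded_surface(Grid(128, 128, pitch, 266.0), seed=3)
source = make_source_model("point", 1, center_wavelength=266.0)

dataset = simulate_dataset(phantom, geometry, scan, source, cs,
                           default_extinction_table())
print(f"{dataset.n_frames} diffraction frames of {dataset.frame_shape} px "
      f"at {dataset.wavelength:.0f} nm")
print(f"frame intensity mean {dataset.frames.mean():.3f} "
      f"(background level {dataset.background_level})")
print(f"scan extent: {scan.positions.max():.1f} µm "
      f"({scan.positions.max() / pitch:.1f} px)")
# Each frame is the speckle-like interference of the shifted object field
# with the coded surface; the stack is what the solver inverts.
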