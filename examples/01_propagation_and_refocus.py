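"""Free-space propagation and digital refocusing.

Builds the exit wavefield of a small cell phantom, propagates it 800 µm to
the coded-surface plane (as the instrument would), then scans the Brenner
focus metric to recover the propagation distance numerically.
"""

import numpy as np

from duvpty import (
    Grid,
    autofocus_field,
    default_extinction_table,
    make_cell_phantom,
    propagate,
    sample_exit_field,
)

grid = Grid(256, 256, 1.85, 266.0)
eps = default_extinction_table()
phantom = make_cell_phantom(grid, 4, seed=7, margin_px=30)
exit_field = sample_exit_field(phantom, 266.0, eps)
print(f"exit field: min amplitude {exit_field.amplitude.min():.3f} "
      f"(max OD {-2 * np.log10(exit_field.amplitude.min()):.2f})")

at_surface = propagate(exit_field, 800.0)
print(f"energy before/after propagation: {exit_field.energy:.2f} / "
      f"{at_surface.energy:.2f}  (conserved)")

z_best, (z_grid, scores) = autofocus_field(at_surface, 100.0, 2000.0, 20.0)
print(f"autofocus over {len(z_grid)} planes: best refocus at {z_best:.1f} µm "
      f"(true distance 800.0 µm)")
# The metric peaks where back-propagation restores the sharp absorption
# image; the sub-step residual comes from the parabolic peak fit.
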