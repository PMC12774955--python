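"""Label-free cytometry: separating leukocyte-like populations.

Segment cells in simulated mass maps and compute the standard morphometric
trio (area, nuclear/cytoplasmic ratio, nuclear roundness).  Cells with one
round nucleus (mononuclear-like) and cells with a lobed nucleus
(polymorphonuclear-like) separate completely on the feature plane.
"""

import numpy as np

from duvpty import Grid, cell_features, make_cell_phantom, segment_cells

grid = Grid(512, 512, 0.8, 266.0)


def population(nucleus_shape, seed):
    phantom = make_cell_phantom(grid, 8, seed=seed, margin_px=20,
                                cell_radius_um=(9.0, 12.0),
                                nucleus_shape=nucleus_shape)
    total = phantom.n_pro + phantom.n_nuc
    cells, nuclei = segment_cells(total / total.max(), phantom.n_nuc)
    recs = [r for r in cell_features(cells, nuclei, 0.8) if not r.flagged]
    return np.array([[r.area, r.nc_ratio, r.nuclear_roundness] for r in recs])


mono = population("round", 3)
poly = population("lobed", 4)

print(f"{'population':<22}{'n':>3}{'area µm²':>12}{'N/C':>8}{'roundness':>11}")
for name, f in (("mononuclear-like", mono), ("polymorphonuclear-like", poly)):
    print(f"{name:<22}{len(f):>3}{f[:, 0].mean():>12.0f}"
          f"{f[:, 1].mean():>8.2f}{f[:, 2].mean():>11.2f}")

gap = mono[:, 2].min() - poly[:, 2].max()
print(f"\nnuclear-roundness gap between populations: {gap:+.2f} "
      f"({'zero overlap' if gap > 0 else 'overlapping'})")
# A positive gap means a single threshold classifies every cell — the
# morphometric basis for label-free differential counts.
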