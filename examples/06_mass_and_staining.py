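"""Two-wavelength Beer–Lambert unmixing and quantitative virtual staining.

Proteins and nucleic acids absorb differently at 266 nm and 280 nm.  From
two amplitude images the per-pixel optical densities form a 2×2 linear
system whose closed-form solution gives areal molar amounts, hence masses
in femtograms per pixel — the quantitative basis for the virtual stains.
"""

import numpy as np

from duvpty import (
    Grid,
    default_extinction_table,
    duv_mass_pipeline,
    make_cell_phantom,
    render_fluorescence,
    render_he,
    sample_exit_field,
)

pitch = 1.85
eps = default_extinction_table()
print(f"extinction matrix condition number: {eps.condition_number:.1f}")

grid = Grid(192, 192, pitch, 266.0)
phantom = make_cell_phantom(grid, 3, seed=6, margin_px=30)
a266 = np.abs(sample_exit_field(phantom, 266.0, eps).values)
a280 = np.abs(sample_exit_field(phantom, 280.0, eps).values)

mass = duv_mass_pipeline(a266, a280, (slice(0, 16), slice(0, 16)), eps, pitch)
print(f"registration shift between wavelengths: "
      f"({mass.shift[0]:+.2f}, {mass.shift[1]:+.2f}) px")
print(f"total protein mass      {mass.total_mass_fg['pro']:.1f} fg")
print(f"total nucleic-acid mass {mass.total_mass_fg['nuc']:.1f} fg")
print(f"peak per-pixel masses: pro {mass.m_pro.max():.2f} fg/px, "
      f"nuc {mass.m_nuc.max():.2f} fg/px")

he = render_he(mass)
fluo = render_fluorescence(mass)
print(f"H&E render: background {he[0, 0]} (white), "
      f"darkest pixel {he.reshape(-1, 3).min(axis=0).round(2)}")
print(f"fluorescence render: background {fluo[0, 0]} (black), "
      f"brightest pixel {fluo.reshape(-1, 3).max(axis=0).round(2)}")
# Nuclei pull the H&E image toward hematoxylin blue-violet, cytoplasm
# toward eosin pink — driven directly by measured mass, not by a learned
# style transfer.
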