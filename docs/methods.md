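# Methods

## Imaging model

The instrument is an on-chip lensless stack: a quasi-point source ~20 cm
away (`source_distance`, default 2×10⁵ µm), the sample at `d1` ∈ 0.2–2 mm
above a known random amplitude/phase modulator (the coded surface), and
the coded surface at a fixed `d2` = 840 µm above the pixel array. During
acquisition the sensor assembly (coded surface included) steps laterally
on a jittered grid; in the object frame this shifts the object wavefield
before the coded-surface modulation, which is how both the simulator and
the solver express it: position *i* evaluates `E(x − x_i, y − y_i)`.

All propagation is scalar and monochromatic per spectral sample, via the
band-limited angular-spectrum transfer function
`H(f) = exp(i 2π d √(1/λ² − f²))` with evanescent components zeroed and
the Matsushima limit `f ≤ 1/(λ √((2 d Δf)² + 1))` applied per axis so the
sampled phase ramp cannot alias at long distances. FFTs are orthonormal,
so `Σ|values|²` is an energy that propagation conserves for in-band
fields; the test suite checks the operator against an independent O(N⁴)
plane-wave summation oracle to 10⁻⁶ relative. A paraxial Fresnel transfer
function is available for cross-checks; the angular spectrum is the
default because the working distances make it exact at no extra cost.

Sign convention: positive distances propagate away from the source;
refocusing back toward the sample uses negative distances. Pixel (0, 0)
is the array top-left, the physical origin is the grid centre, spatial
frequencies are in cycles/µm.

## Sample model

A phantom stores per-pixel **areal molar densities** `n = c·l` (mol/µm²)
for protein and nucleic acid — only the concentration×path product is
identifiable from a transmission measurement, so it is never split — plus
topographic height and a scalar refractive-index contrast `dn`. The exit
field is

```
amplitude = 10^(−OD/2),  OD = ε_λ^pro n_pro + ε_λ^nuc n_nuc
phase     = 2π · dn · height / λ
```

(the ½ because the decadic Beer–Lambert law is defined on intensity).
Generator defaults: elliptical cells of 14–22 µm radius with
nucleic-acid-rich nuclei (nuclear OD at 266 nm ≈ 0.4–0.7) and protein-rich
cytoplasm (OD at 280 nm ≈ 0.2–0.4), typical of thin unstained
preparations; heights 0.3–1.2 µm. `dn` defaults to 0.005, giving deep-UV
phase excursions of ~0.1 rad: for these specimens absorption dominates and
the recovered phase carries little contrast, which is also the regime in
which intensity-based Brenner autofocus peaks at the true plane (a
strongly phase-dominant sample *gains* defocus contrast monotonically and
needs a different focus criterion). Phase-dominant work at 405 nm should
raise `dn` per sample.

The nucleus is either one ellipse ("round", mononuclear-like) or a chain
of three overlapping lobes ("lobed", polymorphonuclear-like); the lobe
spacing is bounded so the nucleus stays one connected component that is
clearly non-circular — this is what makes the two populations separable by
nuclear roundness, and it mirrors real leukocyte morphology.

## Source model

Partial spatial coherence is modelled geometrically: an emitter point at
offset `o` shifts the detector-plane pattern by `o·(d1+d2)/source_distance`
(shadow magnification). Both the simulator and the solver apply the shift
to the propagated detector wavefield of a single master object field, so
an n-state measurement is exactly the weighted incoherent sum of n shifted
intensities and the reconstruction's mode parameterisation (shifted
replicas of one unknown field with fixed offsets and weights) matches the
data-generating process. Fully independent mode fields are out of scope.
Finite temporal bandwidth is simulated by re-evaluating the exit-field
phase and both propagations at each spectral sample (Gaussian weights over
±FWHM) — a genuine model mismatch, not an intensity blur, because that is
what the virtual error bin is meant to absorb. Emitter shape and state
count are free parameters (a disc sampled by a centred sunflower pattern
by default); the default spectral FWHM for artifact studies is 10 nm.

## Reconstruction

Per frame the engine: (1) forms the per-state detector wavefields from the
current `E` (and `E_virtual`); (2) projects the incoherent mixture onto
the measurement by scaling every state with `√(I_meas/I_model)` — the
updated mixture reproduces the measurement exactly, and where the model
intensity is below `10⁻¹² ×` the frame mean the state is replaced by the
measured magnitude with its own phase; (3) back-propagates the corrections
(−d2 object path, −d2·a virtual path) and applies an rPIE-style
regularised inverse modulation through the conjugate coded surface, with
denominator `u·|CS|² + (1−u)·max|CS|²` and `update_step u = 0.9`. rPIE
with a known, strongly modulating "probe" is the standard robust choice;
the coded surface is treated as known and fixed, and the virtual path
reuses it (`CS_virtual = CS`) — refining either sits behind flags and
outside the verified path. `E` starts at unity, `E_virtual` at seeded
complex noise of amplitude 10⁻³. Frames are visited in a fresh random
order per epoch (seeded, so runs are bit-reproducible). The virtual factor
`a = 1.1`; `a = 1` is rejected when the virtual path is on, because a
degenerate duplicate of the object path cannot absorb mismatch.

**Multi-resolution.** With `multires_levels = 2` the first 30% of epochs
run at half sampling (2×2-binned frames, value-preserving Fourier-resized
fields) as a warm start, then the fields are upsampled and refinement
continues at full resolution. The intensity-binning/coarse-model pairing
is not exactly self-consistent, which is fine for a warm start; the final
level is exact.

**Position refinement.** Every `refine_positions_every` epochs each frame
(frame 0 pinned as the gauge reference) scores the forward model on a 3×3
grid of ±1 px trial shifts against the measured amplitude, interpolates
the peak with a parabola fit, and moves at most 1 px per pass. Position
errors are reported after removing the common translation of all frames,
which is a gauge freedom of the problem. Refinement pairs best with
single-resolution runs (the coarse level's 2-px granularity helps little);
the jitter benchmark uses `multires_levels = 1`.

**Convergence diagnostic.** `recon_error` is the mean over frames of
`Σ(√model − √measured)²/Σ measured` — 0 at a perfect fit, 1 for a zero
model. The per-epoch history decreases monotonically during descent and
wobbles within a few percent at the numerical floor because of the random
frame order; tests assert descent with that tolerance.

## Autofocus and height maps

The Brenner gradient (squared finite differences at spacing 2, normalised
by pixel count) is computed on refocused intensity; spacing and
amplitude-vs-intensity are configurable since conventions vary. The axial
search refines the argmax with a parabolic fit (recovered distance within
half a 20-µm step across d1 = 300–1500 µm on the standard phantom; the
score curve is strictly unimodal within ±80 µm of the peak, with weak
coherent sidelobes further out). Height maps refocus each tile inside a
larger context window (default pad = tile/2) so the tile's own fringes are
not cut away, and score only the central tile. A tile is invalid — and
filled from its nearest valid neighbour, never reported as a measurement —
if it lacks amplitude contrast, its score curve has no interior peak, or
its peak score is below 10% of the strongest tile's (stray fringes from
content elsewhere). z is reported relative to the coded surface; display
height is `z_ref − z`.

## Mass recovery and staining

OD per wavelength is `log10(I_background) − log10(I_sample)` with the
sample intensity floored at 10⁻⁶ of background; the background is the
median intensity over a user-chosen empty region (ROI median is this
package's convention — how to choose the empty region is inherently a
user decision). The 280-nm image is registered onto the 266-nm image by
phase cross-correlation (sub-pixel, Fourier resampling) before unmixing.
The 2×2 system is solved in the explicit closed form (exact inverse of the
forward model to machine precision; property-tested over random
nonsingular tables and cross-checked against a generic linear solve).
Negative amounts are recorded and clipped to zero for the *maps*; per-cell
*integrals* in the demo report use the raw (unclipped) solutions, because
clipping zero-mean noise before integrating would bias totals upward.

The shipped extinction table is literature-typical, clearly labelled a
default: BSA-like protein (ε₂₈₀ ≈ 43 800 M⁻¹cm⁻¹, ε₂₆₆ ≈ 0.8·ε₂₈₀,
M = 66.4 kg/mol) and per-nucleotide nucleic acid (ε₂₆₆ ≈ 8 000, ε₂₈₀ ≈
4 400 M⁻¹cm⁻¹, M = 330 g/mol); condition number ≈ 16. Units are per areal
density (µm²/mol; ×10¹¹ from M⁻¹cm⁻¹). Quantitative work on real samples
must supply a sample-specific table (`ExtinctionTable.from_csv`); absolute
femtogram values depend entirely on it.

Virtual staining is a pure function of the mass maps. H&E mode mixes
optical densities along the classic Ruifrok–Johnston hematoxylin/eosin
colour vectors (`RGB = 10^−OD`, plus a constant green background term that
renders zero mass white); fluorescence mode adds saturating emissions
(`1 − exp(−m/scale)`, nucleic acid blue, protein purple) on black. Scales
default to the 95th percentile of the nonzero masses (still deterministic);
all vectors and scales live in a user-editable palette file since the
reference renderings are described only qualitatively. The comparison
contrast metric is Michelson contrast on a 1st–99th-percentile-clipped
ROI — a declared convention of this package (bounded, gain-invariant).

## Cytometry

Segmentation: Gaussian smoothing, log dynamic-range compression (nuclei
can be 10× brighter than cytoplasm; raw Otsu would split nucleus-vs-rest
instead of foreground-vs-background), Otsu threshold, hole filling, size
filter, then marker-controlled watershed with markers from the nucleus
channel (closed with a small disc so a lobed nucleus seeds one cell, not
three). Features: area, nuclear area, N/C area ratio, and isoperimetric
nuclear roundness 4πA/P² (clipped to 1 against rasterisation overshoot).
These conventions are parameterised; other reasonable choices exist.

## What the synthetic benchmarks do and do not show

The simulator emulates: the exact coherent forward model, incoherent
spatial/spectral mixtures, ghost reflections (weak coherent copy with
extra path 2·d2, amplitude 0.1 by default), shot noise at a configurable
photon budget (default 10⁴ counts/pixel at background, a plausible ~0.1 s
LED exposure), Gaussian read noise with clipping bookkeeping, and position
jitter with nominal-vs-true bookkeeping. It does not emulate: rigorous
partial-coherence propagation via mutual intensity, sensor PRNU or dark
current, 3-D (multi-slice) samples, coded-surface miscalibration, or
vectorial/polarisation effects. Passing benchmarks therefore demonstrates
the correctness and self-consistency of the algorithms under the stated
physics — not performance on real data, which additionally depends on
calibration quality and the unmodelled effects above.

Benchmark sizes are chosen for single-CPU turnaround: the pinned
reconstruction benchmark is a 256×256 detector with an 8×8 scan at ~3 px
steps and 100 epochs; the ablation, position, and mass benchmarks use
128×128 with a 6×6 scan. The phantom placement margin keeps cells inside
the region covered by every scan window (the scan is one-sided relative to
the first position, so the well-covered region is offset from the frame
centre by up to the scan extent).

## Known limitations

* Source modes are shifted replicas of one field; strongly extended or
  spectrally wide sources would need independent modes.
* `CS_virtual` is fixed to `CS`; the optimal treatment of the virtual
  path's modulator is an open question and exposed behind a flag.
* The multi-resolution warm start can slightly slow position refinement;
  use a single level when jitter is the dominant error.
* The mass pipeline assumes pure decadic absorption; scattering or
  resonance corrections to Beer–Lambert are out of scope.
* Michelson-on-clipped-ROI is one contrast definition among several; use
  it for orderings, not absolute comparisons with other instruments.
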