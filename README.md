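# microvista

Virtual widefield fluorescence microscopy of bacteria: a forward
image-formation simulator with perfect ground truth, plus quantification
pipelines for the optical artefacts that bias quantitative microbiology —
cell-size estimation errors, light bleedthrough between cells, and
single-molecule undercounting — and the correction procedures they admit.

## Who this is for

Bacterial cells are about the size of the microscope's point spread
function (PSF) and about as thick as its depth of field. A 2D widefield
image of a cell is therefore a *projection* of differentially defocused
planes, each blurred by the corresponding plane of the 3D PSF. Anyone
measuring cell widths from membrane stains, comparing single-cell
fluorescence across a microcolony, or counting labelled molecules from
snapshots is quantifying through that distortion. This package lets you
simulate your exact imaging scenario — with known geometry, intensity,
and molecule positions — and measure the resulting bias directly, or
derive the correction factor that undoes it.

## The model

A cell is a spherocylinder of radius *r* and pole-to-pole length *L*
(volume π r²(L−2r) + (4/3)π r³), filled or shell-labelled with point
emitters. Image formation is the standard widefield sum of per-plane
convolutions

```
I(x, y) = Σ_z  E(·, ·, z) ⊛ h(·, ·, z − z_focus),
```

with *E* the emitter volume and *h* the 3D PSF aligned to the cell
mid-plane, followed by photon-conserving binning to the camera grid and,
optionally, an sCMOS noise model (baseline 100 ADU, 2.9 ADU/e⁻, dark
variance 8). Four PSFs are available: a scalar-diffraction theoretical
kernel (exact high-NA defocus phase; Airy first minimum at 0.61 λ/NA), an
identity kernel (projection-only control), a parametric long-range
"effective" PSF whose halo reproduces the far-reaching light loss of real
high-NA instruments, and an instrumental kernel averaged from bead
stacks. Depth of field can be truncated plane-by-plane to isolate
projection from diffraction.

On top of the simulator: membrane (interpeak) and cytoplasm (FWHM, Otsu)
width estimators with bias curves and inverse correction factors; a
monolayer colony growth model and per-cell intensity/bleedthrough/CV
analyses; and a coordinate-space single-molecule counting model with
defocus (|z| > 0.25 µm) and Rayleigh-merging (0.61 λ/NA, defocus-
broadened) losses, the optimal-focus-shift correction
δz* = argmax ∫a(z)·D(z−δ)dz, and its reciprocal-overlap count correction.

## Worked example: how badly does a snapshot undercount molecules?

```python
from microvista.counting import merge_probability, typical_cell, undercount_curve

p, se = merge_probability(2, typical_cell(), n_trials=2000, rng=1)
print(f"merge probability (n=2): {100*p:.1f}% +/- {100*se:.1f}%")
print(undercount_curve([5, 15, 30], n_trials=2000, rng=1).round(3).to_string(index=False))
```

prints

```
merge probability (n=2): 4.6% +/- 0.5%
 n_true  mean_counted  undercount_fraction  frac_lost_defocus  frac_lost_diffraction
      5         3.030                0.394              0.368                  0.025
     15         8.040                0.464              0.377                  0.087
     30        13.596                0.547              0.379                  0.168
```

Reading: in a typical 1 × 1 × 5 µm cell, two molecules in the same
snapshot fuse into one spot about 5% of the time; at 15 copies the naive
count is ~46% low. The defocus loss (~38%) is the volume fraction of the
cell outside the 0.25 µm focal slab and is independent of copy number,
while the diffraction-merging loss grows with molecular density — so
undercounting worsens exactly when you need counting most. The same
module computes the focus-shift and reciprocal-overlap corrections, and
the flattened-cell (2 × 0.6 × 5.5 µm) geometry that removes the defocus
term entirely.

A CLI wraps the main pipelines (`microvista psf`, `render`, `layout`,
`size-bias`, `bleedthrough`, `cv-distortion`, `count`); every command
writes a provenance JSON sufficient to re-run it bit-identically.

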