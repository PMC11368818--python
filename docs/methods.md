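# Methods

## The forward model

Widefield epifluorescence of a bacterium is modelled in three stages.

1. **Phantom.** A cell is a spherocylinder (cylinder of radius *r* capped
   by hemispheres, pole-to-pole length *L*), lying in the image plane with
   its mid-plane at the focal plane (*z* = 0). Microfluidically flattened
   cells are the same solid clipped to |*z*| ≤ depth/2. Closed forms are
   used for the volume, π r²(L−2r) + (4/3)π r³, and for the axial
   cross-section a(z) = 2√(r²−z²)(L−2r) + π(r²−z²).

2. **Emitters.** Fluorophores are point emitters: uniform in the hull
   (cytoplasmic labels), uniform in a one-voxel-thick outer shell
   (membrane/wall labels), or exactly *n* points (single-molecule
   studies). Cytoplasmic counts are Poisson with mean density × volume.
   Per-cell densities vary across a population as a normal distribution
   truncated at zero whose location is re-targeted (by root finding on the
   truncated mean) so the realized mean equals the requested mean; the
   scale is CV × mean, so the sample CV matches the requested CV wherever
   truncation is negligible (CV ≲ 0.3).

3. **Image formation.** Emitters are binned into a voxel volume; each
   z-plane is 2D-convolved (FFT, zero padding; a direct-summation path
   exists for verification) with the PSF plane at the same defocus, and
   the planes are summed — the widefield projection. The result is
   block-sum binned to the camera pixel (photon-conserving) and optionally
   passed through an sCMOS model: ADU = baseline + gain·(Poisson(photons)
   + N(0, √dark-variance)), quantized and clipped. Defaults: baseline 100
   ADU, gain 2.9 ADU/e⁻, dark-noise variance 8, 16 bit, camera pixel
   0.065 µm.

Because every stored kernel is normalized to unit 3D sum with equal
per-slice energy, and a widefield detector collects (nearly) all light
from an emitter at any defocus, the layerwise sum is rescaled by the
number of PSF planes — equivalent to per-slice unit normalization. This
makes the noiseless pipeline linear, translation-equivariant, and exactly
flux-conserving up to off-field loss; depth-of-field truncation (zeroing
planes) then removes flux, which is precisely the non-physical
"projection off" control it is meant to be.

### PSF variants

* **Theoretical (tPSF).** Scalar diffraction integral
  U(r,z) = ∫₀¹ J₀(k·NA·r·ρ)·exp(−i·k·n·z·(1−√(1−(NA·ρ/n)²)))·ρ dρ,
  I = |U|², with the exact high-NA defocus optical path (its small-angle
  limit is the familiar paraxial phase). Evaluated by 256-node
  Gauss–Legendre quadrature on a radial grid and interpolated onto the
  voxel grid; the integrand is smooth on [0,1], and the in-focus profile
  reproduces the Airy first minimum at 0.61 λ/NA to grid resolution
  (asserted in tests). Defaults: n = 1.518 immersion oil, matched sample.

* **Identity kernel.** A single unit voxel; convolution degenerates to a
  pure z-projection (the "no diffraction" control).

* **Effective (ePSF).** A per-z parametric radial model, Gaussian core
  A(z)·exp(−r²/2σ(z)²) plus a z-independent long-range tail, fittable on a
  small crop of any sampled kernel and evaluable on an arbitrarily large
  domain. Two tail forms are built in: a power law B/(1+(r/ρ)^γ) (γ > 2,
  used when fitting crops) and a screened-exponential annular halo
  B·exp(−r/s)·r²/(r²+r_i²)/(1+r/r₀).

* **Instrumental (iPSF).** Averaged from a fluorescent-bead z-stack:
  peaks above mean + 5 SD of background on the max-projection, crops
  centred laterally and axially on the intensity peak, averaged,
  background-subtracted and normalized.

### The long-range instrument emulation

Real high-NA widefield systems lose a large share of a small object's
light into a halo extending many micrometres — far beyond what an
aberration-free diffraction model predicts, and beyond the domain over
which an instrument kernel can be measured at usable SNR. The default
long-range ePSF (`effective_psf_longrange`) is therefore a **synthetic
stand-in** for such a measured-and-extrapolated kernel: a
diffraction-limited Gaussian core (σ₀ = 0.21 λ/NA, broadened with defocus
by the Gaussian-beam law, per-slice core energy conserved) plus the
annular halo above with screen 1.5 µm, r₀ = 0.2 µm, inner radius 2.0 µm,
carrying 70% of the total energy (enforced on the rasterized domain,
intended extent 12 µm).

The three halo constants were fixed once, against two instrument
characteristics of the emulated 1.49 NA system: an isolated 1-µm-wide
cell retains only ~30% of its true intensity inside its own boundary, and
cell-to-cell bleedthrough falls below ~1% at 10 µm separation. All other
colony- and array-level numbers the package produces (colony-size trend,
brightness fold of ~100-cell colonies, CV crossover) are predictions of
the calibrated model, not inputs. Consequences of the model form worth
knowing: the halo is isotropic and z-independent, and a touching-pitch
5×5 array of 5-µm cells recaptures most of it, so the touching-pitch
bleedthrough comes out near +160% — a figure sensitive to the halo shape
and to the array size used for the measurement.

## Quantification pipelines

**Size.** Radial intensity profiles are sampled perpendicular to the cell
axis at mid-length with sub-pixel interpolation, averaged over a 3-pixel
band along the axis (configurable; wide bands are useful on noisy
cytoplasmic profiles). Width estimators: (i) *interpeak* — the two
dominant maxima on opposite sides of the centre, each refined by a local
quadratic fit; a profile without such a pair returns an explicit
`unresolved` status rather than a number, which is what produces the
narrow-cell/long-wavelength failure regime; (ii) *FWHM* — half-maximum
crossings by linear interpolation above a far-field-median baseline
(pure projection of a uniform cylinder gives FWHM = √3·r, a closed form
the tests pin); (iii) *Otsu* — threshold, largest component,
principal-axis extents. `width_bias_curve` sweeps true widths through the
forward simulation; `width_correction_factor` inverts the monotone
observed(true) mapping by interpolation and refuses observations outside
the simulated range.

**Intensity.** Per-cell means are taken over ground-truth masks (sum /
area); background subtraction removes the mean of the lowest 5% of
pixels. Colony position metrics follow common practice: d_c/D is the
centroid distance to the mean cell centroid normalized by the colony's
maximum Feret radius; neighbour degree comes from dilating all masks by
4 px and reading node degrees off the region-adjacency graph. Array
bleedthrough uses the linearity of the noiseless pipeline: the same
layout is rendered with all cells labelled and with only the centre cell
labelled (same per-cell random streams), and the bleedthrough is the
neighbours' light inside the centre mask relative to the cell's own —
this cancels pixel-alignment effects exactly. Richardson–Lucy
deconvolution (100 iterations by default) is provided as the control
showing that a kernel as large as the data is needed to reassign
long-range light.

**Counting.** The naive counting model operates on molecule coordinates.
Molecules farther than 0.25 µm from the focal plane are lost to defocus;
the remainder merge by single linkage when their projected xy separation
is within the defocus-broadened Rayleigh distance (mean of the two
molecules' w(z) = r₀√(1+(z/z_R)²), r₀ = 0.61 λ/NA, z_R = π r₀² n/λ);
counted = singles + one per cluster. The defocus filter runs before
merging (a molecule too dim to detect cannot merge), and the ordering is
switchable for sensitivity analysis. The two-molecule merge probability
is, by default, computed over *all* molecules regardless of depth —
in a 2D projection spots coalesce whatever their z — which is the reading
that matches the filter-first partition elsewhere producing the expected
n = 15 undercount. Corrections: δz_optimal maximizes ∫a(z)·D(z−δ)dz on a
dense shift scan (ties toward |δ| = 0); the correction factor is
(∫a)/(∫a·D(z−δ)); MACS flattening replaces the geometry with a
2 × 0.6 × 5.5 µm slab-clipped spherocylinder. D(z) itself is estimated by
Monte Carlo: the peak-pixel SNR of the z-defocused kernel at a given
photon budget against the 99th percentile of the background SNR, chance-
corrected so a dark emitter has D = 0.

**Colony growth.** An intentionally simple overdamped agent model stands
in for a full mechanical simulator: spherocylinders of constant 1 µm
width elongate by 3% per step, divide symmetrically at a per-division
target of 3.5 µm + U(−0.25, 0.25) µm into daughters separated by a
0.1 µm septum gap and inheriting orientation with 2° noise; overlaps are
resolved each step by pairwise repulsion along the closest-point normal
with a weak torque, using spatial hashing, under-relaxation (0.8), and an
iteration cap that raises if residual overlap exceeds a quarter radius.
Downstream intensity analyses depend only on dense monolayer geometry;
these colonies are statistically, not mechanically, equivalent to real
ones (they come out somewhat more elongated than isotropic colonies,
which slightly broadens the d_c/D distribution).

## Default problem sizes

Chosen as the package's standard operating points: single-cell size
analyses render at a 0.02 µm lateral voxel and 0.05 µm axial step (fine
enough that interpeak and FWHM estimates are grid-converged to well under
the biases being measured; a 0.01 µm mode exists and shifts results by
<1%). Colony and array intensity analyses render at the camera pixel
(0.065 µm) with a 0.25 µm axial step and a 12 µm kernel extent, matching
the halo's intended domain. The bundled intensity-trend study grows one
colony to 1000 cells and reads the ~100-cell snapshot from the same
lineage; CV-distortion curves replicate colonies of 20–250 cells about
ten times per CV point. Monte-Carlo counting statistics use 2000–3000
trials (standard error ≲ 0.5 pp on the merge probability).

## What the synthetic data do and do not show

The generator reproduces the geometry and statistics the analyses assume:
monolayer colonies, uniform or shell-confined emitters, truncated-normal
expression variation, Poisson shot noise and Gaussian dark noise. It does
not model sample scattering, field-dependent aberrations, photobleaching,
spectral crosstalk, 3D (multi-layer) colonies, or deformable/septating
cell shapes. Passing tests therefore demonstrate correctness of the
optical bookkeeping and the estimators under the stated model — not that
a particular real instrument's biases are numerically identical. In
particular, the membrane-width biases computed with the aberration-free
theoretical kernel (≈9% at 1 µm width, ≈27% at 0.5 µm, two-peak cutoff
near 0.40–0.45 µm at 700 nm for a 1.45 NA system) are smaller than those
measured with real instrument kernels, whose aberration and bead-size
broadening pull the membrane peaks further inward; that gap is a
statement about instruments, not a numerical artefact — it is invariant
under the paraxial/exact-defocus/vectorial model variants and under grid
refinement.

## Numerical choices and degenerate inputs

Quadrature: 256-node Gauss–Legendre for the diffraction integral
(converged ≲ 1e-10); trapezoidal rule on ≥ 500-point grids for a(z) and
overlap integrals. Peak refinement: local quadratic through three
samples; flat or boundary peaks fall back to the grid position. Otsu and
Richardson–Lucy delegate to scikit-image behind the module surface; RL
inputs are validated nonnegative (with a 1e-9 relative allowance for FFT
round-off) and the kernel renormalized. Mask rasterization labels a
camera pixel when ≥ 50% of its area (4×4 subsampling) lies inside the
cell footprint; overlaps keep the earlier cell id. Degenerate inputs
raise rather than guess: empty masks, zero-sum kernels, non-monotone bias
curves, observations outside the invertible range, disjoint a(z)/D(z)
supports, voxel sizes coarser than the cell radius.
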