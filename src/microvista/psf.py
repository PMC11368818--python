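"""Point-spread-function models and derived optical quantities.

Four PSF variants are supported, mirroring common practice in widefield
quantification work:

* a **theoretical** scalar-diffraction PSF (Born–Wolf form with the
  high-NA defocus phase), computed by numerical quadrature;
* an **identity** kernel — the "no diffraction" control that reduces the
  imaging pipeline to a pure z-projection;
* an **effective** PSF (ePSF): a per-z parametric radial model (Gaussian
  core + power-law tail) that can be fitted on a small crop and evaluated
  on an arbitrarily large domain, used to emulate the long-range tails of
  real high-NA instruments;
* an **instrumental** PSF averaged from a fluorescent-bead z-stack.

Also provided: the Rayleigh radius 0.61 λ/NA, Gaussian-beam defocus
broadening, and the depth-dependent detection probability D(z) used by the
single-molecule counting analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import curve_fit
from scipy.special import j0

__all__ = [
    "OpticsConfig",
    "PSF3D",
    "DetectionProfile",
    "EffectivePSF",
    "theoretical_psf",
    "identity_psf",
    "fit_effective_psf",
    "effective_psf_longrange",
    "process_bead_stack",
    "rayleigh_radius",
    "defocus_broadened_radius",
    "detection_probability_profile",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Microscope optics parameters (µm units unless noted)."""

    wavelength_um: float = 0.55
    na: float = 1.49
    n_immersion: float = 1.518
    working_distance_mm: float = 0.17
    pixel_size_um: float = 0.065
    z_step_um: float = 0.05

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if not 0 < self.na < self.n_immersion:
            raise ValueError(
                f"need 0 < NA ({self.na}) < n_immersion ({self.n_immersion})"
            )


def rayleigh_radius(optics: OpticsConfig) -> float:
    """First-minimum (Rayleigh) radius 0.61 λ / NA in µm."""
    return 0.61 * optics.wavelength_um / optics.na


def defocus_broadened_radius(r0: float, z_um: float, optics: OpticsConfig) -> float:
    """Gaussian-beam broadening of an in-focus radius r0 at defocus z.

    w(z) = r0 * sqrt(1 + (z / z_R)^2) with Rayleigh range
    z_R = pi * r0^2 * n / λ.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    z_r = math.pi * r0 * r0 * optics.n_immersion / optics.wavelength_um
    return r0 * math.sqrt(1.0 + (z_um / z_r) ** 2)


@dataclass
class PSF3D:
    """A normalized 3D intensity kernel on a voxel grid, indexed [z, y, x]."""

    data: np.ndarray
    voxel_xy_um: float
    voxel_z_um: float
    focal_plane_index: int
    provenance: str = "theoretical"
    optics: OpticsConfig | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("PSF3D data must be 3D [z, y, x]")
        if np.any(self.data < 0):
            raise ValueError("PSF intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def normalize(self) -> "PSF3D":
        s = self.data.sum()
        if s <= 0:
            raise ValueError("cannot normalize a zero PSF")
        self.data = self.data / s
        return self

    def z_offsets_um(self) -> np.ndarray:
        nz = self.data.shape[0]
        return (np.arange(nz) - self.focal_plane_index) * self.voxel_z_um


def _radial_grid(ny: int, nx: int, voxel_um: float) -> np.ndarray:
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y = (np.arange(ny) - cy) * voxel_um
    x = (np.arange(nx) - cx) * voxel_um
    return np.hypot.outer(y, x)


_GL_NODES, _GL_WEIGHTS = leggauss(256)
_GL_RHO = 0.5 * (_GL_NODES + 1.0)  # map [-1,1] -> [0,1]
_GL_W = 0.5 * _GL_WEIGHTS


def born_wolf_radial(
    r_um: np.ndarray, z_um: float, optics: OpticsConfig
) -> np.ndarray:
    """Scalar Born–Wolf intensity profile I(r; z), unnormalized.

    U(r, z) = ∫_0^1 J0(k NA r ρ) exp(-i k n z (1 - sqrt(1 - (NA ρ / n)²))) ρ dρ,
    I = |U|², with k = 2π/λ.  The defocus phase is the exact optical path
    difference for a high-NA objective (its small-angle limit is the
    familiar paraxial k z ρ² NA²/(2n)).  Evaluated by 256-node
    Gauss–Legendre quadrature, converged to better than 1e-10 for the
    radii and defocus values used here.
    """
    k = 2.0 * math.pi / optics.wavelength_um
    r = np.atleast_1d(np.asarray(r_um, dtype=float))
    arg = k * optics.na * np.outer(r, _GL_RHO)
    sin2 = (optics.na * _GL_RHO / optics.n_immersion) ** 2
    phase = k * optics.n_immersion * z_um * (1.0 - np.sqrt(np.clip(1.0 - sin2, 0.0, None)))
    integ = j0(arg) * (_GL_RHO * _GL_W)
    re = integ @ np.cos(phase)
    im = integ @ np.sin(phase)
    return re * re + im * im


def theoretical_psf(
    optics: OpticsConfig,
    grid_shape: tuple[int, int, int],
    voxel_xy_um: float | None = None,
    voxel_z_um: float | None = None,
) -> PSF3D:
    """Generate a scalar-diffraction widefield PSF on a voxel grid.

    ``grid_shape`` is (nz, ny, nx); odd lateral dimensions keep the kernel
    laterally centred.  The kernel is normalized to unit 3D sum.
    """
    nz, ny, nx = grid_shape
    dxy = voxel_xy_um if voxel_xy_um is not None else optics.pixel_size_um
    dz = voxel_z_um if voxel_z_um is not None else optics.z_step_um
    rr = _radial_grid(ny, nx, dxy)
    r_fine = np.arange(0.0, rr.max() + 2 * dxy, max(dxy / 2.0, 1e-4))
    focal = (nz - 1) // 2
    data = np.empty((nz, ny, nx))
    for iz in range(nz):
        z = (iz - focal) * dz
        prof = born_wolf_radial(r_fine, z, optics)
        data[iz] = np.interp(rr, r_fine, prof)
    psf = PSF3D(data, dxy, dz, focal, "theoretical", optics)
    return psf.normalize()


def identity_psf(grid_shape: tuple[int, int, int] = (1, 1, 1)) -> PSF3D:
    """Identity kernel: a single unit voxel at the grid centre.

    Convolving any volume with it reproduces the volume — the control for
    a hypothetical diffraction-free microscope.
    """
    if any(s % 2 == 0 for s in grid_shape):
        raise ValueError("identity PSF requires odd grid dimensions")
    data = np.zeros(grid_shape)
    c = tuple(s // 2 for s in grid_shape)
    data[c] = 1.0
    return PSF3D(data, 1.0, 1.0, c[0], "identity", None)


# ---------------------------------------------------------------------------
# Effective (long-range) PSF
# ---------------------------------------------------------------------------


@dataclass
class EffectivePSF:
    """Parametric per-z radial PSF model: Gaussian core + long-range tail.

    I(r, z) = A(z) exp(-r² / (2 σ(z)²)) + tail(r)

    with a pluggable tail form:

    * ``powerlaw``:     tail(r) = B / (1 + (r/ρ)^γ)   (γ > 2: integrable)
    * ``exp_screened``: tail(r) = B exp(-r/γ̃) / (1 + r/ρ)  — a screened
      exponential halo whose 2D mass density is nearly flat out to the
      screening length, matching the broad annular halo of high-NA
      instruments.

    The tail is z-independent: defocus redistributes the core, while the
    long-range halo of real systems comes from aberrations and stray
    light that vary slowly with focus.  When ``tail_fraction_target`` is
    set, rasterization rescales the tail so it carries exactly that
    fraction of the kernel's energy on the rasterized domain — so the
    kernel should be evaluated out to the intended tail extent.
    """

    z_um: np.ndarray
    core_amplitude: np.ndarray
    core_sigma_um: np.ndarray
    tail_amplitude: float
    tail_rho_um: float
    tail_gamma: float
    tail_form: str = "powerlaw"
    tail_inner_um: float = 0.0
    tail_fraction_target: float | None = None
    optics: OpticsConfig | None = None
    provenance: str = "effective"

    def _tail(self, r: np.ndarray) -> np.ndarray:
        if self.tail_form == "powerlaw":
            return self.tail_amplitude / (1.0 + (r / self.tail_rho_um) ** self.tail_gamma)
        if self.tail_form == "exp_screened":
            if self.tail_inner_um > 0:
                inner = r * r / (r * r + self.tail_inner_um**2)
            else:
                inner = 1.0
            return (
                self.tail_amplitude
                * np.exp(-r / self.tail_gamma)
                * inner
                / (1.0 + r / self.tail_rho_um)
            )
        raise ValueError(f"unknown tail form {self.tail_form!r}")

    def radial(self, r_um: np.ndarray, z_um: float) -> np.ndarray:
        r = np.asarray(r_um, dtype=float)
        a = np.interp(z_um, self.z_um, self.core_amplitude, left=0.0, right=0.0)
        s = np.interp(
            z_um, self.z_um, self.core_sigma_um,
            left=self.core_sigma_um[0], right=self.core_sigma_um[-1],
        )
        core = a * np.exp(-(r * r) / (2.0 * s * s))
        in_z = self.z_um.min() - 1e-9 <= z_um <= self.z_um.max() + 1e-9
        tail = self._tail(r) if in_z else np.zeros_like(r)
        return core + tail

    def rasterize(
        self,
        grid_shape: tuple[int, int, int],
        voxel_xy_um: float,
        voxel_z_um: float,
    ) -> PSF3D:
        """Evaluate on a voxel grid and renormalize to unit sum."""
        nz, ny, nx = grid_shape
        rr = _radial_grid(ny, nx, voxel_xy_um)
        focal = (nz - 1) // 2
        core = np.empty((nz, ny, nx))
        tail = np.empty((nz, ny, nx))
        for iz in range(nz):
            z = (iz - focal) * voxel_z_um
            a = np.interp(z, self.z_um, self.core_amplitude, left=0.0, right=0.0)
            s = np.interp(
                z, self.z_um, self.core_sigma_um,
                left=self.core_sigma_um[0], right=self.core_sigma_um[-1],
            )
            core[iz] = a * np.exp(-(rr * rr) / (2.0 * s * s))
            in_z = self.z_um.min() - 1e-9 <= z <= self.z_um.max() + 1e-9
            tail[iz] = self._tail(rr) if in_z else 0.0
        if self.tail_fraction_target is not None and tail.sum() > 0:
            f = self.tail_fraction_target
            tail *= (f / (1.0 - f)) * core.sum() / tail.sum()
        psf = PSF3D(core + tail, voxel_xy_um, voxel_z_um, focal,
                    self.provenance, self.optics)
        return psf.normalize()


def _core_tail_model(r, a, sigma, b, rho, gamma):
    return a * np.exp(-(r * r) / (2.0 * sigma * sigma)) + b / (
        1.0 + (r / rho) ** gamma
    )


def fit_effective_psf(
    psf_crop: PSF3D,
    model_form: str = "gauss_core_powerlaw_tail",
    max_rel_residual: float = 0.5,
) -> EffectivePSF:
    """Fit the parametric ePSF model to (a crop of) a sampled PSF.

    Each z-slice is radially averaged; the Gaussian core is fitted per z,
    and the power-law tail parameters are fitted globally on the in-focus
    slice's profile beyond the core.  Raises if the in-focus fit residual
    exceeds ``max_rel_residual`` (relative RMS).
    """
    if model_form != "gauss_core_powerlaw_tail":
        raise ValueError(f"unknown ePSF model form {model_form!r}")
    nz, ny, nx = psf_crop.shape
    rr = _radial_grid(ny, nx, psf_crop.voxel_xy_um)
    nbins = max(ny, nx) // 2
    r_edges = np.linspace(0, rr.max(), nbins + 1)
    r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])

    def radial_mean(sl: np.ndarray) -> np.ndarray:
        idx = np.clip(np.digitize(rr.ravel(), r_edges) - 1, 0, nbins - 1)
        sums = np.bincount(idx, weights=sl.ravel(), minlength=nbins)
        cnts = np.bincount(idx, minlength=nbins)
        return sums / np.maximum(cnts, 1)

    z_off = psf_crop.z_offsets_um()
    focal = psf_crop.focal_plane_index

    # global tail fit on the in-focus slice
    prof0 = radial_mean(psf_crop.data[focal])
    p0 = [prof0[0], 0.2 * rayleigh_radius(psf_crop.optics) if psf_crop.optics else 0.05,
          max(prof0[-1], 1e-12) , max(r_mid[-1] / 4, 0.05), 3.0]
    bounds = ([0, 1e-4, 0, 1e-3, 2.05], [np.inf, 10.0, np.inf, 50.0, 8.0])
    try:
        popt, _ = curve_fit(
            _core_tail_model, r_mid, prof0, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"ePSF tail fit failed to converge: {exc}") from exc
    _, _, b, rho, gamma = popt
    resid = np.sqrt(np.mean((_core_tail_model(r_mid, *popt) - prof0) ** 2))
    rel = resid / max(prof0.max(), 1e-300)
    if rel > max_rel_residual:
        raise RuntimeError(
            f"ePSF in-focus fit residual {rel:.3g} exceeds tolerance "
            f"{max_rel_residual}"
        )

    # per-z Gaussian core on the tail-subtracted profiles
    amps = np.empty(nz)
    sigmas = np.empty(nz)
    for iz in range(nz):
        prof = radial_mean(psf_crop.data[iz]) - b / (1.0 + (r_mid / rho) ** gamma)
        prof = np.clip(prof, 0, None)
        peak = max(prof[0], 1e-300)
        try:
            (a_fit, s_fit), _ = curve_fit(
                lambda r, a, s: a * np.exp(-(r * r) / (2 * s * s)),
                r_mid,
                prof,
                p0=[peak, max(popt[1], 1e-3)],
                bounds=([0, 1e-4], [np.inf, 20.0]),
                maxfev=10000,
            )
        except RuntimeError:
            a_fit, s_fit = peak, popt[1]
        amps[iz], sigmas[iz] = a_fit, s_fit
    return EffectivePSF(z_off, amps, sigmas, b, rho, gamma,
                        tail_form="powerlaw", optics=psf_crop.optics)


def effective_psf_longrange(
    optics: OpticsConfig | None = None,
    z_extent_um: float = 2.0,
    z_step_um: float = 0.05,
    tail_fraction: float = 0.70,
    tail_screen_um: float = 1.5,
    tail_r0_um: float = 0.2,
    tail_inner_um: float = 2.0,
    tail_extent_um: float = 12.0,
) -> EffectivePSF:
    """Construct the default long-range effective PSF of a high-NA system.

    The Gaussian core follows the diffraction-limited in-focus width
    (σ0 ≈ 0.21 λ/NA, the Gaussian equivalent of the Airy core) broadened
    with defocus by the Gaussian-beam law, with per-slice core energy
    conserved.  A screened-exponential halo,
    tail(r) ∝ exp(-r/tail_screen_um) * r² / (r² + tail_inner_um²)
              / (1 + r/tail_r0_um),
    an annular halo carrying ``tail_fraction`` of the total energy
    (enforced at rasterization, intended for kernels evaluated out to
    ``tail_extent_um``).

    The tail constants emulate the characteristics the target class of
    1.49 NA widefield systems exhibits: an isolated 1-µm-wide cell retains
    only ~30% of its true intensity within its own boundary, and
    cell-to-cell bleedthrough becomes negligible (<1%) beyond ~10 µm.
    This is a synthetic stand-in for a bead-measured instrument kernel;
    the constants are instrument characteristics, not fit results.
    """
    optics = optics or OpticsConfig(wavelength_um=0.55, na=1.49)
    z = np.arange(-z_extent_um, z_extent_um + z_step_um / 2, z_step_um)
    sigma0 = 0.21 * optics.wavelength_um / optics.na
    sigmas = np.array([defocus_broadened_radius(sigma0, zz, optics) for zz in z])
    amps = (sigma0 / sigmas) ** 2  # conserve per-slice core energy
    return EffectivePSF(
        z, amps, sigmas, 1.0, tail_r0_um, tail_screen_um,
        tail_form="exp_screened", tail_inner_um=tail_inner_um,
        tail_fraction_target=tail_fraction, optics=optics,
    )


# ---------------------------------------------------------------------------
# Instrumental PSF from bead stacks
# ---------------------------------------------------------------------------


def process_bead_stack(
    stack: np.ndarray,
    voxel_xy_um: float,
    voxel_z_um: float,
    bead_peak_min_separation: int = 15,
    crop_half: int | None = None,
    optics: OpticsConfig | None = None,
) -> PSF3D:
    """Average isolated beads in a z-stack into a low-noise instrumental PSF.

    Peaks are detected on the max-projection above mean + 5 SD of the
    background; each bead is cropped, centred on its intensity peak
    (laterally and axially), averaged, background-subtracted and
    normalized.  The best-focus plane is the z-slice with the highest peak
    intensity (which for a well-sampled bead also has the narrowest FWHM).
    """
    from skimage.feature import peak_local_max

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("bead stack must be 3D [z, y, x]")
    bg = np.median(stack)
    noise_sd = 1.4826 * np.median(np.abs(stack - bg))
    thresh = bg + 5.0 * max(noise_sd, 1e-12)
    proj = stack.max(axis=0)
    peaks = peak_local_max(
        proj, min_distance=bead_peak_min_separation, threshold_abs=thresh
    )
    if len(peaks) == 0:
        raise ValueError("no bead peaks found above the noise threshold")
    ch = crop_half if crop_half is not None else bead_peak_min_separation // 2
    nz = stack.shape[0]
    crops = []
    for (py, px) in peaks:
        if not (ch <= py < proj.shape[0] - ch and ch <= px < proj.shape[1] - ch):
            continue
        sub = stack[:, py - ch : py + ch + 1, px - ch : px + ch + 1]
        zpk = int(np.argmax(sub.max(axis=(1, 2))))
        # recentre axially on the peak plane; pad with background
        shifted = np.full_like(sub, bg)
        src_lo, src_hi = max(0, zpk - nz // 2), min(nz, zpk + (nz - nz // 2))
        dst_lo = nz // 2 - (zpk - src_lo)
        shifted[dst_lo : dst_lo + (src_hi - src_lo)] = sub[src_lo:src_hi]
        crops.append(shifted)
    if not crops:
        raise ValueError("no bead fully inside the field at the requested crop size")
    mean_crop = np.mean(crops, axis=0) - bg
    mean_crop = np.clip(mean_crop, 0, None)
    focal = int(np.argmax(mean_crop.max(axis=(1, 2))))
    psf = PSF3D(mean_crop, voxel_xy_um, voxel_z_um, focal, "instrumental", optics)
    return psf.normalize()


# ---------------------------------------------------------------------------
# Detection probability D(z)
# ---------------------------------------------------------------------------


@dataclass
class DetectionProfile:
    """Depth-dependent single-molecule detection probability."""

    z_um: np.ndarray
    D: np.ndarray
    snr_threshold: float
    photons_assumed: float

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if np.any((self.D < 0) | (self.D > 1)):
            raise ValueError("D(z) must lie in [0, 1]")

    def at(self, z_um: np.ndarray) -> np.ndarray:
        return np.interp(z_um, self.z_um, self.D, left=0.0, right=0.0)


def detection_probability_profile(
    psf: PSF3D,
    photons: float,
    camera=None,
    snr_threshold_quantile: float = 0.99,
    n_trials: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> DetectionProfile:
    """Monte-Carlo detection probability of a point emitter vs defocus.

    At each axial offset the emitter's image is the corresponding PSF
    slice; its peak pixel receives ``photons * peak_fraction(z)`` expected
    photons.  A molecule is detected when its peak-pixel SNR (signal above
    baseline over the background SD) exceeds the ``snr_threshold_quantile``
    quantile of the background SNR distribution.  The reported D(z) is
    chance-corrected so that a zero-photon emitter has D = 0.
    """
    from .imaging import CameraModel

    if photons < 0:
        raise ValueError("photons must be >= 0")
    camera = camera or CameraModel()
    rng = np.random.default_rng(rng)
    z = psf.z_offsets_um()
    slice_sums = psf.data.sum(axis=(1, 2))
    peak_frac = np.where(
        slice_sums > 0, psf.data.max(axis=(1, 2)) / np.maximum(slice_sums, 1e-300), 0.0
    )
    sigma_bg = camera.sensitivity_adu_per_electron * math.sqrt(
        max(camera.dark_noise_variance, 1e-12)
    )
    # background SNR threshold (analytic for the Gaussian dark-noise model)
    from scipy.stats import norm

    thr = norm.ppf(snr_threshold_quantile)
    alpha = 1.0 - snr_threshold_quantile
    D = np.zeros_like(z)
    if photons > 0:
        for i, pf in enumerate(peak_frac):
            s = photons * pf
            sig = rng.poisson(s, n_trials) + rng.normal(
                0.0, math.sqrt(camera.dark_noise_variance), n_trials
            )
            snr = (
                camera.sensitivity_adu_per_electron * sig
            ) / sigma_bg
            p_hat = float(np.mean(snr > thr))
            D[i] = min(max((p_hat - alpha) / (1.0 - alpha), 0.0), 1.0)
    if D.max() == 0:
        warnings.warn(
            "photon budget too low: D(z) is identically zero", stacklevel=2
        )
    return DetectionProfile(z, D, thr, photons)
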