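"""The virtual widefield microscope: layer-wise 3D convolution, depth-of-field
control, camera binning and sensor noise.

Image formation follows the standard widefield model: fluorophores at each
axial plane of the sample are blurred by the matching plane of the 3D PSF
and all planes are summed (projected) onto the detector,

    image(x, y) = sum_z  volume(., ., z) (*) psf(., ., z - z_focus),

with the PSF mid-plane aligned to the cell mid-plane by default.  The
pipeline is linear in the emitters, conserves flux up to off-field loss,
and reduces exactly to a z-projection when the PSF is the identity kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import convolve2d, fftconvolve

from .geometry import Spherocylinder, sample_emitters
from .psf import PSF3D, EffectivePSF

__all__ = [
    "CameraModel",
    "SyntheticImagePair",
    "convolve_layerwise",
    "restrict_depth_of_field",
    "downsample_to_camera",
    "apply_camera_noise",
    "bin_emitters",
    "render_masks",
    "render_scene",
]


@dataclass(frozen=True)
class CameraModel:
    """sCMOS-style sensor: ADU = baseline + gain * (shot noise + dark noise)."""

    baseline_adu: float = 100.0
    sensitivity_adu_per_electron: float = 2.9
    dark_noise_variance: float = 8.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if min(self.baseline_adu, self.sensitivity_adu_per_electron,
               self.dark_noise_variance) < 0:
            raise ValueError("camera parameters must be nonnegative")


def convolve_layerwise(
    volume: np.ndarray,
    psf: PSF3D,
    voxel_xy_um: float,
    voxel_z_um: float,
    focal_offset_um: float = 0.0,
    method: str = "fft",
) -> np.ndarray:
    """Sum of per-plane 2D convolutions of a 3D emitter volume with a 3D PSF.

    ``volume`` is indexed [z, y, x]; its mid-plane is aligned with the PSF
    focal plane shifted by ``focal_offset_um``.  Output has the lateral
    shape of the volume ("same" convolution); light diffracted beyond the
    field is lost, as on a real detector.

    A widefield detector collects (nearly) all light from an emitter at
    any defocus, so each PSF z-slice must carry unit 2D energy in this
    sum.  Stored kernels are normalized to unit 3D sum with equal
    per-slice energy, so the layerwise result is rescaled by the number of
    PSF planes; planes zeroed by depth-of-field truncation then remove
    flux, exactly as intended.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D [z, y, x]")
    if psf.provenance != "identity":
        if not math.isclose(psf.voxel_xy_um, voxel_xy_um, rel_tol=1e-6):
            raise ValueError(
                f"lateral voxel mismatch: volume {voxel_xy_um} vs PSF "
                f"{psf.voxel_xy_um}"
            )
        if not math.isclose(psf.voxel_z_um, voxel_z_um, rel_tol=1e-6):
            raise ValueError(
                f"axial voxel mismatch: volume {voxel_z_um} vs PSF "
                f"{psf.voxel_z_um}"
            )
    nz = volume.shape[0]
    out = np.zeros(volume.shape[1:])
    zc = (nz - 1) / 2.0
    for iz in range(nz):
        plane = volume[iz]
        if not plane.any():
            continue
        if psf.provenance == "identity":
            out += plane
            continue
        z_um = (iz - zc) * voxel_z_um - focal_offset_um
        ipsf = psf.focal_plane_index + int(round(z_um / psf.voxel_z_um))
        if not 0 <= ipsf < psf.data.shape[0]:
            raise ValueError(
                f"PSF z-extent too small: needed slice at offset {z_um:.3f} µm"
            )
        kern = psf.data[ipsf]
        if not kern.any():
            continue
        if method == "fft":
            out += fftconvolve(plane, kern, mode="same")
        else:
            out += convolve2d(plane, kern, mode="same")
    if psf.provenance != "identity":
        out *= psf.data.shape[0]
    return out


def restrict_depth_of_field(psf: PSF3D, dof_um: float) -> PSF3D:
    """Zero all PSF planes farther than dof/2 from focus (not renormalized).

    This is the deliberately non-physical projection control: truncating
    planes removes out-of-focus flux instead of redistributing it.
    """
    if dof_um <= 0:
        raise ValueError("dof_um must be positive")
    z = psf.z_offsets_um()
    keep = np.abs(z) <= dof_um / 2.0 + 1e-12
    data = psf.data * keep[:, None, None]
    return PSF3D(
        data, psf.voxel_xy_um, psf.voxel_z_um, psf.focal_plane_index,
        psf.provenance, psf.optics,
    )


def downsample_to_camera(image_highres: np.ndarray, factor: int) -> np.ndarray:
    """Photon-conserving block-sum binning to the camera pixel grid."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    img = np.asarray(image_highres, dtype=float)
    if factor == 1:
        return img.copy()
    ny, nx = img.shape
    py, px = (-ny) % factor, (-nx) % factor
    if py or px:
        warnings.warn(
            f"image shape {img.shape} not divisible by {factor}; zero-padding",
            stacklevel=2,
        )
        img = np.pad(img, ((0, py), (0, px)))
    ny, nx = img.shape
    return img.reshape(ny // factor, factor, nx // factor, factor).sum(axis=(1, 3))


def apply_camera_noise(
    photon_image: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Convert an expected-photon image to noisy integer ADU counts.

    ADU = baseline + gain * (Poisson(photons) + N(0, sqrt(dark_variance))),
    quantized and clipped to the sensor bit depth.
    """
    img = np.asarray(photon_image, dtype=float)
    if np.any(img < 0):
        raise ValueError("photon image must be nonnegative")
    rng = np.random.default_rng(rng)
    electrons = rng.poisson(img).astype(float)
    electrons += rng.normal(0.0, math.sqrt(camera.dark_noise_variance), img.shape)
    adu = camera.baseline_adu + camera.sensitivity_adu_per_electron * electrons
    return np.clip(np.rint(adu), 0, 2**camera.bit_depth - 1).astype(np.uint16)


def bin_emitters(
    positions_xyz_um: np.ndarray,
    weights: np.ndarray | float,
    shape_zyx: tuple[int, int, int],
    origin_xyz_um: tuple[float, float, float],
    voxel_xy_um: float,
    voxel_z_um: float,
) -> np.ndarray:
    """Accumulate point emitters into a 3D photon-count volume [z, y, x]."""
    pos = np.atleast_2d(positions_xyz_um)
    nz, ny, nx = shape_zyx
    vol = np.zeros(shape_zyx)
    if len(pos) == 0:
        return vol
    ix = np.floor((pos[:, 0] - origin_xyz_um[0]) / voxel_xy_um).astype(int)
    iy = np.floor((pos[:, 1] - origin_xyz_um[1]) / voxel_xy_um).astype(int)
    iz = np.floor((pos[:, 2] - origin_xyz_um[2]) / voxel_z_um).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    w = np.broadcast_to(np.asarray(weights, dtype=float), (len(pos),))
    np.add.at(vol, (iz[ok], iy[ok], ix[ok]), w[ok])
    return vol


def _footprint_highres(
    cell: Spherocylinder,
    shape_yx: tuple[int, int],
    origin_xy_um: tuple[float, float],
    voxel_xy_um: float,
) -> np.ndarray:
    """Boolean 2D capsule footprint of a cell at high resolution."""
    ny, nx = shape_yx
    xs = origin_xy_um[0] + (np.arange(nx) + 0.5) * voxel_xy_um
    ys = origin_xy_um[1] + (np.arange(ny) + 0.5) * voxel_xy_um
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    local = cell.to_local(pts)
    a = cell.half_axis_um
    ax = np.clip(local[:, 0], -a, a)
    d2 = (local[:, 0] - ax) ** 2 + local[:, 1] ** 2
    return (d2 <= cell.radius_um**2).reshape(ny, nx)


def render_masks(
    cells: list[Spherocylinder],
    field_size_px: tuple[int, int],
    pixel_size_um: float,
    oversample: int = 4,
) -> np.ndarray:
    """Ground-truth labelled masks at camera resolution.

    A camera pixel is labelled with a cell id when >= 50% of its area lies
    inside that cell's footprint; overlaps keep the earlier cell id.
    """
    ny, nx = field_size_px
    hi = pixel_size_um / oversample
    labels = np.zeros((ny, nx), dtype=np.int32)
    for idx, cell in enumerate(cells):
        cx, cy = cell.center_xyz_um[0], cell.center_xyz_um[1]
        ext = cell.length_um / 2.0 + cell.radius_um + pixel_size_um
        x0 = max(int((cx - ext) / pixel_size_um), 0)
        x1 = min(int(np.ceil((cx + ext) / pixel_size_um)), nx)
        y0 = max(int((cy - ext) / pixel_size_um), 0)
        y1 = min(int(np.ceil((cy + ext) / pixel_size_um)), ny)
        if x1 <= x0 or y1 <= y0:
            continue
        fp = _footprint_highres(
            cell,
            ((y1 - y0) * oversample, (x1 - x0) * oversample),
            (x0 * pixel_size_um, y0 * pixel_size_um),
            hi,
        )
        frac = fp.reshape(y1 - y0, oversample, x1 - x0, oversample).mean(axis=(1, 3))
        sub = labels[y0:y1, x0:x1]
        sel = (frac >= 0.5) & (sub == 0)
        sub[sel] = cell.cell_id if cell.cell_id > 0 else idx + 1
    return labels


@dataclass
class SyntheticImagePair:
    """A rendered image with its perfect ground truth."""

    image: np.ndarray
    masks: np.ndarray
    truth: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.masks.shape:
            raise ValueError("image and masks must share shape")


def render_scene(
    layout,
    psf: PSF3D | EffectivePSF,
    camera: CameraModel | None = None,
    dof_um: float | None = None,
    rng: np.random.Generator | int | None = None,
    noise: bool = False,
    voxel_xy_um: float = 0.0325,
    voxel_z_um: float = 0.1,
    photons_per_emitter: float = 1.0,
    label_kind: str = "cytoplasm",
    kernel_extent_um: float | None = None,
) -> SyntheticImagePair:
    """Render a full scene: emitters -> layerwise convolution -> camera image.

    ``layout`` is a :class:`~microvista.layouts.SceneLayout`.  The
    high-resolution lateral voxel is snapped to an exact integer divisor of
    the camera pixel.  With ``noise=False`` (the default for artefact
    quantification) the returned image is the expected photon count per
    camera pixel; with ``noise=True`` a camera model is applied.
    """
    rng = np.random.default_rng(rng)
    # one independent, deterministic stream per cell: the same seed renders
    # the same per-cell emitter draws even when other cells' densities change
    cell_streams = rng.spawn(len(layout.cells))
    noise_stream = rng.spawn(1)[0]
    pixel = layout.pixel_size_um
    factor = max(1, int(round(pixel / voxel_xy_um)))
    actual = pixel / factor
    if not math.isclose(actual, voxel_xy_um, rel_tol=1e-6):
        warnings.warn(
            f"high-res voxel adjusted to {actual:.5f} µm "
            f"({factor}x oversampling of the {pixel} µm camera pixel)",
            stacklevel=2,
        )
    voxel_xy_um = actual
    ny_c, nx_c = layout.field_size_px
    ny, nx = ny_c * factor, nx_c * factor

    max_depth = max(c.depth_um for c in layout.cells)
    nz = int(np.ceil(max_depth / voxel_z_um))
    nz += 1 - nz % 2  # odd so the mid-plane is a grid plane
    origin = (0.0, 0.0, -nz * voxel_z_um / 2.0)

    # rasterize the PSF model if needed, matched to the volume grid
    if isinstance(psf, EffectivePSF):
        ext = kernel_extent_um or 2.0 * float(psf.tail_rho_um) * 30.0
        half = int(np.ceil(ext / voxel_xy_um))
        kz = int(np.ceil((max_depth / 2) / voxel_z_um)) * 2 + 1
        psf = psf.rasterize((max(kz, nz), 2 * half + 1, 2 * half + 1),
                            voxel_xy_um, voxel_z_um)
    if dof_um is not None:
        psf = restrict_depth_of_field(psf, dof_um)

    volume = np.zeros((nz, ny, nx))
    records = []
    for i, cell in enumerate(layout.cells):
        density = layout.densities[i]
        ef = sample_emitters(
            cell,
            label_kind=label_kind,
            rng=cell_streams[i],
            density_override=density,
            shell_thickness_um=voxel_xy_um,
            photons_per_emitter=photons_per_emitter,
        )
        volume += bin_emitters(
            ef.positions_xyz_um, photons_per_emitter, (nz, ny, nx), origin,
            voxel_xy_um, voxel_z_um,
        )
        records.append(
            {
                "cell_id": i + 1,
                "density": density,
                "n_emitters": ef.n,
                "photons_total": ef.n * photons_per_emitter,
                "length_um": cell.length_um,
                "radius_um": cell.radius_um,
            }
        )

    highres = convolve_layerwise(volume, psf, voxel_xy_um, voxel_z_um)
    image = downsample_to_camera(highres, factor)

    cells_idd = [
        c if c.cell_id == i + 1 else _with_id(c, i + 1)
        for i, c in enumerate(layout.cells)
    ]
    masks = render_masks(cells_idd, (ny_c, nx_c), pixel)
    truth = pd.DataFrame(records)
    areas = np.bincount(masks.ravel(), minlength=len(layout.cells) + 1)
    truth["mask_area_px"] = areas[truth["cell_id"].to_numpy()]
    with np.errstate(divide="ignore", invalid="ignore"):
        truth["true_mean"] = np.where(
            truth["mask_area_px"] > 0,
            truth["photons_total"] / truth["mask_area_px"],
            np.nan,
        )
    if noise:
        camera = camera or CameraModel()
        image = apply_camera_noise(np.clip(image, 0, None), camera, noise_stream)
    prov = {
        "psf": getattr(psf, "provenance", "unknown"),
        "dof_um": dof_um,
        "noise": bool(noise),
        "oversample": factor,
        "voxel_z_um": voxel_z_um,
    }
    return SyntheticImagePair(image, masks, truth, prov)


def _with_id(cell: Spherocylinder, cid: int) -> Spherocylinder:
    from dataclasses import replace

    return replace(cell, cell_id=cid)
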