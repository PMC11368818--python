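"""Readers/writers, run configuration, and deterministic test fixtures.

TIFF is the interchange format for images, PSFs and masks (8/16-bit,
multi-page z-stacks), each with a JSON sidecar holding voxel sizes and
provenance.  Tables travel as CSV, layouts and configs as JSON/YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import EmitterField, Spherocylinder
from .layouts import SceneLayout
from .psf import PSF3D, OpticsConfig

__all__ = [
    "RunConfig",
    "write_image",
    "read_image",
    "write_psf",
    "read_psf",
    "write_emitters_csv",
    "read_emitters_csv",
    "write_layout",
    "read_layout",
    "make_fixtures",
]

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


def write_image(path: str | Path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 2D image or 3D z-stack as (multi-page) TIFF plus JSON sidecar."""
    path = Path(path)
    img = np.asarray(image)
    if not any(img.dtype == np.dtype(d) for d in _SUPPORTED_DTYPES):
        raise ValueError(f"unsupported dtype {img.dtype}; use 8/16-bit or float")
    kwargs = {"photometric": "minisblack"} if img.ndim == 3 else {}
    tifffile.imwrite(path, img, **kwargs)
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(metadata, indent=2)
        )


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    img = tifffile.imread(path)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return img, meta


def write_psf(path: str | Path, psf: PSF3D) -> None:
    meta = {
        "voxel_xy_um": psf.voxel_xy_um,
        "voxel_z_um": psf.voxel_z_um,
        "focal_plane_index": psf.focal_plane_index,
        "provenance": psf.provenance,
    }
    if psf.optics is not None:
        meta["optics"] = asdict(psf.optics)
    write_image(path, psf.data.astype(np.float32), meta)


def read_psf(path: str | Path) -> PSF3D:
    data, meta = read_image(path)
    optics = OpticsConfig(**meta["optics"]) if "optics" in meta else None
    return PSF3D(
        np.asarray(data, dtype=float),
        meta["voxel_xy_um"],
        meta["voxel_z_um"],
        meta["focal_plane_index"],
        meta.get("provenance", "instrumental"),
        optics,
    )


def write_emitters_csv(path: str | Path, field_: EmitterField) -> None:
    df = pd.DataFrame(
        field_.positions_xyz_um, columns=["x_um", "y_um", "z_um"]
    )
    df["photons"] = field_.photons_per_emitter
    df["cell_id"] = field_.parent_cell_id
    df.to_csv(path, index=False)


def read_emitters_csv(path: str | Path) -> EmitterField:
    df = pd.read_csv(path)
    photons = float(df["photons"].iloc[0]) if len(df) else 1.0
    cell_id = int(df["cell_id"].iloc[0]) if len(df) else 0
    return EmitterField(
        df[["x_um", "y_um", "z_um"]].to_numpy(), photons, "cytoplasm", cell_id
    )


def write_layout(path: str | Path, layout: SceneLayout) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=2))


def read_layout(path: str | Path) -> SceneLayout:
    return SceneLayout.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """A fully serializable description of one simulation run."""

    scene: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    camera: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def make_fixtures(kind: str, seed: int = 0):
    """Deterministic small fixtures for tests and examples.

    kinds: ``psf`` (33³ theoretical kernel), ``colony`` (<= 20-cell grown
    monolayer), ``scatter`` (60 cells on a small field), ``bead_stack``
    (synthetic noisy bead z-stack with its injected kernel).
    """
    from .layouts import grow_monolayer_colony, scatter_layout
    from .psf import theoretical_psf

    rng = np.random.default_rng(seed)
    if kind == "psf":
        return theoretical_psf(
            OpticsConfig(wavelength_um=0.55, na=1.4), (33, 33, 33),
            voxel_xy_um=0.04, voxel_z_um=0.1,
        )
    if kind == "colony":
        snaps = grow_monolayer_colony(20, rng=rng)
        # divisions can overshoot the target; keep the last snapshot <= 20
        return [s for s in snaps if s.n_cells <= 20][-1]
    if kind == "scatter":
        return scatter_layout(
            60, field_size_px=(512, 512), pixel_size_um=0.065,
            cell_template=Spherocylinder(3.0, 0.5), rng=rng,
        )
    if kind == "bead_stack":
        kern = theoretical_psf(
            OpticsConfig(wavelength_um=0.55, na=1.4), (9, 21, 21),
            voxel_xy_um=0.065, voxel_z_um=0.2,
        )
        stack = np.full((9, 256, 256), 10.0)
        positions = [(60, 60), (60, 190), (190, 60), (190, 190), (128, 128)]
        for (py, px) in positions:
            stack[:, py - 10 : py + 11, px - 10 : px + 11] += 5e4 * kern.data
        noisy = rng.poisson(stack).astype(float)
        return noisy, kern, positions
    raise ValueError(f"unknown fixture kind {kind!r}")
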