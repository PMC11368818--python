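"""Cell arrangements: isolated cells, scatters, pitch-controlled arrays,
mother-machine-style trench arrays, and grown monolayer microcolonies.

The colony generator is a deliberately simple agent-based model:
spherocylinders grow exponentially in length, divide symmetrically at a
target length of 3.5 µm ± U(−0.25, 0.25) µm, and overlaps are resolved by
overdamped rigid-body relaxation (pairwise repulsion with a small torque).
Downstream intensity analyses depend only on realistic dense monolayer
geometry, not on mechanical fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Spherocylinder

__all__ = [
    "SceneLayout",
    "isolated_layout",
    "scatter_layout",
    "grid_array_layout",
    "trench_array_layout",
    "grow_monolayer_colony",
]

_LAYOUT_KINDS = ("isolated", "scatter", "grid", "trench", "colony")


@dataclass
class SceneLayout:
    """A set of posed cells in a field of view plus per-cell densities."""

    cells: list[Spherocylinder]
    densities: np.ndarray
    field_size_px: tuple[int, int]
    pixel_size_um: float
    layout_kind: str = "isolated"

    def __post_init__(self) -> None:
        if self.layout_kind not in _LAYOUT_KINDS:
            raise ValueError(f"unknown layout_kind {self.layout_kind!r}")
        self.densities = np.broadcast_to(
            np.asarray(self.densities, dtype=float), (len(self.cells),)
        ).copy()

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_dict(self) -> dict:
        return {
            "layout_kind": self.layout_kind,
            "field_size_px": list(self.field_size_px),
            "pixel_size_um": self.pixel_size_um,
            "densities": self.densities.tolist(),
            "cells": [
                {
                    "length_um": c.length_um,
                    "radius_um": c.radius_um,
                    "center_xyz_um": list(c.center_xyz_um),
                    "orientation_rad": c.orientation_rad,
                    "depth_um": c.depth_um,
                    "cell_id": c.cell_id,
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneLayout":
        cells = [
            Spherocylinder(
                length_um=c["length_um"],
                radius_um=c["radius_um"],
                center_xyz_um=tuple(c["center_xyz_um"]),
                orientation_rad=c["orientation_rad"],
                depth_um=c["depth_um"],
                cell_id=c.get("cell_id", 0),
            )
            for c in d["cells"]
        ]
        return cls(
            cells,
            np.asarray(d["densities"], dtype=float),
            tuple(d["field_size_px"]),
            d["pixel_size_um"],
            d["layout_kind"],
        )


def _field_for(
    extent_x_um: float, extent_y_um: float, pixel_size_um: float, margin_um: float
) -> tuple[int, int]:
    nx = int(np.ceil((extent_x_um + 2 * margin_um) / pixel_size_um))
    ny = int(np.ceil((extent_y_um + 2 * margin_um) / pixel_size_um))
    return ny, nx


def isolated_layout(
    cell: Spherocylinder,
    density: float = 100.0,
    pixel_size_um: float = 0.065,
    margin_um: float = 3.0,
) -> SceneLayout:
    """A single cell centred in a field with a configurable dark margin."""
    ext = cell.length_um + 2 * cell.radius_um
    ny, nx = _field_for(ext, ext, pixel_size_um, margin_um)
    c = replace(
        cell,
        center_xyz_um=(nx * pixel_size_um / 2.0, ny * pixel_size_um / 2.0, 0.0),
        cell_id=1,
    )
    return SceneLayout([c], np.array([density]), (ny, nx), pixel_size_um, "isolated")


def scatter_layout(
    n: int,
    field_size_px: tuple[int, int] = (2048, 2048),
    pixel_size_um: float = 0.065,
    cell_template: Spherocylinder | None = None,
    min_separation_um: float = 1.5,
    density: float = 100.0,
    rng: np.random.Generator | int | None = None,
    max_attempts_per_cell: int = 2000,
) -> SceneLayout:
    """Uniform random positions and orientations, rejection-sampled so cell
    centres are at least ``min_separation_um`` plus one cell extent apart."""
    if not np.isfinite(min_separation_um):
        raise ValueError("min_separation_um must be finite")
    rng = np.random.default_rng(rng)
    tpl = cell_template or Spherocylinder(3.0, 0.5)
    ny, nx = field_size_px
    w, h = nx * pixel_size_um, ny * pixel_size_um
    ext = tpl.length_um / 2.0 + tpl.radius_um
    min_d = min_separation_um + tpl.length_um / 2.0
    placed = np.empty((0, 2))
    cells = []
    for i in range(n):
        for _ in range(max_attempts_per_cell):
            x = rng.uniform(ext, w - ext)
            y = rng.uniform(ext, h - ext)
            if len(placed) == 0 or np.min(
                np.hypot(placed[:, 0] - x, placed[:, 1] - y)
            ) >= min_d:
                break
        else:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n} at separation "
                f"{min_separation_um} µm in the field"
            )
        theta = rng.uniform(0, math.pi)
        cells.append(
            replace(tpl, center_xyz_um=(x, y, 0.0), orientation_rad=theta,
                    cell_id=i + 1)
        )
        placed = np.vstack([placed, [x, y]])
    return SceneLayout(cells, np.full(n, density), field_size_px, pixel_size_um,
                       "scatter")


def grid_array_layout(
    pitch_x_um: float,
    pitch_y_um: float,
    rows: int,
    cols: int,
    cell_template: Spherocylinder | None = None,
    density: float = 100.0,
    pixel_size_um: float = 0.065,
    margin_um: float = 3.0,
) -> SceneLayout:
    """Regular lattice of identical cells, long axes aligned with y.

    ``pitch_x`` is the centre-to-centre spacing across the cell width,
    ``pitch_y`` along the cell length; touching is allowed at equality with
    the cell extent.
    """
    tpl = cell_template or Spherocylinder(5.0, 0.5)
    if pitch_x_um < 2 * tpl.radius_um - 1e-9:
        raise ValueError("pitch_x_um below cell-to-cell contact")
    if pitch_y_um < tpl.length_um - 1e-9:
        raise ValueError("pitch_y_um below cell-to-cell contact")
    ext_x = (cols - 1) * pitch_x_um + 2 * tpl.radius_um
    ext_y = (rows - 1) * pitch_y_um + tpl.length_um
    ny, nx = _field_for(ext_x, ext_y, pixel_size_um, margin_um)
    x0 = (nx * pixel_size_um - (cols - 1) * pitch_x_um) / 2.0
    y0 = (ny * pixel_size_um - (rows - 1) * pitch_y_um) / 2.0
    cells = []
    cid = 0
    for i in range(rows):
        for j in range(cols):
            cid += 1
            cells.append(
                replace(
                    tpl,
                    center_xyz_um=(x0 + j * pitch_x_um, y0 + i * pitch_y_um, 0.0),
                    orientation_rad=math.pi / 2.0,
                    cell_id=cid,
                )
            )
    return SceneLayout(cells, np.full(len(cells), density), (ny, nx),
                       pixel_size_um, "grid")


def trench_array_layout(
    trench_pitch_um: float,
    cells_per_trench: int,
    labelled_pattern: list[list[bool]] | None = None,
    n_trenches: int = 2,
    cell_template: Spherocylinder | None = None,
    density: float = 100.0,
    pixel_size_um: float = 0.065,
    margin_um: float = 3.0,
) -> SceneLayout:
    """Mother-machine-style vertical trenches of end-to-end stacked cells.

    ``labelled_pattern[t][k]`` marks whether cell ``k`` of trench ``t``
    carries fluorophores (density > 0); unlabelled cells get density 0, for
    bleedthrough-into-unlabelled-cell experiments.
    """
    tpl = cell_template or Spherocylinder(3.0, 0.5)
    if labelled_pattern is None:
        labelled_pattern = [[True] * cells_per_trench for _ in range(n_trenches)]
    n_trenches = len(labelled_pattern)
    ext_x = (n_trenches - 1) * trench_pitch_um + 2 * tpl.radius_um
    ext_y = cells_per_trench * tpl.length_um
    ny, nx = _field_for(ext_x, ext_y, pixel_size_um, margin_um)
    x0 = (nx * pixel_size_um - (n_trenches - 1) * trench_pitch_um) / 2.0
    y0 = (ny * pixel_size_um - (cells_per_trench - 1) * tpl.length_um) / 2.0
    cells, dens = [], []
    cid = 0
    for t, pattern in enumerate(labelled_pattern):
        for k in range(cells_per_trench):
            cid += 1
            cells.append(
                replace(
                    tpl,
                    center_xyz_um=(
                        x0 + t * trench_pitch_um,
                        y0 + k * tpl.length_um,
                        0.0,
                    ),
                    orientation_rad=math.pi / 2.0,
                    cell_id=cid,
                )
            )
            dens.append(density if (k < len(pattern) and pattern[k]) else 0.0)
    return SceneLayout(cells, np.asarray(dens), (ny, nx), pixel_size_um, "trench")


# ---------------------------------------------------------------------------
# Monolayer colony growth
# ---------------------------------------------------------------------------


def _segment_endpoints(x, y, theta, length, radius):
    a = length / 2.0 - radius
    dx, dy = np.cos(theta) * a, np.sin(theta) * a
    return np.stack([x - dx, y - dy], -1), np.stack([x + dx, y + dy], -1)


def _seg_seg_distance(p1, q1, p2, q2):
    """Closest-point distance between 2D segments (vectorized, Ericson)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t_cl = np.clip(t, 0, 1)
    s = np.where(
        (t != t_cl),
        np.clip((np.einsum("ij,ij->i", d1, p2 + t_cl[:, None] * d2 - p1)) / np.where(a > 1e-12, a, 1.0), 0, 1),
        s,
    )
    cp1 = p1 + s[:, None] * d1
    cp2 = p2 + t_cl[:, None] * d2
    diff = cp1 - cp2
    return np.sqrt(np.einsum("ij,ij->i", diff, diff)), cp1, cp2


def _candidate_pairs(x, y, cutoff):
    """Neighbour pairs via spatial hashing on a grid of size `cutoff`."""
    n = len(x)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    gx = np.floor(x / cutoff).astype(np.int64)
    gy = np.floor(y / cutoff).astype(np.int64)
    buckets: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        buckets.setdefault((gx[i], gy[i]), []).append(i)
    pairs = []
    for (bx, by), members in buckets.items():
        neigh = []
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                neigh.extend(buckets.get((bx + ox, by + oy), []))
        for i in members:
            for j in neigh:
                if j > i:
                    pairs.append((i, j))
    return np.asarray(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)


def _relax(state, radius, max_iter=400, tol_frac=0.01, torque_gain=0.15):
    """Overdamped rigid-body overlap resolution; returns max residual overlap."""
    x, y, theta, length = state
    tol = tol_frac * radius
    cutoff = float(length.max()) + 2 * radius
    for _ in range(max_iter):
        pairs = _candidate_pairs(x, y, cutoff)
        if len(pairs) == 0:
            return 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        p1, q1 = _segment_endpoints(x[i], y[i], theta[i], length[i], radius)
        p2, q2 = _segment_endpoints(x[j], y[j], theta[j], length[j], radius)
        dist, cp1, cp2 = _seg_seg_distance(p1, q1, p2, q2)
        overlap = 2 * radius - dist
        active = overlap > tol
        if not np.any(active):
            return float(max(overlap.max(), 0.0))
        i, j = i[active], j[active]
        ov = overlap[active]
        d = cp1[active] - cp2[active]
        norm = np.hypot(d[:, 0], d[:, 1])
        zero = norm < 1e-9
        if np.any(zero):  # coincident closest points: push along a fixed axis
            d[zero] = [1.0, 0.0]
            norm[zero] = 1.0
        ux, uy = d[:, 0] / norm, d[:, 1] / norm
        push = 0.5 * ov * 0.8  # under-relaxation
        np.add.at(x, i, push * ux)
        np.add.at(y, i, push * uy)
        np.add.at(x, j, -push * ux)
        np.add.at(y, j, -push * uy)
        # torque: contact offset from the centre rotates the cell slightly
        rx1, ry1 = cp1[active, 0] - x[i], cp1[active, 1] - y[i]
        rx2, ry2 = cp2[active, 0] - x[j], cp2[active, 1] - y[j]
        tq1 = (rx1 * uy - ry1 * ux) * push
        tq2 = -(rx2 * uy - ry2 * ux) * push
        np.add.at(theta, i, torque_gain * tq1 / np.maximum(length[i], 1.0))
        np.add.at(theta, j, torque_gain * tq2 / np.maximum(length[j], 1.0))
    # recompute residual after the iteration cap
    pairs = _candidate_pairs(x, y, cutoff)
    if len(pairs) == 0:
        return 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    p1, q1 = _segment_endpoints(x[i], y[i], theta[i], length[i], radius)
    p2, q2 = _segment_endpoints(x[j], y[j], theta[j], length[j], radius)
    dist, _, _ = _seg_seg_distance(p1, q1, p2, q2)
    return float(max((2 * radius - dist).max(), 0.0))


def grow_monolayer_colony(
    n_target: int,
    width_um: float = 1.0,
    division_length_um: float = 3.5,
    division_jitter_um: float = 0.25,
    septum_gap_um: float = 0.1,
    orientation_noise_rad: float = math.radians(2.0),
    growth_per_step: float = 0.03,
    density: float = 100.0,
    pixel_size_um: float = 0.065,
    margin_um: float = 3.0,
    rng: np.random.Generator | int | None = None,
    snapshot_counts: list[int] | None = None,
    overlap_tol_frac: float = 0.01,
) -> list[SceneLayout]:
    """Grow a monolayer microcolony to ``n_target`` cells.

    Cells keep a constant width, elongate exponentially
    (``growth_per_step`` fractional length increase per step) and divide
    symmetrically when reaching their target length, drawn per division as
    ``division_length_um + U(-division_jitter_um, +division_jitter_um)``.
    Overlaps are resolved after every step by rigid-body relaxation.

    Returns a list of :class:`SceneLayout` snapshots — one for each cell
    count in ``snapshot_counts`` (default: every count up to 16 and a
    geometric ladder beyond) plus the final colony.  A ``RuntimeError`` is
    raised if relaxation cannot resolve overlaps within the iteration cap.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(rng)
    radius = width_um / 2.0

    if snapshot_counts is None:
        ladder = {int(round(2**k)) for k in np.arange(4, 11, 0.5)}
        snapshot_counts = sorted({c for c in (set(range(1, 17)) | ladder) if c <= n_target})
    wanted = sorted(set(snapshot_counts) | {n_target})

    x = np.array([0.0])
    y = np.array([0.0])
    theta = np.array([rng.uniform(0, math.pi)])
    length = np.array([rng.uniform(2.0, division_length_um - division_jitter_um)])
    target = np.array([division_length_um + rng.uniform(-division_jitter_um,
                                                        division_jitter_um)])
    snapshots: list[SceneLayout] = []
    taken: set[int] = set()

    def take_snapshot():
        n = len(x)
        ext = max(
            x.max() - x.min(), y.max() - y.min()
        ) + 2 * (length.max() / 2 + radius)
        ny, nx = _field_for(ext, ext, pixel_size_um, margin_um)
        cx = (x.min() + x.max()) / 2.0
        cy = (y.min() + y.max()) / 2.0
        ox = nx * pixel_size_um / 2.0 - cx
        oy = ny * pixel_size_um / 2.0 - cy
        cells = [
            Spherocylinder(
                length_um=float(length[i]),
                radius_um=radius,
                center_xyz_um=(float(x[i] + ox), float(y[i] + oy), 0.0),
                orientation_rad=float(theta[i]),
                cell_id=i + 1,
            )
            for i in range(n)
        ]
        snapshots.append(
            SceneLayout(cells, np.full(n, density), (ny, nx), pixel_size_um,
                        "colony")
        )
        taken.add(n)

    wanted_idx = 0
    if wanted[0] == 1:
        take_snapshot()
        wanted_idx = 1
    safety = 0
    while len(x) < n_target:
        safety += 1
        if safety > 100000:  # pragma: no cover
            raise RuntimeError("colony growth failed to reach target size")
        length = length * (1.0 + growth_per_step)
        # divisions
        div = np.nonzero(length >= target)[0]
        if len(div):
            keep = np.setdiff1d(np.arange(len(x)), div)
            nx_, ny_, nth, nl, ntg = [x[keep]], [y[keep]], [theta[keep]], [length[keep]], [target[keep]]
            for idx in div:
                ld = (length[idx] - septum_gap_um) / 2.0
                off = (length[idx] - ld) / 2.0
                for sgn in (-1.0, 1.0):
                    nx_.append(np.array([x[idx] + sgn * off * math.cos(theta[idx])]))
                    ny_.append(np.array([y[idx] + sgn * off * math.sin(theta[idx])]))
                    nth.append(np.array([theta[idx] + rng.normal(0, orientation_noise_rad)]))
                    nl.append(np.array([ld]))
                    ntg.append(np.array([
                        division_length_um
                        + rng.uniform(-division_jitter_um, division_jitter_um)
                    ]))
            x = np.concatenate(nx_)
            y = np.concatenate(ny_)
            theta = np.concatenate(nth)
            length = np.concatenate(nl)
            target = np.concatenate(ntg)
        residual = _relax((x, y, theta, length), radius, tol_frac=overlap_tol_frac)
        if residual > 0.25 * radius:
            raise RuntimeError(
                f"overlap relaxation failed: residual overlap {residual:.3f} µm "
                f"at {len(x)} cells"
            )
        n = len(x)
        if wanted_idx < len(wanted) and n >= wanted[wanted_idx]:
            take_snapshot()
            while wanted_idx < len(wanted) and wanted[wanted_idx] <= n:
                wanted_idx += 1
    if len(x) not in taken:
        take_snapshot()
    return snapshots
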