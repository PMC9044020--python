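"""Seeded synthetic volumes: labeled balls, tubes, boxes, ramps, label fields.

These generators stand in for real electron-microscopy volumes so every
operation in the library is exercisable offline and deterministically.
Inside/outside tests place voxel *centers* at integer coordinates + 0.5,
which keeps voxelized ball volumes unbiased relative to the continuous
4/3*pi*r^3 and makes mesh enclosed-volume tolerances meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import CoordinateFrame, CutoutRequest, Resource, VolumeBlock
from .errors import BoundsError, VoxelKitError

__all__ = [
    "FixtureSpec",
    "FixtureObject",
    "render_fixture",
    "make_ball_volume",
    "make_tube_volume",
    "make_ramp_volume",
    "make_random_labels",
    "wrap_array",
]


def _fixture_resource(
    shape_xyz: Tuple[int, int, int],
    dtype: str,
    voxel_size: Tuple[float, float, float],
    name: str = "fixture",
) -> Resource:
    channel_kind = "annotation" if dtype == "uint64" else "image"
    frame = CoordinateFrame(extents=tuple(shape_xyz), voxel_size=tuple(voxel_size))
    return Resource.data_instance(name, dtype=dtype, channel_kind=channel_kind, frame=frame)


def wrap_array(
    data: np.ndarray,
    *,
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    name: str = "fixture",
) -> VolumeBlock:
    """Wrap a raw (z, y, x) array as a full-extent VolumeBlock with a
    synthetic data-instance resource."""
    data = np.asarray(data)
    nz, ny, nx = data.shape
    resource = _fixture_resource((nx, ny, nz), str(data.dtype), voxel_size, name)
    request = CutoutRequest(
        resource=resource, resolution=0, x_range=(0, nx), y_range=(0, ny), z_range=(0, nz)
    )
    return VolumeBlock(request=request, data=data)


def _centers(shape_xyz) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinate grids (x, y, z), each of array shape (z, y, x)."""
    nx, ny, nz = shape_xyz
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    return xx + 0.5, yy + 0.5, zz + 0.5


@dataclass(frozen=True)
class FixtureObject:
    """One geometric object in a fixture: ball, tube (axis-aligned
    cylinder) or box."""

    kind: str  # ball | tube | box
    label: int
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # ball center (x,y,z)
    radius: float = 0.0  # ball/tube radius
    axis: str = "z"  # tube axis
    span: Tuple[float, float] = (0.0, 0.0)  # tube extent along its axis
    corner_low: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # box corners (x,y,z)
    corner_high: Tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class FixtureSpec:
    """A deterministic description of a synthetic labeled volume."""

    shape: Tuple[int, int, int]  # (X, Y, Z)
    dtype: str = "uint64"
    seed: int = 0
    objects: Tuple[FixtureObject, ...] = ()
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        labels = [o.label for o in self.objects]
        if any(l == 0 for l in labels):
            raise VoxelKitError("object labels must be nonzero (0 is background)")
        if len(set(labels)) != len(labels):
            raise VoxelKitError("object labels must be distinct")


def _paint(mask_target: np.ndarray, obj: FixtureObject, shape_xyz) -> None:
    xx, yy, zz = _centers(shape_xyz)
    if obj.kind == "ball":
        cx, cy, cz = obj.center
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= obj.radius**2
    elif obj.kind == "tube":
        lo, hi = obj.span
        cx, cy, cz = obj.center
        if obj.axis == "z":
            inside = ((xx - cx) ** 2 + (yy - cy) ** 2 <= obj.radius**2) & (zz >= lo) & (zz < hi)
        elif obj.axis == "y":
            inside = ((xx - cx) ** 2 + (zz - cz) ** 2 <= obj.radius**2) & (yy >= lo) & (yy < hi)
        elif obj.axis == "x":
            inside = ((yy - cy) ** 2 + (zz - cz) ** 2 <= obj.radius**2) & (xx >= lo) & (xx < hi)
        else:
            raise VoxelKitError(f"unknown tube axis {obj.axis!r}")
    elif obj.kind == "box":
        (x0, y0, z0), (x1, y1, z1) = obj.corner_low, obj.corner_high
        inside = (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1) & (zz >= z0) & (zz < z1)
    else:
        raise VoxelKitError(f"unknown fixture object kind {obj.kind!r}")
    mask_target[inside] = obj.label


def render_fixture(spec: FixtureSpec) -> VolumeBlock:
    """Render a FixtureSpec; bytes are a pure function of (spec, seed).

    Later objects overwrite earlier ones where they overlap.
    """
    nx, ny, nz = spec.shape
    data = np.zeros((nz, ny, nx), dtype=np.dtype(spec.dtype))
    for obj in spec.objects:
        _paint(data, obj, spec.shape)
    return wrap_array(data, voxel_size=spec.voxel_size)


def make_ball_volume(
    shape: Tuple[int, int, int],
    center: Tuple[float, float, float],
    radius: float,
    label: int = 1,
    *,
    dtype: str = "uint64",
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeBlock:
    """A single labeled ball: voxel==label iff the voxel center lies within
    ``radius`` of ``center`` (coordinates in voxel units, x/y/z order).

    The ball must fit inside the volume with at least one voxel of
    background margin on every side, so the resulting surface is closed.
    """
    for axis, c, ext in zip("xyz", center, shape):
        if c - radius < 1.0 or c + radius > ext - 1.0:
            raise BoundsError(
                axis, f"ball (center {c}, radius {radius}) breaches the 1-voxel margin on {axis}"
            )
    spec = FixtureSpec(
        shape=tuple(shape),
        dtype=dtype,
        objects=(FixtureObject(kind="ball", label=label, center=tuple(center), radius=radius),),
        voxel_size=tuple(voxel_size),
    )
    return render_fixture(spec)


def make_tube_volume(
    shape: Tuple[int, int, int],
    center: Tuple[float, float, float],
    radius: float,
    span: Tuple[float, float],
    axis: str = "z",
    label: int = 1,
    *,
    dtype: str = "uint64",
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeBlock:
    """An axis-aligned cylinder (tube) of the given radius and axial span."""
    spec = FixtureSpec(
        shape=tuple(shape),
        dtype=dtype,
        objects=(
            FixtureObject(
                kind="tube", label=label, center=tuple(center), radius=radius,
                axis=axis, span=tuple(span),
            ),
        ),
        voxel_size=tuple(voxel_size),
    )
    return render_fixture(spec)


def make_ramp_volume(
    shape: Tuple[int, int, int],
    modulus: int = 251,
    *,
    dtype: str = "uint8",
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeBlock:
    """The oracle-friendly ramp: voxel(x, y, z) = (x + 10y + 100z) mod m.

    Any sub-box is independently recomputable from the formula, which makes
    this the standard ground truth for cutout round-trip tests.
    """
    if modulus < 1 or modulus - 1 > np.iinfo(np.dtype(dtype)).max:
        raise VoxelKitError(f"modulus {modulus} does not fit dtype {dtype}")
    nx, ny, nz = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    data = ((xx + 10 * yy + 100 * zz) % modulus).astype(np.dtype(dtype))
    return wrap_array(data, voxel_size=voxel_size)


def ramp_value(x, y, z, modulus: int = 251):
    """Closed-form ramp formula, usable as an independent oracle on indices."""
    return (np.asarray(x) + 10 * np.asarray(y) + 100 * np.asarray(z)) % modulus


def make_random_labels(
    shape: Tuple[int, int, int],
    n_labels: int,
    seed: int = 0,
    *,
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> VolumeBlock:
    """Seeded Voronoi-style label field.

    ``n_labels`` sites are placed uniformly at random (one RNG seeded per
    call; no global state) and every voxel takes the label (1..n_labels) of
    its nearest site, so each label's support is a connected convex-ish
    cell and every label appears for reasonable shapes.
    """
    if n_labels < 1:
        raise VoxelKitError("n_labels must be >= 1")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    sites = rng.uniform(low=(0, 0, 0), high=(nx, ny, nz), size=(n_labels, 3))
    xx, yy, zz = _centers(shape)
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    # nearest site by squared distance, chunked to bound memory
    best = np.zeros(pts.shape[0], dtype=np.uint64)
    step = 1 << 18
    for lo in range(0, pts.shape[0], step):
        d2 = ((pts[lo : lo + step, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        best[lo : lo + step] = np.argmin(d2, axis=1) + 1
    data = best.reshape((nz, ny, nx))
    return wrap_array(data, voxel_size=voxel_size)
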