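"""Local marching-cubes MeshService, mesh metrics and format writers.

A segmentation label is binarized (``voxel == label``), isosurfaced at
level 0.5 with linear interpolation using the classic marching-cubes
lookup table, and scaled into physical units using the source frame's
voxel size. The mesh can be exported as Wavefront OBJ or as a Neuroglancer
legacy *precomputed* mesh fragment.

The service runs against any remote that provides volume reads; if a
remote declares a ``mesh_server_side`` capability the service delegates to
it instead of computing locally, so server-backed and local meshing share
one call site ("shock absorption").
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from skimage.measure import marching_cubes as _skimage_marching_cubes

from .core import CutoutRequest, Remote, Resource, Service, VolumeBlock, validate_request
from .errors import ShapeError, VoxelKitError

__all__ = [
    "Mesh",
    "MeshStats",
    "MeshService",
    "marching_cubes",
    "mesh_for_id",
    "mesh_stats",
    "write_obj",
    "read_obj",
    "write_precomputed",
    "read_precomputed",
]


@dataclass
class Mesh:
    """Indexed triangle set for one segmentation label.

    ``vertices`` are (n, 3) float64 points in physical units, axis order
    (x, y, z); ``triangles`` are (m, 3) integer index triples.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    label: int = 0
    source_box: Optional[CutoutRequest] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise VoxelKitError("triangle index out of range")
            same = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if same.any():
                raise VoxelKitError("degenerate triangle (repeated vertex index)")

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def translated(self, offset) -> "Mesh":
        return Mesh(
            vertices=self.vertices + np.asarray(offset, dtype=np.float64),
            triangles=self.triangles.copy(),
            label=self.label,
            source_box=self.source_box,
        )


@dataclass(frozen=True)
class MeshStats:
    """Verification metrics for a mesh.

    ``euler_characteristic`` is V - E + F; a watertight, single-component,
    genus-0 surface has Euler characteristic 2. ``enclosed_volume`` is the
    absolute signed tetrahedron sum, in physical units cubed, and is only
    geometrically meaningful when the mesh is watertight.
    """

    n_vertices: int
    n_triangles: int
    n_edges: int
    euler_characteristic: int
    enclosed_volume: float
    watertight: bool


def _as_mask_and_scale(volume, label, voxel_size):
    if isinstance(volume, VolumeBlock):
        data = volume.data
        if voxel_size is None:
            frame = volume.resource.frame
            voxel_size = frame.voxel_size_at(volume.request.resolution) if frame else (1.0, 1.0, 1.0)
        origin = volume.origin
    else:
        data = np.asarray(volume)
        origin = (0, 0, 0)
        if voxel_size is None:
            voxel_size = (1.0, 1.0, 1.0)
    if data.ndim != 3:
        raise ShapeError(f"marching cubes needs a 3D volume, got ndim={data.ndim}")
    return (data == label), tuple(float(v) for v in voxel_size), origin


def marching_cubes(
    volume: Union[VolumeBlock, np.ndarray],
    label: int,
    *,
    voxel_size: Optional[Tuple[float, float, float]] = None,
    pad: bool = True,
) -> Mesh:
    """Extract the isosurface of one label from a segmentation volume.

    The binary mask (``voxel == label``) is contoured at iso-level 0.5 with
    linear interpolation; vertex coordinates are placed at voxel centers
    (index + 0.5), scaled by the per-axis voxel size and offset by the
    source box origin so meshes land in global physical coordinates.

    With ``pad=True`` (default) the mask is surrounded by one layer of
    zeros before contouring, so objects touching the box face still close
    into watertight surfaces; disable to keep user-requested clips open.

    An absent label yields an empty mesh, not an error.
    """
    mask, vsize, origin = _as_mask_and_scale(volume, label, voxel_size)
    source_box = volume.request if isinstance(volume, VolumeBlock) else None
    if not mask.any():
        return Mesh(
            vertices=np.zeros((0, 3)), triangles=np.zeros((0, 3), dtype=np.int64),
            label=label, source_box=source_box,
        )
    shift = 0.0
    field_arr = mask.astype(np.float32)
    if pad:
        field_arr = np.pad(field_arr, 1)
        shift = 1.0
    vx, vy, vz = vsize
    # array axes are (z, y, x) -> spacing in that order
    verts_zyx, faces, _, _ = _skimage_marching_cubes(
        field_arr, level=0.5, spacing=(1.0, 1.0, 1.0), method="lorensen",
        allow_degenerate=False,
    )
    # back to voxel indices, voxel centers at index + 0.5, then physical units
    verts_zyx = verts_zyx - shift + 0.5
    ox, oy, oz = origin
    vertices = np.empty_like(verts_zyx)
    vertices[:, 0] = (verts_zyx[:, 2] + ox) * vx
    vertices[:, 1] = (verts_zyx[:, 1] + oy) * vy
    vertices[:, 2] = (verts_zyx[:, 0] + oz) * vz
    return Mesh(vertices=vertices, triangles=faces.astype(np.int64), label=label,
                source_box=source_box)


class MeshService(Service):
    """Marching-cubes service: requires only volume reads.

    ``run`` delegates to a remote's server-side mesher when the remote
    declares ``mesh_server_side`` (exposing a ``mesh(resource, label,
    box)`` method); otherwise it fetches the cutout and meshes locally.
    Either path yields the same mesh for the same voxels.
    """

    required_capabilities = frozenset({"read"})

    def __init__(self, pad: bool = True):
        self.pad = pad

    def run(self, remote: Remote, resource: Resource, label: int,
            box: CutoutRequest, workers: Optional[int] = None) -> Mesh:
        if not self.can_run(remote):
            from .errors import CapabilityError

            raise CapabilityError(
                f"{type(remote).__name__} lacks capabilities {set(self.required_capabilities)}"
            )
        if "mesh_server_side" in remote.capabilities:
            return remote.mesh(resource, label, box)
        block = remote.get_cutout(box, workers=workers)
        return marching_cubes(block, label, pad=self.pad)


def mesh_for_id(remote: Remote, resource: Resource, label: int,
                box: CutoutRequest, *, pad: bool = True,
                workers: Optional[int] = None) -> Mesh:
    """Mesh one segmentation id from any remote holding the voxels."""
    return MeshService(pad=pad).run(remote, resource, label, box, workers=workers)


# -- metrics -------------------------------------------------------------


def mesh_stats(mesh: Mesh) -> MeshStats:
    """Counts, Euler characteristic, enclosed volume and watertightness.

    Watertightness is an edge-incidence census: every undirected edge must
    border exactly two triangles. Enclosed volume is the signed tetrahedron
    sum |sum(v1 . (v2 x v3)) / 6|.
    """
    if mesh.is_empty:
        return MeshStats(0, 0, 0, 0, 0.0, False)
    tri = mesh.triangles
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    watertight = bool((counts == 2).all())
    v = mesh.vertices
    v1, v2, v3 = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    volume = abs(float(np.einsum("ij,ij->", v1, np.cross(v2, v3))) / 6.0)
    n_v, n_t, n_e = mesh.n_vertices, mesh.n_triangles, len(uniq)
    return MeshStats(
        n_vertices=n_v,
        n_triangles=n_t,
        n_edges=n_e,
        euler_characteristic=n_v - n_e + n_t,
        enclosed_volume=volume,
        watertight=watertight,
    )


# -- OBJ -----------------------------------------------------------------


def write_obj(mesh: Mesh, destination) -> None:
    """Write Wavefront OBJ: ``v x y z`` lines then ``f a b c`` lines with
    1-based indices, 6 significant digits. An empty mesh writes an empty
    file."""
    own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
    fh = open(destination, "w") if own else destination
    try:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.6g} {y:.6g} {z:.6g}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")
    finally:
        if own:
            fh.close()


def read_obj(source, label: int = 0) -> Mesh:
    """Read the v/f subset of OBJ written by :func:`write_obj`."""
    own = isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
    fh = open(source) if own else source
    try:
        vertices, triangles = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                vertices.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                triangles.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    finally:
        if own:
            fh.close()
    return Mesh(
        vertices=np.array(vertices, dtype=np.float64).reshape(-1, 3),
        triangles=np.array(triangles, dtype=np.int64).reshape(-1, 3),
        label=label,
    )


# -- Neuroglancer legacy precomputed fragment ----------------------------


def write_precomputed(mesh: Mesh, destination=None) -> bytes:
    """Serialize the legacy single-resolution precomputed mesh fragment.

    Layout: uint32 little-endian vertex count; float32 LE (x, y, z)
    triples in nanometers; uint32 LE triangle index triples. Total byte
    length is exactly 4 + 12 V + 12 T.
    """
    if mesh.n_vertices >= 2**32:
        raise VoxelKitError("vertex count exceeds uint32")
    buf = io.BytesIO()
    buf.write(struct.pack("<I", mesh.n_vertices))
    buf.write(mesh.vertices.astype("<f4").tobytes(order="C"))
    buf.write(mesh.triangles.astype("<u4").tobytes(order="C"))
    blob = buf.getvalue()
    if destination is not None:
        own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
        fh = open(destination, "wb") if own else destination
        try:
            fh.write(blob)
        finally:
            if own:
                fh.close()
    return blob


def read_precomputed(blob: bytes, label: int = 0) -> Mesh:
    """Decode a legacy precomputed mesh fragment."""
    if len(blob) < 4:
        raise VoxelKitError("precomputed fragment shorter than its header")
    (n_vertices,) = struct.unpack("<I", blob[:4])
    v_end = 4 + 12 * n_vertices
    if len(blob) < v_end or (len(blob) - v_end) % 12 != 0:
        raise VoxelKitError("precomputed fragment length inconsistent with header")
    vertices = np.frombuffer(blob[4:v_end], dtype="<f4").reshape(-1, 3).astype(np.float64)
    triangles = np.frombuffer(blob[v_end:], dtype="<u4").reshape(-1, 3).astype(np.int64)
    return Mesh(vertices=vertices, triangles=triangles, label=label)
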