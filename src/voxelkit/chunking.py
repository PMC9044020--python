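"""Chunk-aligned decomposition and stitching of cutout requests.

Chunked volumetric stores serve fixed-shape cuboids; an arbitrary request
box generally straddles several of them, and any voxels in touched chunks
that fall outside the request ("periphery") must be downloaded and cropped
client-side. This module turns a request into a deterministic
:class:`BlockPlan` whose entries tile the request exactly, quantifies the
periphery overhead, and stitches fetched chunks back into one dense array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import CoordinateFrame, CutoutRequest, VolumeBlock
from .errors import IncompletePlanError, ShapeError, VoxelKitError

__all__ = [
    "ChunkShape",
    "ChunkKey",
    "PlanEntry",
    "BlockPlan",
    "decompose",
    "chunks_touched",
    "periphery_fraction",
    "stitch",
    "chunk_box",
    "clipped_chunk_shape",
]

Box = Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]  # (x, y, z) ranges


@dataclass(frozen=True)
class ChunkShape:
    """Voxels per chunk along X, Y, Z."""

    cx: int
    cy: int
    cz: int

    def __post_init__(self):
        if min(self.cx, self.cy, self.cz) < 1:
            raise VoxelKitError(f"chunk shape components must be >= 1, got {self}")

    @property
    def as_xyz(self) -> Tuple[int, int, int]:
        return (self.cx, self.cy, self.cz)

    @property
    def n_voxels(self) -> int:
        return self.cx * self.cy * self.cz

    @classmethod
    def of(cls, value) -> "ChunkShape":
        if isinstance(value, ChunkShape):
            return value
        cx, cy, cz = value
        return cls(int(cx), int(cy), int(cz))


@dataclass(frozen=True)
class ChunkKey:
    """Identity of one stored cuboid: resource URI, resolution, grid index.

    The chunk's voxel box is [i*cx,(i+1)*cx) x [j*cy,(j+1)*cy) x [k*cz,(k+1)*cz).
    """

    uri: str
    resolution: int
    i: int
    j: int
    k: int


@dataclass(frozen=True)
class PlanEntry:
    """One piece of a decomposed request.

    ``global_box`` is the intersection of the request with the chunk, in
    global voxel coordinates; ``local_box`` is the same box shifted into
    request-local coordinates (destination in the output array).
    """

    key: ChunkKey
    global_box: Box
    local_box: Box


BlockPlan = List[PlanEntry]


def chunk_box(key: ChunkKey, chunks: ChunkShape) -> Box:
    """Full (unclipped) voxel box of a chunk, (x, y, z) ranges."""
    return (
        (key.i * chunks.cx, (key.i + 1) * chunks.cx),
        (key.j * chunks.cy, (key.j + 1) * chunks.cy),
        (key.k * chunks.cz, (key.k + 1) * chunks.cz),
    )


def clipped_chunk_shape(
    key: ChunkKey, chunks: ChunkShape, extents_xyz: Sequence[int]
) -> Tuple[int, int, int]:
    """On-disk (truncated) shape of an edge chunk, (z, y, x) order."""
    box = chunk_box(key, chunks)
    dims = [min(stop, ext) - start for (start, stop), ext in zip(box, extents_xyz)]
    if min(dims) <= 0:
        raise VoxelKitError(f"chunk {key} lies entirely outside extents {tuple(extents_xyz)}")
    return (dims[2], dims[1], dims[0])


def _axis_pieces(start: int, stop: int, c: int) -> List[Tuple[int, int, int]]:
    """Split [start, stop) at multiples of c -> [(index, lo, hi), ...]."""
    pieces = []
    lo = start
    while lo < stop:
        idx = lo // c
        hi = min((idx + 1) * c, stop)
        pieces.append((idx, lo, hi))
        lo = hi
    return pieces


def decompose(request: CutoutRequest, chunks) -> BlockPlan:
    """Decompose a validated request into chunk-aligned plan entries.

    Entries are ordered k-major, then j, then i (z outermost) so plans are
    deterministic; stitching does not depend on this order.
    """
    chunks = ChunkShape.of(chunks)
    uri = request.resource.uri
    (x0, x1), (y0, y1), (z0, z1) = request.ranges
    xs = _axis_pieces(x0, x1, chunks.cx)
    ys = _axis_pieces(y0, y1, chunks.cy)
    zs = _axis_pieces(z0, z1, chunks.cz)
    plan: BlockPlan = []
    for k, zlo, zhi in zs:
        for j, ylo, yhi in ys:
            for i, xlo, xhi in xs:
                entry = PlanEntry(
                    key=ChunkKey(uri=uri, resolution=request.resolution, i=i, j=j, k=k),
                    global_box=((xlo, xhi), (ylo, yhi), (zlo, zhi)),
                    local_box=(
                        (xlo - x0, xhi - x0),
                        (ylo - y0, yhi - y0),
                        (zlo - z0, zhi - z0),
                    ),
                )
                plan.append(entry)
    return plan


def chunks_touched(request: CutoutRequest, chunks) -> int:
    """Closed-form number of chunks a request intersects.

    Per axis: floor((stop-1)/c) - floor(start/c) + 1; the product over axes
    equals ``len(decompose(request, chunks))``.
    """
    chunks = ChunkShape.of(chunks)
    n = 1
    for (start, stop), c in zip(request.ranges, chunks.as_xyz):
        n *= (stop - 1) // c - start // c + 1
    return n


def periphery_fraction(
    request: CutoutRequest, chunks, frame: Optional[CoordinateFrame] = None
) -> float:
    """Fraction of downloaded voxels that are cropped away.

    (voxels in touched chunks - requested voxels) / voxels in touched
    chunks. Chunks are clipped to the volume extents before counting:
    nothing beyond the extents ever crosses the wire, so extent-truncation
    is not periphery. Zero iff every request face lies on a chunk boundary
    or on the volume boundary.
    """
    chunks = ChunkShape.of(chunks)
    frame = frame if frame is not None else request.resource.frame
    extents = frame.extents_at(request.resolution) if frame is not None else None
    total = 0
    for entry in decompose(request, chunks):
        box = chunk_box(entry.key, chunks)
        vox = 1
        for axis, (lo, hi) in enumerate(box):
            if extents is not None:
                hi = min(hi, extents[axis])
            vox *= hi - lo
        total += vox
    return (total - request.n_voxels) / total


def stitch(
    request: CutoutRequest,
    plan: BlockPlan,
    blocks: Mapping[ChunkKey, np.ndarray],
    chunks,
) -> VolumeBlock:
    """Assemble fetched chunk arrays into the dense request box.

    ``blocks`` maps each plan entry's key to the full-chunk (z, y, x)
    array, zero-filled where the chunk extends beyond stored data. The
    result is independent of the order blocks were fetched in.
    """
    chunks = ChunkShape.of(chunks)
    dtype = request.resource.np_dtype
    out = np.zeros(request.shape, dtype=dtype)
    for entry in plan:
        if entry.key not in blocks:
            raise IncompletePlanError(f"missing block for {entry.key}")
        arr = np.asarray(blocks[entry.key])
        expected = (chunks.cz, chunks.cy, chunks.cx)
        if tuple(arr.shape) != expected:
            raise ShapeError(
                f"chunk array for {entry.key} has shape {tuple(arr.shape)}, expected {expected}"
            )
        (gx0, gx1), (gy0, gy1), (gz0, gz1) = entry.global_box
        (lx0, lx1), (ly0, ly1), (lz0, lz1) = entry.local_box
        ox, oy, oz = entry.key.i * chunks.cx, entry.key.j * chunks.cy, entry.key.k * chunks.cz
        out[lz0:lz1, ly0:ly1, lx0:lx1] = arr[
            gz0 - oz : gz1 - oz, gy0 - oy : gy1 - oy, gx0 - ox : gx1 - ox
        ]
    return VolumeBlock(request=request, data=out)
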