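"""On-disk chunked-file Remote.

Layout (the full dialect is documented in ``docs/formats.md``)::

    root/<collection>/<experiment>/<channel>/metadata.json
    root/<collection>/<experiment>/<channel>/res{r}/{i}_{j}_{k}.bin
    root/<name>/metadata.json                  # flat data_instance

Chunk files are raw little-endian C-order (z, y, x) arrays, truncated to
the volume extents at edge chunks. An absent chunk file means an all-zero
chunk, so sparse volumes cost no disk. Metadata is one JSON document per
volume resource and round-trips byte-identically.
"""

from __future__ import annotations

import json
import os
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from ..chunking import (
    ChunkKey,
    ChunkShape,
    clipped_chunk_shape,
    chunk_box,
    decompose,
    stitch,
)
from ..core import CoordinateFrame, CutoutRequest, Remote, Resource, VolumeBlock, validate_request
from ..errors import AlreadyExistsError, DtypeError, NotFoundError, ShapeError, VoxelKitError

DEFAULT_CHUNK_SHAPE = ChunkShape(512, 512, 16)
DEFAULT_WORKERS = 4

_METADATA = "metadata.json"


class FileChunkRemote(Remote):
    """Chunked-file store rooted at a directory.

    Reads decompose the request into chunk-aligned pieces, load the chunk
    files (in parallel when ``workers > 1``) and stitch them; writes do a
    per-chunk read-modify-write. Chunks that would be entirely zero and
    have no file yet are never materialised.
    """

    capabilities = frozenset({"read", "write", "create", "list"})

    def __init__(self, root, default_chunk_shape=DEFAULT_CHUNK_SHAPE, workers: int = DEFAULT_WORKERS):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.default_chunk_shape = ChunkShape.of(default_chunk_shape)
        self.workers = workers

    # -- layout helpers --------------------------------------------------

    def _dir_for(self, path) -> Path:
        return self.root.joinpath(*path)

    def _meta_path(self, path) -> Path:
        return self._dir_for(path) / _METADATA

    def _chunk_path(self, path, key: ChunkKey) -> Path:
        return self._dir_for(path) / f"res{key.resolution}" / f"{key.i}_{key.j}_{key.k}.bin"

    def _load_meta(self, path) -> dict:
        meta_path = self._meta_path(path)
        if not meta_path.exists():
            raise NotFoundError(f"unknown resource at {'/'.join(path)}")
        with open(meta_path) as fh:
            return json.load(fh)

    # -- resources -------------------------------------------------------

    def create_resource(self, resource: Resource) -> Resource:
        self._require("create")
        if not resource.is_volume:
            self._dir_for(resource.path).mkdir(parents=True, exist_ok=True)
            return resource
        if resource.frame is None:
            raise VoxelKitError(f"resource {resource.uri} carries no coordinate frame")
        meta_path = self._meta_path(resource.path)
        if meta_path.exists():
            raise AlreadyExistsError(f"resource {resource.uri} already exists")
        meta_path.parent.mkdir(parents=True, exist_ok=True)
        doc = resource.to_dict()
        doc["chunk_shape"] = list(self.default_chunk_shape.as_xyz)
        with open(meta_path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
        return resource

    def get_resource(self, uri: str) -> Resource:
        from ..core import parse_uri

        kind, path = parse_uri(uri)
        doc = self._load_meta(path)
        return Resource.from_dict(doc)

    def chunk_shape(self, resource: Resource) -> ChunkShape:
        doc = self._load_meta(resource.path)
        return ChunkShape.of(doc.get("chunk_shape", self.default_chunk_shape.as_xyz))

    def list_resources(self, prefix: str = "") -> list:
        parts = tuple(p for p in prefix.split("/") if p) if prefix else ()
        base = self._dir_for(parts)
        if not base.is_dir():
            return []
        uris = []
        for entry in sorted(base.iterdir()):
            if not entry.is_dir():
                continue
            child = parts + (entry.name,)
            meta = entry / _METADATA
            if meta.exists():
                with open(meta) as fh:
                    kind = json.load(fh).get("kind")
                if kind == "data_instance":
                    uris.append("instance://" + entry.name)
                    continue
            uris.append("bosslike://" + "/".join(child))
        return sorted(uris)

    # -- chunk IO --------------------------------------------------------

    def _read_chunk(self, resource: Resource, chunks: ChunkShape, key: ChunkKey) -> np.ndarray:
        """Full-chunk (z, y, x) array, zero-padded beyond stored extents."""
        extents = resource.frame.extents_at(key.resolution)
        stored_shape = clipped_chunk_shape(key, chunks, extents)
        full_shape = (chunks.cz, chunks.cy, chunks.cx)
        path = self._chunk_path(resource.path, key)
        if not path.exists():
            return np.zeros(full_shape, dtype=resource.np_dtype)
        raw = np.fromfile(path, dtype=resource.np_dtype.newbyteorder("<"))
        if raw.size != int(np.prod(stored_shape)):
            raise ShapeError(
                f"chunk file {path} holds {raw.size} voxels, expected {int(np.prod(stored_shape))}"
            )
        arr = raw.astype(resource.np_dtype, copy=False).reshape(stored_shape)
        if stored_shape == full_shape:
            return arr
        out = np.zeros(full_shape, dtype=resource.np_dtype)
        out[: stored_shape[0], : stored_shape[1], : stored_shape[2]] = arr
        return out

    def _write_chunk(self, resource: Resource, chunks: ChunkShape, key: ChunkKey, full: np.ndarray) -> None:
        extents = resource.frame.extents_at(key.resolution)
        sz, sy, sx = clipped_chunk_shape(key, chunks, extents)
        clipped = np.ascontiguousarray(full[:sz, :sy, :sx])
        path = self._chunk_path(resource.path, key)
        if not path.exists() and not clipped.any():
            return  # sparse economy: never materialise all-zero chunks
        path.parent.mkdir(parents=True, exist_ok=True)
        clipped.astype(resource.np_dtype.newbyteorder("<"), copy=False).tofile(path)

    # -- voxels ----------------------------------------------------------

    def get_cutout(self, request: CutoutRequest, workers: Optional[int] = None) -> VolumeBlock:
        self._require("read")
        resource = self.get_resource(request.resource.uri)
        request = CutoutRequest(
            resource=resource, resolution=request.resolution,
            x_range=request.x_range, y_range=request.y_range, z_range=request.z_range,
        )
        validate_request(request)
        chunks = self.chunk_shape(resource)
        plan = decompose(request, chunks)
        workers = self.workers if workers is None else workers
        keys = [e.key for e in plan]
        if workers > 1 and len(keys) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                arrays = list(pool.map(lambda k: self._read_chunk(resource, chunks, k), keys))
        else:
            arrays = [self._read_chunk(resource, chunks, k) for k in keys]
        return stitch(request, plan, dict(zip(keys, arrays)), chunks)

    def post_cutout(self, request: CutoutRequest, data: np.ndarray) -> None:
        self._require("write")
        resource = self.get_resource(request.resource.uri)
        request = CutoutRequest(
            resource=resource, resolution=request.resolution,
            x_range=request.x_range, y_range=request.y_range, z_range=request.z_range,
        )
        validate_request(request)
        data = np.asarray(data)
        if data.dtype != resource.np_dtype:
            raise DtypeError(f"write dtype {data.dtype} != resource dtype {resource.np_dtype}")
        if tuple(data.shape) != request.shape:
            raise ShapeError(f"write shape {tuple(data.shape)} != request shape {request.shape}")
        chunks = self.chunk_shape(resource)
        for entry in decompose(request, chunks):
            full = self._read_chunk(resource, chunks, entry.key)
            (gx0, gx1), (gy0, gy1), (gz0, gz1) = entry.global_box
            (lx0, lx1), (ly0, ly1), (lz0, lz1) = entry.local_box
            ox = entry.key.i * chunks.cx
            oy = entry.key.j * chunks.cy
            oz = entry.key.k * chunks.cz
            full[gz0 - oz : gz1 - oz, gy0 - oy : gy1 - oy, gx0 - ox : gx1 - ox] = data[
                lz0:lz1, ly0:ly1, lx0:lx1
            ]
            self._write_chunk(resource, chunks, entry.key, full)
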