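"""Caching relay: answer cutouts from a local chunk cache, fetch misses
upstream, evict least-recently-used chunks.

The relay is itself a :class:`~voxelkit.core.Remote`, so it can be served
over HTTP with the reference server and — because it speaks the same
dialect it consumes — relays can be daisy-chained into a multi-tier cache
(client -> relay -> relay -> store). Cache granularity equals the
*upstream's* chunk shape, so cache keys align with the server's storage
cuboids and a warm cache answers chunk-aligned requests with zero upstream
contact.

Coherence: writes through the relay invalidate intersecting cached chunks
before being forwarded upstream (write-through). Writes that bypass the
relay are out of contract.
"""

from __future__ import annotations

import hashlib
from collections import OrderedDict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chunking import ChunkKey, ChunkShape, chunk_box, clipped_chunk_shape, decompose, stitch
from .core import CutoutRequest, Remote, Resource, VolumeBlock, validate_request
from .errors import ShapeError, VoxelKitError

__all__ = ["CacheTier", "Relay"]


class _MemoryStore:
    def __init__(self):
        self._data: Dict[ChunkKey, bytes] = {}

    def put(self, key, blob):
        self._data[key] = blob

    def get(self, key):
        return self._data[key]

    def delete(self, key):
        self._data.pop(key, None)


class _DiskStore:
    """Chunk bytes as files under a directory, named by key digest."""

    def __init__(self, directory):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, key: ChunkKey) -> Path:
        token = f"{key.uri}|{key.resolution}|{key.i}|{key.j}|{key.k}"
        return self.directory / (hashlib.sha1(token.encode()).hexdigest() + ".chunk")

    def put(self, key, blob):
        self._path(key).write_bytes(blob)

    def get(self, key):
        return self._path(key).read_bytes()

    def delete(self, key):
        self._path(key).unlink(missing_ok=True)


class CacheTier:
    """LRU cache over chunk-addressed byte blobs.

    Total stored bytes never exceed ``capacity_bytes``; a single blob
    larger than the whole capacity is refused (the relay then passes it
    through uncached). Recency is updated on both reads and writes.
    """

    def __init__(self, capacity_bytes: int, directory=None):
        if capacity_bytes < 1:
            raise VoxelKitError("capacity_bytes must be positive")
        self.capacity_bytes = int(capacity_bytes)
        self._store = _DiskStore(directory) if directory else _MemoryStore()
        self._sizes: "OrderedDict[ChunkKey, int]" = OrderedDict()  # LRU -> MRU
        self.stored_bytes = 0
        self.hit_count = 0
        self.miss_count = 0

    def __contains__(self, key) -> bool:
        return key in self._sizes

    def __len__(self) -> int:
        return len(self._sizes)

    def get(self, key: ChunkKey) -> Optional[bytes]:
        """Blob for the key, or None on a miss. Counts the access and
        refreshes recency."""
        if key not in self._sizes:
            self.miss_count += 1
            return None
        self.hit_count += 1
        self._sizes.move_to_end(key)
        return self._store.get(key)

    def put(self, key: ChunkKey, blob: bytes) -> List[ChunkKey]:
        """Insert (or refresh) a blob; returns any keys evicted to make
        room. Oversized blobs are refused and nothing changes."""
        if len(blob) > self.capacity_bytes:
            return []
        if key in self._sizes:
            self.stored_bytes -= self._sizes.pop(key)
        self._store.put(key, blob)
        self._sizes[key] = len(blob)
        self.stored_bytes += len(blob)
        return self.evict()

    def evict(self) -> List[ChunkKey]:
        """Drop least-recently-used keys until within capacity; returns the
        removed keys in eviction order."""
        removed = []
        while self.stored_bytes > self.capacity_bytes and self._sizes:
            key, size = next(iter(self._sizes.items()))
            del self._sizes[key]
            self._store.delete(key)
            self.stored_bytes -= size
            removed.append(key)
        return removed

    def invalidate(self, keys) -> int:
        removed = 0
        for key in list(keys):
            if key in self._sizes:
                self.stored_bytes -= self._sizes.pop(key)
                self._store.delete(key)
                removed += 1
        return removed

    def invalidate_all(self) -> int:
        n = len(self._sizes)
        for key in list(self._sizes):
            self._store.delete(key)
        self._sizes.clear()
        self.stored_bytes = 0
        return n

    def keys(self):
        return list(self._sizes)


class Relay(Remote):
    """A Remote that caches an upstream Remote chunk-by-chunk."""

    capabilities = frozenset({"read"})  # refined from upstream at construction

    def __init__(self, upstream: Remote, capacity_bytes: int = 256 * 2**20,
                 cache_dir=None):
        self.upstream = upstream
        self.tier = CacheTier(capacity_bytes, directory=cache_dir)
        self.capabilities = frozenset(upstream.capabilities) | {"read"}
        self.upstream_fetches = 0
        self._resources: Dict[str, Resource] = {}
        self._chunk_shapes: Dict[str, ChunkShape] = {}

    # -- metadata (cached; invalidated on create) ------------------------

    def get_resource(self, uri: str) -> Resource:
        if uri not in self._resources:
            self._resources[uri] = self.upstream.get_resource(uri)
        return self._resources[uri]

    def chunk_shape(self, resource: Resource) -> ChunkShape:
        uri = resource.uri
        if uri not in self._chunk_shapes:
            self._chunk_shapes[uri] = ChunkShape.of(self.upstream.chunk_shape(resource))
        return self._chunk_shapes[uri]

    def create_resource(self, resource: Resource) -> Resource:
        self._require("create")
        out = self.upstream.create_resource(resource)
        self._resources.pop(resource.uri, None)
        self._chunk_shapes.pop(resource.uri, None)
        return out

    def list_resources(self, prefix: str = "") -> list:
        self._require("list")
        return self.upstream.list_resources(prefix)

    # -- cache machinery -------------------------------------------------

    def _chunk_request(self, resource: Resource, key: ChunkKey) -> CutoutRequest:
        extents = resource.frame.extents_at(key.resolution)
        chunks = self.chunk_shape(resource)
        (x0, x1), (y0, y1), (z0, z1) = chunk_box(key, chunks)
        return CutoutRequest(
            resource=resource, resolution=key.resolution,
            x_range=(x0, min(x1, extents[0])),
            y_range=(y0, min(y1, extents[1])),
            z_range=(z0, min(z1, extents[2])),
        )

    def _blob_to_full_chunk(self, resource: Resource, key: ChunkKey, blob: bytes) -> np.ndarray:
        chunks = self.chunk_shape(resource)
        stored = clipped_chunk_shape(key, chunks, resource.frame.extents_at(key.resolution))
        dtype = resource.np_dtype.newbyteorder("<")
        arr = np.frombuffer(blob, dtype=dtype)
        if arr.size != int(np.prod(stored)):
            raise ShapeError(f"cached blob for {key} holds {arr.size} voxels")
        arr = arr.astype(resource.np_dtype, copy=False).reshape(stored)
        full = np.zeros((chunks.cz, chunks.cy, chunks.cx), dtype=resource.np_dtype)
        full[: stored[0], : stored[1], : stored[2]] = arr
        return full

    def _fetch_chunk(self, resource: Resource, key: ChunkKey) -> np.ndarray:
        """Serve a full (zero-padded) chunk from cache, or fetch upstream
        and insert."""
        blob = self.tier.get(key)
        if blob is not None:
            return self._blob_to_full_chunk(resource, key, blob)
        sub = self.upstream.get_cutout(self._chunk_request(resource, key))
        self.upstream_fetches += 1
        clipped = np.ascontiguousarray(
            sub.data.astype(resource.np_dtype.newbyteorder("<"), copy=False)
        )
        self.tier.put(key, clipped.tobytes())
        chunks = self.chunk_shape(resource)
        full = np.zeros((chunks.cz, chunks.cy, chunks.cx), dtype=resource.np_dtype)
        sz, sy, sx = sub.data.shape
        full[:sz, :sy, :sx] = sub.data
        return full

    # -- Remote interface ------------------------------------------------

    def get_cutout(self, request: CutoutRequest, workers: Optional[int] = None) -> VolumeBlock:
        resource = self.get_resource(request.resource.uri)
        from dataclasses import replace

        request = replace(request, resource=resource)
        validate_request(request)
        chunks = self.chunk_shape(resource)
        plan = decompose(request, chunks)
        blocks = {e.key: self._fetch_chunk(resource, e.key) for e in plan}
        return stitch(request, plan, blocks, chunks)

    def post_cutout(self, request: CutoutRequest, data: np.ndarray) -> None:
        self._require("write")
        resource = self.get_resource(request.resource.uri)
        from dataclasses import replace

        request = replace(request, resource=resource)
        validate_request(request)
        self.invalidate(resource, box=request)  # write-through coherence
        self.upstream.post_cutout(request, data)

    # -- invalidation ----------------------------------------------------

    def invalidate(self, resource: Optional[Resource] = None,
                   box: Optional[CutoutRequest] = None) -> int:
        """Drop cached chunks: all of them, all for one resource, or only
        those intersecting a box. Returns the number removed."""
        if resource is None:
            return self.tier.invalidate_all()
        if box is None:
            keys = [k for k in self.tier.keys() if k.uri == resource.uri]
            return self.tier.invalidate(keys)
        chunks = self.chunk_shape(resource)
        touched = {e.key for e in decompose(box, chunks)}
        return self.tier.invalidate(touched)

    def cache_stats(self) -> dict:
        return {
            "hits": self.tier.hit_count,
            "misses": self.tier.miss_count,
            "stored_bytes": self.tier.stored_bytes,
            "capacity_bytes": self.tier.capacity_bytes,
            "chunks_cached": len(self.tier),
            "upstream_fetches": self.upstream_fetches,
        }
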