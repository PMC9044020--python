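"""In-memory Remote: dense arrays keyed by resource URI.

Allocates one zero-filled array per resolution level at creation time, so
it is intended for test-sized volumes. It implements the full capability
set and is the reference behaviour the other remotes are tested against.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from ..chunking import ChunkShape
from ..core import CoordinateFrame, CutoutRequest, Remote, Resource, VolumeBlock, validate_request
from ..errors import AlreadyExistsError, DtypeError, NotFoundError, ShapeError

DEFAULT_CHUNK_SHAPE = ChunkShape(512, 512, 16)


class InMemoryRemote(Remote):
    capabilities = frozenset({"read", "write", "create", "list"})

    def __init__(self, default_chunk_shape=DEFAULT_CHUNK_SHAPE):
        self._resources: Dict[str, Resource] = {}
        self._arrays: Dict[Tuple[str, int], np.ndarray] = {}
        self._groups: set = set()  # hierarchy prefixes seen (tuples of path parts)
        self.default_chunk_shape = ChunkShape.of(default_chunk_shape)

    # -- resources -------------------------------------------------------

    def create_resource(self, resource: Resource) -> Resource:
        self._require("create")
        if not resource.is_volume:
            self._groups.add(resource.path)
            return resource
        if resource.frame is None:
            raise NotFoundError(f"resource {resource.uri} carries no coordinate frame")
        uri = resource.uri
        if uri in self._resources:
            raise AlreadyExistsError(f"resource {uri} already exists")
        self._resources[uri] = resource
        for r in range(resource.frame.num_resolutions):
            ex, ey, ez = resource.frame.extents_at(r)
            self._arrays[(uri, r)] = np.zeros((ez, ey, ex), dtype=resource.np_dtype)
        # implicit parents for listing
        for depth in range(1, len(resource.path)):
            self._groups.add(resource.path[:depth])
        return resource

    def get_resource(self, uri: str) -> Resource:
        try:
            return self._resources[uri]
        except KeyError:
            raise NotFoundError(f"unknown resource {uri}") from None

    def list_resources(self, prefix: str = "") -> list:
        parts = tuple(p for p in prefix.split("/") if p) if prefix else ()
        uris = set()
        for res in self._resources.values():
            if res.path[: len(parts)] == parts and len(res.path) == len(parts) + 1:
                uris.add(res.uri)
        for grp in self._groups:
            if grp[: len(parts)] == parts and len(grp) == len(parts) + 1:
                uris.add("bosslike://" + "/".join(grp))
        return sorted(uris)

    def chunk_shape(self, resource: Resource) -> ChunkShape:
        return self.default_chunk_shape

    # -- voxels ----------------------------------------------------------

    def _array(self, request: CutoutRequest) -> np.ndarray:
        stored = self.get_resource(request.resource.uri)
        validate_request(request, stored.frame)
        return self._arrays[(stored.uri, request.resolution)]

    def get_cutout(self, request: CutoutRequest, workers: Optional[int] = None) -> VolumeBlock:
        self._require("read")
        arr = self._array(request)
        (x0, x1), (y0, y1), (z0, z1) = request.ranges
        return VolumeBlock(request=request, data=arr[z0:z1, y0:y1, x0:x1].copy())

    def post_cutout(self, request: CutoutRequest, data: np.ndarray) -> None:
        self._require("write")
        arr = self._array(request)
        data = np.asarray(data)
        if data.dtype != request.resource.np_dtype:
            raise DtypeError(
                f"write dtype {data.dtype} != resource dtype {request.resource.np_dtype}"
            )
        if tuple(data.shape) != request.shape:
            raise ShapeError(f"write shape {tuple(data.shape)} != request shape {request.shape}")
        (x0, x1), (y0, y1), (z0, z1) = request.ranges
        arr[z0:z1, y0:y1, x0:x1] = data
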