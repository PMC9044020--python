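"""HTTP client Remote for the cutout REST dialect.

Speaks to the bundled reference server (or a relay, which serves the same
dialect). Idempotent GETs are retried with exponential backoff up to the
configured count; POSTs are never auto-retried. Large reads can be split
into chunk-aligned sub-requests fetched by a thread pool to saturate
client bandwidth; the assembled result is bit-identical to a single
request.
"""

from __future__ import annotations

import gzip
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from dataclasses import replace
from typing import Dict, Optional

import numpy as np

from ..chunking import ChunkShape, decompose
from ..core import CutoutRequest, Remote, Resource, VolumeBlock, validate_request
from ..errors import (
    AlreadyExistsError,
    CapabilityError,
    NotFoundError,
    UpstreamUnavailableError,
    VoxelKitError,
)

DEFAULT_WORKERS = 4

_CODE_ERRORS = {404: NotFoundError, 403: CapabilityError, 409: AlreadyExistsError}


class HttpRemote(Remote):
    capabilities = frozenset({"read"})  # refined from the server at connect time

    def __init__(self, base_url: str, timeout: float = 10.0, retries: int = 3,
                 workers: int = DEFAULT_WORKERS, backoff: float = 0.05):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout
        self.retries = retries
        self.workers = workers
        self.backoff = backoff
        self._meta_cache: Dict[str, dict] = {}
        self.capabilities = frozenset(self._get_json("/v1/capabilities")["capabilities"]) | {"read"}

    # -- transport -------------------------------------------------------

    def _raise_for(self, err: urllib.error.HTTPError):
        try:
            message = json.loads(err.read()).get("message", "")
        except Exception:  # noqa: BLE001 - body may not be JSON
            message = err.reason
        exc_type = _CODE_ERRORS.get(err.code, VoxelKitError)
        raise exc_type(f"HTTP {err.code}: {message}") from None

    def _request(self, path: str, data: Optional[bytes] = None, retry: bool = True) -> bytes:
        url = self.base_url + path
        attempts = (self.retries + 1) if retry else 1
        for attempt in range(attempts):
            try:
                req = urllib.request.Request(url, data=data)
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    return resp.read()
            except urllib.error.HTTPError as err:
                self._raise_for(err)  # server answered: no retry
            except (urllib.error.URLError, ConnectionError, TimeoutError) as err:
                if attempt + 1 >= attempts:
                    raise UpstreamUnavailableError(f"cannot reach {url}: {err}") from None
                time.sleep(self.backoff * (2**attempt))
        raise AssertionError("unreachable")

    def _get_json(self, path: str):
        return json.loads(self._request(path))

    # -- resources -------------------------------------------------------

    def _resource_path(self, resource_or_uri) -> str:
        if isinstance(resource_or_uri, Resource):
            return "/".join(resource_or_uri.path)
        from ..core import parse_uri

        _, path = parse_uri(resource_or_uri)
        return "/".join(path)

    def _meta(self, resource_or_uri) -> dict:
        path = self._resource_path(resource_or_uri)
        if path not in self._meta_cache:
            self._meta_cache[path] = self._get_json(f"/v1/resource/{path}")
        return self._meta_cache[path]

    def get_resource(self, uri: str) -> Resource:
        return Resource.from_dict(self._meta(uri))

    def chunk_shape(self, resource: Resource) -> ChunkShape:
        return ChunkShape.of(self._meta(resource)["chunk_shape"])

    def create_resource(self, resource: Resource) -> Resource:
        self._require("create")
        body = json.dumps(resource.to_dict()).encode()
        req = urllib.request.Request(
            self.base_url + "/v1/resource", data=body,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                resp.read()
        except urllib.error.HTTPError as err:
            self._raise_for(err)
        except (urllib.error.URLError, ConnectionError, TimeoutError) as err:
            raise UpstreamUnavailableError(f"cannot reach {self.base_url}: {err}") from None
        self._meta_cache.pop("/".join(resource.path), None)
        return resource

    def list_resources(self, prefix: str = "") -> list:
        self._require("list")
        q = urllib.parse.urlencode({"prefix": prefix})
        return self._get_json(f"/v1/list?{q}")

    def cache_stats(self) -> dict:
        """Relay cache counters, when the server end is a caching relay."""
        return self._get_json("/v1/cache/stats")

    # -- voxels ----------------------------------------------------------

    def _cutout_path(self, request: CutoutRequest) -> str:
        p = "/".join(request.resource.path)
        (x0, x1), (y0, y1), (z0, z1) = request.ranges
        return f"/v1/cutout/{p}/{request.resolution}/{x0}:{x1}/{y0}:{y1}/{z0}:{z1}/"

    def _fetch_box(self, request: CutoutRequest) -> np.ndarray:
        raw = gzip.decompress(self._request(self._cutout_path(request)))
        dtype = request.resource.np_dtype.newbyteorder("<")
        expected = request.n_voxels * dtype.itemsize
        if len(raw) != expected:
            raise VoxelKitError(f"payload holds {len(raw)} bytes, expected {expected}")
        return (
            np.frombuffer(raw, dtype=dtype)
            .reshape(request.shape)
            .astype(request.resource.np_dtype, copy=False)
        )

    def get_cutout(self, request: CutoutRequest, workers: Optional[int] = None) -> VolumeBlock:
        resource = self.get_resource(request.resource.uri)
        request = replace(request, resource=resource)
        validate_request(request)
        workers = self.workers if workers is None else workers
        if workers <= 1:
            return VolumeBlock(request=request, data=self._fetch_box(request))
        plan = decompose(request, self.chunk_shape(resource))
        if len(plan) == 1:
            return VolumeBlock(request=request, data=self._fetch_box(request))
        out = np.zeros(request.shape, dtype=resource.np_dtype)

        def fetch(entry):
            sub = replace(
                request,
                x_range=entry.global_box[0],
                y_range=entry.global_box[1],
                z_range=entry.global_box[2],
            )
            return entry, self._fetch_box(sub)

        with ThreadPoolExecutor(max_workers=workers) as pool:
            for entry, arr in pool.map(fetch, plan):
                (lx0, lx1), (ly0, ly1), (lz0, lz1) = entry.local_box
                out[lz0:lz1, ly0:ly1, lx0:lx1] = arr
        return VolumeBlock(request=request, data=out)

    def post_cutout(self, request: CutoutRequest, data: np.ndarray) -> None:
        self._require("write")
        resource = self.get_resource(request.resource.uri)
        request = replace(request, resource=resource)
        validate_request(request)
        data = np.asarray(data)
        if data.dtype != resource.np_dtype:
            from ..errors import DtypeError

            raise DtypeError(f"write dtype {data.dtype} != resource dtype {resource.np_dtype}")
        if tuple(data.shape) != request.shape:
            from ..errors import ShapeError

            raise ShapeError(f"write shape {tuple(data.shape)} != request shape {request.shape}")
        raw = np.ascontiguousarray(data.astype(data.dtype.newbyteorder("<"), copy=False)).tobytes()
        self._request(self._cutout_path(request), data=gzip.compress(raw, compresslevel=1),
                      retry=False)
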