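"""Bundled reference HTTP server speaking the cutout REST dialect.

Serves any backing :class:`~voxelkit.core.Remote` (in-memory, chunked-file,
a caching relay, ...) over a small REST surface::

    GET  /v1/capabilities
    GET  /v1/resource/{collection}/{experiment}/{channel}   (or /{name})
    POST /v1/resource                      JSON resource document
    GET  /v1/list?prefix=coll/exp
    GET  /v1/cutout/{path...}/{res}/{xs}:{xe}/{ys}:{ye}/{zs}:{ze}/
    POST /v1/cutout/...                    gzip raw little-endian payload
    GET  /v1/cache/stats                   (relays only)

Cutout payloads are the C-order (z, y, x) little-endian raw array,
gzip-compressed; the dtype is implied by the resource. Responses decoded
by the bundled client are byte-identical to direct backing-store calls.
"""

from __future__ import annotations

import gzip
import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional
from urllib.parse import parse_qs, urlparse

import numpy as np

from ..core import CutoutRequest, Remote, Resource, validate_request
from ..errors import (
    AlreadyExistsError,
    BoundsError,
    CapabilityError,
    DtypeError,
    EmptyRangeError,
    NotFoundError,
    ResolutionError,
    ShapeError,
    VoxelKitError,
)

__all__ = ["ReferenceServer", "serve_reference"]

_STATUS = {
    NotFoundError: 404,
    CapabilityError: 403,
    AlreadyExistsError: 409,
    BoundsError: 400,
    EmptyRangeError: 400,
    ResolutionError: 400,
    DtypeError: 400,
    ShapeError: 400,
}


def _status_for(exc: Exception) -> int:
    for etype, code in _STATUS.items():
        if isinstance(exc, etype):
            return code
    return 400 if isinstance(exc, VoxelKitError) else 500


def _parse_range(token: str):
    parts = token.split(":")
    if len(parts) != 2:
        raise VoxelKitError(f"malformed range {token!r}, expected start:stop")
    try:
        start, stop = int(parts[0]), int(parts[1])
    except ValueError:
        raise VoxelKitError(f"malformed range {token!r}, expected integers") from None
    return (start, stop)


def _uri_for_path(path_parts):
    if len(path_parts) == 1:
        return "instance://" + path_parts[0]
    if len(path_parts) == 3:
        return "bosslike://" + "/".join(path_parts)
    raise NotFoundError(f"resource path must have 1 or 3 components, got {path_parts}")


class _Handler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    # the server instance injects these
    backing: Remote = None
    advertised: frozenset = frozenset()

    def log_message(self, fmt, *args):  # quiet by default
        pass

    # -- plumbing --------------------------------------------------------

    def _send(self, code: int, body: bytes, content_type: str = "application/octet-stream"):
        self.send_response(code)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _send_json(self, code: int, obj):
        self._send(code, json.dumps(obj).encode(), "application/json")

    def _error(self, exc: Exception):
        self._send_json(_status_for(exc), {"error": type(exc).__name__, "message": str(exc)})

    def _read_body(self) -> bytes:
        length = int(self.headers.get("Content-Length", "0"))
        return self.rfile.read(length)

    def _cutout_request(self, segments) -> CutoutRequest:
        if len(segments) < 5:
            raise VoxelKitError("cutout path needs {path...}/{res}/{x}/{y}/{z}")
        *path_parts, res_s, xr, yr, zr = segments
        uri = _uri_for_path(tuple(path_parts))
        try:
            resolution = int(res_s)
        except ValueError:
            raise VoxelKitError(f"malformed resolution {res_s!r}") from None
        resource = self.backing.get_resource(uri)
        req = CutoutRequest(
            resource=resource,
            resolution=resolution,
            x_range=_parse_range(xr),
            y_range=_parse_range(yr),
            z_range=_parse_range(zr),
        )
        return validate_request(req)

    # -- routes ----------------------------------------------------------

    def do_GET(self):
        try:
            parsed = urlparse(self.path)
            segments = [s for s in parsed.path.split("/") if s]
            if segments[:2] == ["v1", "capabilities"]:
                self._send_json(200, {"capabilities": sorted(self.advertised)})
            elif segments[:2] == ["v1", "resource"]:
                uri = _uri_for_path(tuple(segments[2:]))
                resource = self.backing.get_resource(uri)
                doc = resource.to_dict()
                doc["chunk_shape"] = list(self.backing.chunk_shape(resource).as_xyz)
                self._send_json(200, doc)
            elif segments[:2] == ["v1", "list"]:
                prefix = parse_qs(parsed.query).get("prefix", [""])[0]
                self._send_json(200, self.backing.list_resources(prefix))
            elif segments[:2] == ["v1", "cutout"]:
                req = self._cutout_request(segments[2:])
                block = self.backing.get_cutout(req)
                raw = np.ascontiguousarray(
                    block.data.astype(block.data.dtype.newbyteorder("<"), copy=False)
                ).tobytes()
                self._send(200, gzip.compress(raw, compresslevel=1))
            elif segments[:2] == ["v1", "cache"] and segments[2:3] == ["stats"]:
                stats = getattr(self.backing, "cache_stats", None)
                if stats is None:
                    raise NotFoundError("backing store exposes no cache stats")
                self._send_json(200, stats())
            else:
                raise NotFoundError(f"no such endpoint {parsed.path}")
        except Exception as exc:  # noqa: BLE001 - every error becomes a status
            self._error(exc)

    def do_POST(self):
        try:
            parsed = urlparse(self.path)
            segments = [s for s in parsed.path.split("/") if s]
            if segments[:2] == ["v1", "resource"]:
                if "create" not in self.advertised:
                    raise CapabilityError("server is read-only: create not permitted")
                doc = json.loads(self._read_body())
                resource = Resource.from_dict(doc)
                self.backing.create_resource(resource)
                self._send_json(201, {"created": resource.uri})
            elif segments[:2] == ["v1", "cutout"]:
                if "write" not in self.advertised:
                    raise CapabilityError("server is read-only: write not permitted")
                req = self._cutout_request(segments[2:])
                raw = gzip.decompress(self._read_body())
                dtype = req.resource.np_dtype.newbyteorder("<")
                expected = req.n_voxels * dtype.itemsize
                if len(raw) != expected:
                    raise ShapeError(f"payload holds {len(raw)} bytes, expected {expected}")
                data = (
                    np.frombuffer(raw, dtype=dtype)
                    .reshape(req.shape)
                    .astype(req.resource.np_dtype, copy=False)
                )
                self.backing.post_cutout(req, data)
                self._send_json(200, {"written": req.n_voxels})
            else:
                raise NotFoundError(f"no such endpoint {parsed.path}")
        except Exception as exc:  # noqa: BLE001
            self._error(exc)


class ReferenceServer:
    """A reference server bound to a host/port, running on a daemon thread.

    Use as a context manager in tests, or call :meth:`serve_forever` from
    the CLI for a blocking foreground server.
    """

    def __init__(self, backing: Remote, host: str = "127.0.0.1", port: int = 0,
                 read_only: bool = False):
        advertised = frozenset(backing.capabilities)
        if read_only:
            advertised = advertised - {"write", "create"}
        handler = type(
            "_BoundHandler", (_Handler,), {"backing": backing, "advertised": advertised}
        )
        self.backing = backing
        self._httpd = ThreadingHTTPServer((host, port), handler)
        self._httpd.daemon_threads = True
        self._thread: Optional[threading.Thread] = None

    @property
    def base_url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "ReferenceServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)
            self._thread = None

    def serve_forever(self) -> None:
        self._httpd.serve_forever()

    def __enter__(self) -> "ReferenceServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve_reference(backing: Remote, host: str = "127.0.0.1", port: int = 0,
                    read_only: bool = False) -> ReferenceServer:
    """Construct (but do not start) a reference server over ``backing``."""
    return ReferenceServer(backing, host=host, port=port, read_only=read_only)
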