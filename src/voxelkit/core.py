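"""Core trait architecture and shared coordinate/data types.

The library is organised around three trait-based interfaces, the pattern
used by large-volume connectomics stores:

* **Remote** — a data-storage backend. Every remote provides at minimum
  volumetric reads (``read``); it may additionally declare ``write``,
  ``create``, ``list`` and ``mesh_server_side`` capabilities.
* **Resource** — an addressable unit of data inside a remote: either the
  hierarchical collection/experiment/channel form, or a flat data-instance.
* **Service** — a computation over remote data (e.g. meshing). A service
  declares the capabilities it requires; any remote satisfying them can run
  it, and the output is independent of which remote supplied the voxels.

Coordinate convention: the public API takes ranges in X, Y, Z order as
0-based half-open intervals ``[start, stop)``; arrays are indexed
``(z, y, x)`` so the fastest-varying axis (x) is last.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    BoundsError,
    DtypeError,
    EmptyRangeError,
    ResolutionError,
    ShapeError,
    VoxelKitError,
)

__all__ = [
    "CoordinateFrame",
    "Resource",
    "CutoutRequest",
    "VolumeBlock",
    "Remote",
    "Service",
    "capability_check",
    "validate_request",
    "parse_uri",
    "CAPABILITIES",
]

#: The full capability vocabulary a Remote may declare.
CAPABILITIES = frozenset({"read", "write", "create", "list", "mesh_server_side"})

_NAME_RE = re.compile(r"^[^\s/\\]+$")

_IMAGE_DTYPES = ("uint8", "uint16")
_ANNOTATION_DTYPE = "uint64"


@dataclass(frozen=True)
class CoordinateFrame:
    """Voxel extents, resolution pyramid and physical voxel size of a channel.

    Parameters
    ----------
    extents
        (X, Y, Z) voxel counts at resolution 0.
    voxel_size
        Physical size of one voxel along (X, Y, Z), in ``voxel_unit``.
    voxel_unit
        Unit tag for ``voxel_size``; nanometers by default (EM convention).
    num_resolutions
        Number of resolution levels in the pyramid (level 0 is full-res).
    downsample_factor
        Per-level integer downsampling factor applied to X and Y.
    downsample_z
        Whether Z is downsampled too. Defaults to False — the anisotropic
        electron-microscopy convention where Z sections are much coarser
        than the in-plane resolution.
    """

    extents: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    voxel_unit: str = "nanometers"
    num_resolutions: int = 1
    downsample_factor: int = 2
    downsample_z: bool = False

    def __post_init__(self):
        object.__setattr__(self, "extents", tuple(int(e) for e in self.extents))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if len(self.extents) != 3 or any(e < 0 for e in self.extents):
            raise VoxelKitError(f"extents must be three non-negative ints, got {self.extents}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VoxelKitError(f"voxel_size must be three positive reals, got {self.voxel_size}")
        if self.num_resolutions < 1:
            raise VoxelKitError("num_resolutions must be >= 1")
        if self.downsample_factor < 1:
            raise VoxelKitError("downsample_factor must be >= 1")

    def extents_at(self, resolution: int) -> Tuple[int, int, int]:
        """Voxel extents at a resolution level: ceil(extent / factor**level)
        along downsampled axes, unchanged along exempt axes."""
        if not 0 <= resolution < self.num_resolutions:
            raise ResolutionError(
                f"resolution {resolution} outside [0, {self.num_resolutions})"
            )
        f = self.downsample_factor ** resolution
        x, y, z = self.extents
        return (
            math.ceil(x / f),
            math.ceil(y / f),
            math.ceil(z / f) if self.downsample_z else z,
        )

    def voxel_size_at(self, resolution: int) -> Tuple[float, float, float]:
        f = self.downsample_factor ** resolution
        x, y, z = self.voxel_size
        return (x * f, y * f, z * f if self.downsample_z else z)

    def to_dict(self) -> dict:
        return {
            "extents": list(self.extents),
            "voxel_size": list(self.voxel_size),
            "voxel_unit": self.voxel_unit,
            "num_resolutions": self.num_resolutions,
            "downsample_factor": self.downsample_factor,
            "downsample_z": self.downsample_z,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinateFrame":
        return cls(
            extents=tuple(d["extents"]),
            voxel_size=tuple(d.get("voxel_size", (1.0, 1.0, 1.0))),
            voxel_unit=d.get("voxel_unit", "nanometers"),
            num_resolutions=int(d.get("num_resolutions", 1)),
            downsample_factor=int(d.get("downsample_factor", 2)),
            downsample_z=bool(d.get("downsample_z", False)),
        )


@dataclass(frozen=True)
class Resource:
    """Pointer to an atomic unit or grouping of data in a Remote.

    Either hierarchical (``collection`` -> ``experiment`` -> ``channel``) or
    a flat ``data_instance``. Channels and data-instances carry voxel
    metadata: a dtype, a channel kind (``image`` holds intensities,
    ``annotation`` holds uint64 object labels) and a
    :class:`CoordinateFrame`.
    """

    kind: str
    path: Tuple[str, ...]
    channel_kind: Optional[str] = None
    dtype: Optional[str] = None
    frame: Optional[CoordinateFrame] = None
    version: Optional[str] = None  # opaque tag; only one version is stored

    _EXPECTED_LEN = {"collection": 1, "experiment": 2, "channel": 3, "data_instance": 1}

    def __post_init__(self):
        object.__setattr__(self, "path", tuple(self.path))
        if self.kind not in self._EXPECTED_LEN:
            raise VoxelKitError(f"unknown resource kind {self.kind!r}")
        if len(self.path) != self._EXPECTED_LEN[self.kind]:
            raise VoxelKitError(
                f"{self.kind} resource needs {self._EXPECTED_LEN[self.kind]} "
                f"path component(s), got {self.path!r}"
            )
        for part in self.path:
            if not _NAME_RE.match(part):
                raise VoxelKitError(
                    f"path component {part!r} is empty or contains separators/whitespace"
                )
        if self.is_volume:
            if self.channel_kind not in ("image", "annotation"):
                raise VoxelKitError(
                    f"channel_kind must be 'image' or 'annotation', got {self.channel_kind!r}"
                )
            if self.channel_kind == "annotation" and self.dtype != _ANNOTATION_DTYPE:
                raise DtypeError(
                    f"annotation channels are {_ANNOTATION_DTYPE}, got {self.dtype!r}"
                )
            if self.channel_kind == "image" and self.dtype not in _IMAGE_DTYPES:
                raise DtypeError(
                    f"image channels are one of {_IMAGE_DTYPES}, got {self.dtype!r}"
                )
        else:
            if self.channel_kind is not None or self.dtype is not None or self.frame is not None:
                raise VoxelKitError(f"{self.kind} resources carry no voxel metadata")

    # -- constructors ----------------------------------------------------

    @classmethod
    def collection(cls, name: str) -> "Resource":
        return cls(kind="collection", path=(name,))

    @classmethod
    def experiment(cls, collection: str, name: str) -> "Resource":
        return cls(kind="experiment", path=(collection, name))

    @classmethod
    def channel(
        cls,
        collection: str,
        experiment: str,
        name: str,
        *,
        dtype: str = "uint8",
        channel_kind: str = "image",
        frame: Optional[CoordinateFrame] = None,
    ) -> "Resource":
        return cls(
            kind="channel",
            path=(collection, experiment, name),
            channel_kind=channel_kind,
            dtype=dtype,
            frame=frame,
        )

    @classmethod
    def data_instance(
        cls,
        name: str,
        *,
        dtype: str = "uint8",
        channel_kind: str = "image",
        frame: Optional[CoordinateFrame] = None,
        version: Optional[str] = None,
    ) -> "Resource":
        return cls(
            kind="data_instance",
            path=(name,),
            channel_kind=channel_kind,
            dtype=dtype,
            frame=frame,
            version=version,
        )

    # -- properties ------------------------------------------------------

    @property
    def is_volume(self) -> bool:
        """True for resources that address voxels (channel or data_instance)."""
        return self.kind in ("channel", "data_instance")

    @property
    def uri(self) -> str:
        """Canonical URI: ``bosslike://coll/exp/chan`` or ``instance://name``."""
        if self.kind == "data_instance":
            return "instance://" + self.path[0]
        return "bosslike://" + "/".join(self.path)

    @property
    def np_dtype(self) -> np.dtype:
        if self.dtype is None:
            raise DtypeError(f"{self.kind} resource has no dtype")
        return np.dtype(self.dtype)

    def with_frame(self, frame: CoordinateFrame) -> "Resource":
        return replace(self, frame=frame)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "path": list(self.path)}
        if self.is_volume:
            d.update(
                channel_kind=self.channel_kind,
                dtype=self.dtype,
                frame=self.frame.to_dict() if self.frame else None,
            )
            if self.version is not None:
                d["version"] = self.version
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Resource":
        frame = d.get("frame")
        return cls(
            kind=d["kind"],
            path=tuple(d["path"]),
            channel_kind=d.get("channel_kind"),
            dtype=d.get("dtype"),
            frame=CoordinateFrame.from_dict(frame) if frame else None,
            version=d.get("version"),
        )


def parse_uri(uri: str) -> Tuple[str, Tuple[str, ...]]:
    """Parse a canonical resource URI into (kind, path components).

    ``bosslike://`` URIs map to collection/experiment/channel by component
    count; ``instance://`` URIs are flat data-instances. The metadata
    (dtype, frame) lives with the remote and is resolved by
    ``Remote.get_resource``.
    """
    if uri.startswith("instance://"):
        name = uri[len("instance://"):]
        if not name or "/" in name:
            raise VoxelKitError(f"malformed instance URI {uri!r}")
        return "data_instance", (name,)
    if uri.startswith("bosslike://"):
        parts = tuple(p for p in uri[len("bosslike://"):].split("/") if p != "")
        kinds = {1: "collection", 2: "experiment", 3: "channel"}
        if len(parts) not in kinds:
            raise VoxelKitError(f"malformed bosslike URI {uri!r}")
        return kinds[len(parts)], parts
    raise VoxelKitError(f"unknown URI scheme in {uri!r}")


@dataclass(frozen=True)
class CutoutRequest:
    """An axis-aligned half-open 3D box plus resolution level.

    Ranges are given in X, Y, Z order; the resulting array is (z, y, x).
    """

    resource: Resource
    resolution: int
    x_range: Tuple[int, int]
    y_range: Tuple[int, int]
    z_range: Tuple[int, int]

    def __post_init__(self):
        for name in ("x_range", "y_range", "z_range"):
            rng = getattr(self, name)
            object.__setattr__(self, name, (int(rng[0]), int(rng[1])))
        if not self.resource.is_volume:
            raise VoxelKitError("cutouts address channel or data_instance resources only")

    @property
    def ranges(self) -> Tuple[Tuple[int, int], ...]:
        """(x_range, y_range, z_range)."""
        return (self.x_range, self.y_range, self.z_range)

    @property
    def shape(self) -> Tuple[int, int, int]:
        """Array shape (z, y, x) of the requested box."""
        return (
            self.z_range[1] - self.z_range[0],
            self.y_range[1] - self.y_range[0],
            self.x_range[1] - self.x_range[0],
        )

    @property
    def n_voxels(self) -> int:
        dz, dy, dx = self.shape
        return dz * dy * dx

    def translated(self, dx: int, dy: int, dz: int) -> "CutoutRequest":
        return replace(
            self,
            x_range=(self.x_range[0] + dx, self.x_range[1] + dx),
            y_range=(self.y_range[0] + dy, self.y_range[1] + dy),
            z_range=(self.z_range[0] + dz, self.z_range[1] + dz),
        )


def validate_request(
    request: CutoutRequest, frame: Optional[CoordinateFrame] = None
) -> CutoutRequest:
    """Check a cutout request against its coordinate frame.

    Returns the request unchanged if every invariant holds (so validation
    is idempotent). ``frame`` defaults to the frame carried by the
    request's resource.

    Raises
    ------
    EmptyRangeError
        if start >= stop on any axis.
    BoundsError
        if a range starts below 0 or stops beyond the frame extent at the
        requested resolution; the error names the axis.
    ResolutionError
        if the resolution level is outside the frame's pyramid.
    """
    frame = frame if frame is not None else request.resource.frame
    if frame is None:
        raise VoxelKitError("no coordinate frame available to validate against")
    if not 0 <= request.resolution < frame.num_resolutions:
        raise ResolutionError(
            f"resolution {request.resolution} outside [0, {frame.num_resolutions})"
        )
    extents = frame.extents_at(request.resolution)
    for axis, rng, extent in zip("xyz", request.ranges, extents):
        start, stop = rng
        if start >= stop:
            raise EmptyRangeError(axis, f"empty range on {axis}: [{start}, {stop})")
        if start < 0:
            raise BoundsError(axis, f"{axis} start {start} < 0")
        if stop > extent:
            raise BoundsError(
                axis,
                f"{axis} stop {stop} exceeds extent {extent} at resolution {request.resolution}",
            )
    return request


@dataclass
class VolumeBlock:
    """A dense (z, y, x) array tied to the cutout request that produced it.

    The universal payload between remotes and services.
    """

    request: CutoutRequest
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"VolumeBlock data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != self.request.shape:
            raise ShapeError(
                f"data shape {tuple(self.data.shape)} != request shape {self.request.shape}"
            )
        expected = self.request.resource.np_dtype
        if self.data.dtype != expected:
            raise DtypeError(f"data dtype {self.data.dtype} != resource dtype {expected}")

    @property
    def resource(self) -> Resource:
        return self.request.resource

    @property
    def origin(self) -> Tuple[int, int, int]:
        """(x0, y0, z0) of the box in global voxel coordinates."""
        return (self.request.x_range[0], self.request.y_range[0], self.request.z_range[0])

    def __getitem__(self, idx):
        return self.data[idx]


class Remote:
    """Trait contract for data-storage backends.

    Subclasses set :attr:`capabilities` and implement the operations their
    capabilities promise. ``read`` is mandatory for every remote.
    """

    #: Capabilities this remote declares; must include "read".
    capabilities: frozenset = frozenset({"read"})

    def __init_subclass__(cls, **kw):
        super().__init_subclass__(**kw)
        if "read" not in cls.capabilities:
            raise TypeError(f"{cls.__name__} must declare at least the 'read' capability")

    # -- interface -------------------------------------------------------

    def get_resource(self, uri: str) -> Resource:
        """Resolve a URI to a fully-populated Resource (dtype, frame)."""
        raise NotImplementedError

    def create_resource(self, resource: Resource) -> Resource:
        raise NotImplementedError

    def list_resources(self, prefix: str = "") -> list:
        raise NotImplementedError

    def get_cutout(self, request: CutoutRequest, workers: Optional[int] = None) -> VolumeBlock:
        raise NotImplementedError

    def post_cutout(self, request: CutoutRequest, data: np.ndarray) -> None:
        raise NotImplementedError

    def chunk_shape(self, resource: Resource):
        """The chunk (cuboid) shape this remote stores ``resource`` in.

        Used by callers that want to align requests — or cache keys — with
        the backend's storage subdivisions.
        """
        raise NotImplementedError

    # -- helpers shared by implementations -------------------------------

    def _require(self, capability: str) -> None:
        from .errors import CapabilityError

        if capability not in self.capabilities:
            raise CapabilityError(
                f"{type(self).__name__} lacks the {capability!r} capability"
            )

    def cutout(
        self,
        uri: str,
        x_range: Sequence[int],
        y_range: Sequence[int],
        z_range: Sequence[int],
        resolution: int = 0,
        workers: Optional[int] = None,
    ) -> VolumeBlock:
        """Convenience wrapper: resolve the URI, build and validate the
        request, and fetch it."""
        resource = self.get_resource(uri)
        req = CutoutRequest(
            resource=resource,
            resolution=resolution,
            x_range=tuple(x_range),
            y_range=tuple(y_range),
            z_range=tuple(z_range),
        )
        validate_request(req)
        return self.get_cutout(req, workers=workers)


class Service:
    """Trait contract for computations over remote data.

    A service declares ``required_capabilities``; :func:`capability_check`
    decides whether a given remote can run it. The contract is that output
    depends only on the voxels, never on which remote supplied them.
    """

    required_capabilities: frozenset = frozenset({"read"})

    def can_run(self, remote: Remote) -> bool:
        return capability_check(remote, self)


def capability_check(remote: Remote, service: Service) -> bool:
    """True iff the service's required capabilities are a subset of the
    remote's declared capabilities."""
    return frozenset(service.required_capabilities) <= frozenset(remote.capabilities)
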