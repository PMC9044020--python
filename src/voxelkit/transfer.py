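"""Remote-to-remote subvolume copy with chunked streaming and verification.

The headline interoperability use case: voxels held in one store (say, a
cloud service) are streamed block-by-block into another (say, a local
chunked-file store) to leverage each store's unique capabilities. Blocks
follow the *destination's* chunk shape, which minimises destination write
amplification; at most ``workers`` blocks are resident at once. No dtype
casting, ever: a mismatch aborts before any write.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chunking import ChunkShape, decompose
from .core import CutoutRequest, Remote, Resource, validate_request
from .errors import DtypeError, TransferError, VoxelKitError

__all__ = ["TransferJob", "TransferReport", "transfer_subvolume", "verify_transfer"]


@dataclass
class TransferJob:
    """A source box, a destination resource and an offset.

    ``destination[x + dx, y + dy, z + dz] = source[x, y, z]`` for every
    (x, y, z) in the source box.
    """

    source: Remote
    source_resource: Resource
    box: CutoutRequest
    destination: Remote
    destination_resource: Resource
    offset: Tuple[int, int, int] = (0, 0, 0)
    resolution: int = 0
    workers: int = 1
    status: Dict[int, str] = field(default_factory=dict)  # block index -> pending/done/failed

    def dest_request(self, sub: CutoutRequest) -> CutoutRequest:
        dx, dy, dz = self.offset
        return CutoutRequest(
            resource=self.destination_resource,
            resolution=sub.resolution,
            x_range=(sub.x_range[0] + dx, sub.x_range[1] + dx),
            y_range=(sub.y_range[0] + dy, sub.y_range[1] + dy),
            z_range=(sub.z_range[0] + dz, sub.z_range[1] + dz),
        )

    def plan(self):
        """Block plan over the destination box, in the destination's chunk
        shape, mapped back to source coordinates."""
        dest_box = self.dest_request(self.box)
        chunks = ChunkShape.of(self.destination.chunk_shape(self.destination_resource))
        return decompose(dest_box, chunks)

    def _check(self) -> None:
        src = self.source.get_resource(self.source_resource.uri)
        dst = self.destination.get_resource(self.destination_resource.uri)
        if src.dtype != dst.dtype:
            raise DtypeError(
                f"source dtype {src.dtype} != destination dtype {dst.dtype}; "
                "transfers never cast"
            )
        self.source_resource = src
        self.destination_resource = dst
        validate_request(replace(self.box, resource=src))
        validate_request(self.dest_request(replace(self.box, resource=src)))


@dataclass
class TransferReport:
    blocks_copied: int
    bytes_moved: int
    failures: List[str]

    @property
    def ok(self) -> bool:
        return not self.failures


def transfer_subvolume(job: TransferJob) -> TransferReport:
    """Stream the source box into the destination, block by block.

    The dtype check runs before any write. A block failure is recorded and
    the remaining blocks still run, so an idempotent re-run completes the
    job; completed blocks stay written.
    """
    job._check()
    dx, dy, dz = job.offset
    plan = job.plan()
    copied = 0
    bytes_moved = 0
    failures: List[str] = []
    for idx, entry in enumerate(plan):
        if job.status.get(idx) == "done":
            continue
        job.status[idx] = "pending"
        (gx0, gx1), (gy0, gy1), (gz0, gz1) = entry.global_box
        src_req = CutoutRequest(
            resource=job.source_resource, resolution=job.box.resolution,
            x_range=(gx0 - dx, gx1 - dx), y_range=(gy0 - dy, gy1 - dy),
            z_range=(gz0 - dz, gz1 - dz),
        )
        dst_req = CutoutRequest(
            resource=job.destination_resource, resolution=job.box.resolution,
            x_range=(gx0, gx1), y_range=(gy0, gy1), z_range=(gz0, gz1),
        )
        try:
            block = job.source.get_cutout(src_req, workers=job.workers)
            job.destination.post_cutout(dst_req, block.data)
        except VoxelKitError as exc:
            job.status[idx] = "failed"
            failures.append(f"block {idx} {entry.global_box}: {exc}")
            continue
        job.status[idx] = "done"
        copied += 1
        bytes_moved += block.data.nbytes
    return TransferReport(blocks_copied=copied, bytes_moved=bytes_moved, failures=failures)


def verify_transfer(job: TransferJob, sample_fraction: float = 1.0,
                    seed: int = 0) -> Tuple[bool, List[str]]:
    """Re-read and compare blocks after a transfer.

    At fraction 1.0 every block is compared; below that a deterministic
    seeded sample is drawn, so repeated runs check the same subset.
    Returns (all_match, list of mismatching block descriptions).
    """
    if not 0 < sample_fraction <= 1.0:
        raise TransferError("sample_fraction must be in (0, 1]")
    job._check()
    dx, dy, dz = job.offset
    plan = job.plan()
    indices = np.arange(len(plan))
    if sample_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n = max(1, int(round(sample_fraction * len(plan))))
        indices = np.sort(rng.choice(indices, size=n, replace=False))
    mismatches: List[str] = []
    for idx in indices:
        entry = plan[int(idx)]
        (gx0, gx1), (gy0, gy1), (gz0, gz1) = entry.global_box
        src_req = CutoutRequest(
            resource=job.source_resource, resolution=job.box.resolution,
            x_range=(gx0 - dx, gx1 - dx), y_range=(gy0 - dy, gy1 - dy),
            z_range=(gz0 - dz, gz1 - dz),
        )
        dst_req = CutoutRequest(
            resource=job.destination_resource, resolution=job.box.resolution,
            x_range=(gx0, gx1), y_range=(gy0, gy1), z_range=(gz0, gz1),
        )
        src = job.source.get_cutout(src_req).data
        dst = job.destination.get_cutout(dst_req).data
        if not np.array_equal(src, dst):
            mismatches.append(f"block {int(idx)} {entry.global_box}")
    return (not mismatches, mismatches)
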