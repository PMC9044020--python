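import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxelkit as vk
from voxelkit import fixtures as fx

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Small chunk shape used throughout the suite so requests straddle many
#: chunk boundaries without large volumes.
SMALL_CHUNKS = (32, 32, 8)

RAMP_EXTENTS = (100, 90, 40)  # X, Y, Z


def make_ramp_channel() -> vk.Resource:
    frame = vk.CoordinateFrame(extents=RAMP_EXTENTS, voxel_size=(4.0, 4.0, 40.0),
                               num_resolutions=3)
    return vk.Resource.channel("col", "exp", "ramp", dtype="uint8", frame=frame)


def full_request(resource: vk.Resource, resolution: int = 0) -> vk.CutoutRequest:
    ex, ey, ez = resource.frame.extents_at(resolution)
    return vk.CutoutRequest(resource=resource, resolution=resolution,
                            x_range=(0, ex), y_range=(0, ey), z_range=(0, ez))


def load_ramp(remote: vk.Remote) -> vk.Resource:
    """Create the ramp channel on a remote and fill it with the formula."""
    resource = make_ramp_channel()
    remote.create_resource(resource)
    ramp = fx.make_ramp_volume(RAMP_EXTENTS)
    remote.post_cutout(full_request(resource), ramp.data)
    return resource


@pytest.fixture
def ramp_channel():
    return make_ramp_channel()


@pytest.fixture
def memory_ramp():
    remote = vk.InMemoryRemote(default_chunk_shape=SMALL_CHUNKS)
    resource = load_ramp(remote)
    return remote, resource


@pytest.fixture
def file_ramp(tmp_path):
    remote = vk.FileChunkRemote(tmp_path / "store", default_chunk_shape=SMALL_CHUNKS)
    resource = load_ramp(remote)
    return remote, resource


@pytest.fixture
def http_ramp(file_ramp):
    backing, resource = file_ramp
    with vk.serve_reference(backing) as server:
        yield vk.HttpRemote(server.base_url, workers=1), resource


def random_request(rng: np.random.Generator, resource: vk.Resource,
                   resolution: int = 0) -> vk.CutoutRequest:
    extents = resource.frame.extents_at(resolution)
    ranges = []
    for ext in extents:
        lo = int(rng.integers(0, ext))
        hi = int(rng.integers(lo + 1, ext + 1))
        ranges.append((lo, hi))
    return vk.CutoutRequest(resource=resource, resolution=resolution,
                            x_range=ranges[0], y_range=ranges[1], z_range=ranges[2])
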