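"""Remote implementations: shared read/write semantics, the on-disk chunk
dialect, and the HTTP reference server."""

import json

import numpy as np
import pytest

import voxelkit as vk
from voxelkit import fixtures as fx
from voxelkit.errors import (
    AlreadyExistsError,
    BoundsError,
    CapabilityError,
    DtypeError,
    NotFoundError,
    ShapeError,
    VoxelKitError,
)
from conftest import RAMP_EXTENTS, SMALL_CHUNKS, full_request, load_ramp, \
    make_ramp_channel, random_request


def fresh_channel(name="ch", extents=(128, 128, 32), dtype="uint8"):
    frame = vk.CoordinateFrame(extents=extents)
    kind = "annotation" if dtype == "uint64" else "image"
    return vk.Resource.channel("c", "e", name, dtype=dtype, channel_kind=kind, frame=frame)


@pytest.fixture(params=["memory", "file"])
def any_remote(request, tmp_path):
    if request.param == "memory":
        return vk.InMemoryRemote(default_chunk_shape=SMALL_CHUNKS)
    return vk.FileChunkRemote(tmp_path / "store", default_chunk_shape=SMALL_CHUNKS)


class TestResourceLifecycle:
    def test_created_channel_reads_zeros_everywhere(self, any_remote):
        ch = fresh_channel()
        any_remote.create_resource(ch)
        block = any_remote.cutout(ch.uri, (0, 8), (0, 8), (0, 8))
        assert (block.data == 0).all()
        assert block.data.dtype == np.uint8

    def test_duplicate_create_is_rejected(self, any_remote):
        ch = fresh_channel()
        any_remote.create_resource(ch)
        with pytest.raises(AlreadyExistsError):
            any_remote.create_resource(ch)

    def test_unknown_resource_is_not_found(self, any_remote):
        with pytest.raises(NotFoundError):
            any_remote.get_resource("bosslike://no/such/channel")

    def test_listing_is_sorted_and_prefix_scoped(self, any_remote):
        for name in ("d", "c"):
            any_remote.create_resource(fresh_channel(name))
        assert any_remote.list_resources("c/e") == [
            "bosslike://c/e/c", "bosslike://c/e/d"]
        assert any_remote.list_resources("c") == ["bosslike://c/e"]
        assert any_remote.list_resources("nope") == []

    def test_data_instance_round_trip(self, any_remote):
        inst = vk.Resource.data_instance(
            "vol1", dtype="uint64", channel_kind="annotation",
            frame=vk.CoordinateFrame(extents=(32, 32, 8)), version="v0")
        any_remote.create_resource(inst)
        got = any_remote.get_resource("instance://vol1")
        assert got.kind == "data_instance" and got.dtype == "uint64"
        block = any_remote.cutout("instance://vol1", (0, 4), (0, 4), (0, 4))
        assert block.data.dtype == np.uint64


class TestWriteReadSemantics:
    def test_write_then_read_identical_box_is_bit_exact(self, any_remote):
        ch = fresh_channel()
        any_remote.create_resource(ch)
        rng = np.random.default_rng(0)
        data = rng.integers(0, 255, size=(8, 16, 24), dtype=np.uint8)
        req = vk.CutoutRequest(resource=ch, resolution=0, x_range=(3, 27),
                               y_range=(5, 21), z_range=(2, 10))
        any_remote.post_cutout(req, data)
        assert np.array_equal(any_remote.get_cutout(req).data, data)

    def test_last_writer_wins_on_overlap(self, any_remote):
        ch = fresh_channel()
        any_remote.create_resource(ch)
        box_a = vk.CutoutRequest(resource=ch, resolution=0, x_range=(0, 20),
                                 y_range=(0, 10), z_range=(0, 4))
        box_b = vk.CutoutRequest(resource=ch, resolution=0, x_range=(10, 30),
                                 y_range=(0, 10), z_range=(0, 4))
        any_remote.post_cutout(box_a, np.full((4, 10, 20), 1, dtype=np.uint8))
        any_remote.post_cutout(box_b, np.full((4, 10, 20), 2, dtype=np.uint8))
        union = any_remote.cutout(ch.uri, (0, 30), (0, 10), (0, 4))
        assert (union.data[:, :, 10:20] == 2).all()  # B wins on the overlap
        assert (union.data[:, :, :10] == 1).all()

    def test_dtype_mismatch_is_rejected_not_cast(self, any_remote):
        ch = fresh_channel(dtype="uint64")
        any_remote.create_resource(ch)
        req = vk.CutoutRequest(resource=ch, resolution=0, x_range=(0, 4),
                               y_range=(0, 4), z_range=(0, 4))
        with pytest.raises(DtypeError):
            any_remote.post_cutout(req, np.zeros((4, 4, 4), dtype=np.uint16))

    def test_ramp_random_boxes_match_formula(self, any_remote):
        resource = load_ramp(any_remote)
        rng = np.random.default_rng(21)
        for _ in range(25):
            req = random_request(rng, resource)
            block = any_remote.get_cutout(req)
            (x0, x1), (y0, y1), (z0, z1) = req.ranges
            zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
            assert np.array_equal(block.data, fx.ramp_value(xx, yy, zz).astype(np.uint8))

    def test_writes_at_higher_resolution_levels_are_independent(self, any_remote):
        ch = fresh_channel(extents=(64, 64, 16))
        frame = vk.CoordinateFrame(extents=(64, 64, 16), num_resolutions=2)
        ch = ch.with_frame(frame)
        any_remote.create_resource(ch)
        req1 = vk.CutoutRequest(resource=ch, resolution=1, x_range=(0, 32),
                                y_range=(0, 32), z_range=(0, 16))
        any_remote.post_cutout(req1, np.full((16, 32, 32), 9, dtype=np.uint8))
        assert (any_remote.get_cutout(req1).data == 9).all()
        req0 = vk.CutoutRequest(resource=ch, resolution=0, x_range=(0, 64),
                                y_range=(0, 64), z_range=(0, 16))
        assert (any_remote.get_cutout(req0).data == 0).all()


class TestFileChunkDialect:
    def test_durability_across_reopen(self, tmp_path):
        remote = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        resource = load_ramp(remote)
        before = remote.get_cutout(full_request(resource)).data
        reopened = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        after = reopened.get_cutout(full_request(resource)).data
        assert np.array_equal(before, after)

    def test_metadata_document_round_trips(self, tmp_path):
        remote = vk.FileChunkRemote(tmp_path / "s")
        ch = make_ramp_channel()
        remote.create_resource(ch)
        meta_path = tmp_path / "s" / "col" / "exp" / "ramp" / "metadata.json"
        doc = json.loads(meta_path.read_text())
        meta_path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        assert vk.FileChunkRemote(tmp_path / "s").get_resource(ch.uri) == ch

    def test_single_voxel_write_creates_at_most_one_chunk_file(self, tmp_path):
        remote = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        ch = fresh_channel()
        remote.create_resource(ch)
        req = vk.CutoutRequest(resource=ch, resolution=0, x_range=(40, 41),
                               y_range=(40, 41), z_range=(10, 11))
        remote.post_cutout(req, np.array([[[7]]], dtype=np.uint8))
        chunk_files = list((tmp_path / "s").rglob("*.bin"))
        assert len(chunk_files) == 1

    def test_all_zero_write_creates_no_files(self, tmp_path):
        remote = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        ch = fresh_channel()
        remote.create_resource(ch)
        req = vk.CutoutRequest(resource=ch, resolution=0, x_range=(0, 64),
                               y_range=(0, 64), z_range=(0, 16))
        remote.post_cutout(req, np.zeros((16, 64, 64), dtype=np.uint8))
        assert list((tmp_path / "s").rglob("*.bin")) == []

    def test_edge_chunks_are_truncated_on_disk(self, tmp_path):
        # extents (100, 90, 40) with (32, 32, 8) chunks: the (3, 2, 0) corner
        # chunk stores only 4 x 26 x 8 voxels
        remote = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        resource = load_ramp(remote)
        corner = tmp_path / "s" / "col" / "exp" / "ramp" / "res0" / "3_2_0.bin"
        assert corner.stat().st_size == (100 - 96) * (90 - 64) * 8

    def test_parallel_and_serial_reads_are_bit_identical(self, tmp_path):
        remote = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        resource = load_ramp(remote)
        rng = np.random.default_rng(17)
        for _ in range(100):
            req = random_request(rng, resource)
            serial = remote.get_cutout(req, workers=1)
            parallel = remote.get_cutout(req, workers=4)
            assert np.array_equal(serial.data, parallel.data)


class TestHttpDialect:
    def test_http_cutout_equals_direct_backing_call(self, http_ramp, file_ramp):
        http, resource = http_ramp
        backing, _ = file_ramp
        rng = np.random.default_rng(9)
        for _ in range(20):
            req = random_request(rng, resource)
            assert np.array_equal(http.get_cutout(req).data,
                                  backing.get_cutout(req).data)

    def test_parallel_http_fetch_matches_single_request(self, http_ramp):
        http, resource = http_ramp
        rng = np.random.default_rng(13)
        for _ in range(10):
            req = random_request(rng, resource)
            assert np.array_equal(http.get_cutout(req, workers=1).data,
                                  http.get_cutout(req, workers=4).data)

    def test_http_write_round_trip(self, http_ramp):
        http, resource = http_ramp
        rng = np.random.default_rng(1)
        data = rng.integers(0, 255, size=(8, 10, 12), dtype=np.uint8)
        req = vk.CutoutRequest(resource=resource, resolution=0, x_range=(4, 16),
                               y_range=(2, 12), z_range=(1, 9))
        http.post_cutout(req, data)
        assert np.array_equal(http.get_cutout(req).data, data)

    def test_malformed_range_is_a_400_class_error(self, http_ramp):
        import urllib.error
        import urllib.request

        http, resource = http_ramp
        url = http.base_url + "/v1/cutout/col/exp/ramp/0/10:5/0:8/0:8/"
        with pytest.raises(urllib.error.HTTPError) as err:
            urllib.request.urlopen(url)
        assert err.value.code == 400

    def test_unknown_channel_is_a_404(self, http_ramp):
        http, _ = http_ramp
        with pytest.raises(NotFoundError):
            http.get_resource("bosslike://col/exp/missing")

    def test_out_of_bounds_request_is_rejected(self, http_ramp):
        http, resource = http_ramp
        with pytest.raises(VoxelKitError):
            http.cutout(resource.uri, (0, RAMP_EXTENTS[0] + 1), (0, 8), (0, 8))

    def test_read_only_server_rejects_create_with_capability_error(self, file_ramp):
        backing, _ = file_ramp
        with vk.serve_reference(backing, read_only=True) as server:
            client = vk.HttpRemote(server.base_url)
            assert "create" not in client.capabilities
            with pytest.raises(CapabilityError):
                client.create_resource(fresh_channel("other"))

    def test_http_metadata_matches_backing(self, http_ramp, file_ramp):
        http, resource = http_ramp
        backing, _ = file_ramp
        got = http.get_resource(resource.uri)
        assert got == backing.get_resource(resource.uri)
        assert http.chunk_shape(got) == backing.chunk_shape(got)


class TestInterchangeability:
    def test_randomized_script_is_bit_identical_across_remote_kinds(self, tmp_path):
        """The same 60-step write/read script executed against the
        in-memory, chunked-file and HTTP remotes yields identical bytes at
        every read."""
        mem = vk.InMemoryRemote(default_chunk_shape=SMALL_CHUNKS)
        disk = vk.FileChunkRemote(tmp_path / "s", default_chunk_shape=SMALL_CHUNKS)
        with vk.serve_reference(
            vk.FileChunkRemote(tmp_path / "h", default_chunk_shape=SMALL_CHUNKS)
        ) as server:
            http = vk.HttpRemote(server.base_url, workers=1)
            remotes = [mem, disk, http]
            ch = fresh_channel(extents=(96, 80, 24))
            for remote in remotes:
                remote.create_resource(ch)
            rng = np.random.default_rng(123)
            for step in range(60):
                req = random_request(np.random.default_rng(1000 + step), ch)
                if rng.random() < 0.5:
                    data = np.random.default_rng(step).integers(
                        0, 255, size=req.shape, dtype=np.uint8)
                    for remote in remotes:
                        remote.post_cutout(req, data)
                else:
                    reads = [remote.get_cutout(req).data for remote in remotes]
                    assert np.array_equal(reads[0], reads[1])
                    assert np.array_equal(reads[0], reads[2])
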