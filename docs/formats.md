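# On-disk and wire formats

This file is the bit-exact specification of every format the toolkit
reads or writes. All multi-byte values are little-endian; all arrays are
C-order with axes (z, y, x); all intervals are 0-based and half-open.

## Resource URIs

- Hierarchical: `bosslike://{collection}/{experiment}/{channel}`
- Flat data-instance: `instance://{name}`

Path components are non-empty and contain no `/`, `\` or whitespace.

## Chunked-file store dialect

A store is a directory tree:

```
root/
  {collection}/{experiment}/{channel}/
      metadata.json
      res{r}/{i}_{j}_{k}.bin
  {name}/                       # flat data_instance, same inner layout
      metadata.json
      res{r}/{i}_{j}_{k}.bin
```

`metadata.json` is one JSON document per volume resource:

```json
{
  "kind": "channel",
  "path": ["col", "exp", "ramp"],
  "channel_kind": "image",
  "dtype": "uint8",
  "frame": {
    "extents": [100, 90, 40],
    "voxel_size": [4.0, 4.0, 40.0],
    "voxel_unit": "nanometers",
    "num_resolutions": 3,
    "downsample_factor": 2,
    "downsample_z": false
  },
  "chunk_shape": [32, 32, 8]
}
```

The document round-trips read -> write -> read identically. A directory
whose `metadata.json` has `"kind": "data_instance"` is listed under the
`instance://` scheme; every other directory level is part of the
collection/experiment hierarchy.

Chunk files:

- `{i}_{j}_{k}.bin` holds the chunk whose voxel box is
  `[i*cx,(i+1)*cx) x [j*cy,(j+1)*cy) x [k*cz,(k+1)*cz)` at resolution `r`.
- Contents are the raw little-endian array, C-order (z, y, x), with the
  resource dtype. No header, no compression.
- Chunks at the volume boundary are stored **truncated** to the extents at
  that resolution (file size = clipped_z * clipped_y * clipped_x *
  itemsize); readers zero-pad them back to full chunk shape in memory.
- An **absent** chunk file means an all-zero chunk. Writers never create a
  file for a chunk that has no file yet and would be entirely zero.

Resolution `r` extents are `ceil(extent_0 / downsample_factor**r)` along X
and Y, and along Z only when `downsample_z` is true. Levels are
independent storage; the store performs no automatic downsampling.

## Cutout REST dialect

```
GET  /v1/capabilities
GET  /v1/resource/{collection}/{experiment}/{channel}
GET  /v1/resource/{name}
POST /v1/resource                      (JSON resource document as above)
GET  /v1/list?prefix={partial/path}
GET  /v1/cutout/{path...}/{res}/{xs}:{xe}/{ys}:{ye}/{zs}:{ze}/
POST /v1/cutout/...                    (payload below)
GET  /v1/cache/stats                   (caching relays only)
```

The `{path...}` segment count (1 or 3) selects the flat or hierarchical
resource form. Cutout payloads — both GET responses and POST bodies — are
the raw little-endian C-order (z, y, x) array, **gzip-compressed**; the
dtype is implied by the resource metadata. Production cloud stores frame
their payloads with blosc; this dialect deliberately uses gzip (stdlib,
no codec negotiation) and documents the difference here.

Status codes: 400 malformed range / bounds / empty range / bad resolution
/ dtype or shape mismatch; 403 capability not offered (e.g. write to a
read-only server); 404 unknown resource or endpoint; 409 create at an
occupied URI.

## Wavefront OBJ (subset)

`write_obj` emits only `v` and `f` records: one `v x y z` line per vertex
(physical units, 6 significant digits) followed by one `f a b c` line per
triangle with 1-based vertex indices. An empty mesh produces an empty
file. `read_obj` accepts exactly this subset (plus `f a/…` forms, index
part only).

## Neuroglancer legacy precomputed mesh fragment

A single-resolution binary fragment:

| offset | size | content |
| ------ | ---- | ------- |
| 0      | 4    | uint32 LE vertex count V |
| 4      | 12·V | float32 LE (x, y, z) triples, nanometers |
| 4+12·V | 12·T | uint32 LE triangle index triples |

Total length is exactly `4 + 12*V + 12*T` bytes. Vertex counts at or
above 2^32 are refused.
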