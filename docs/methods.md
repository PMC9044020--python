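# Methods

## The problem

Connectomics volumes — electron-microscopy image stacks and their
segmentation label fields — are too large to move or hold whole, so the
community stores them in chunked datastores behind 3D *cutout* APIs, each
with its own dialect and feature set. Analysis code written against one
store does not run against another, and capabilities like server-side
mesh generation exist in some ecosystems and not others. voxelkit
standardises *in abstraction* rather than in format: one trait-based API
over interchangeable backends, so the same analysis runs whether the
voxels live in RAM, in a directory of chunk files, or behind an HTTP
service.

## The trait model

Three contracts organise everything:

- **Remote** — a storage backend. Declares a capability set drawn from
  `{read, write, create, list, mesh_server_side}`; `read` is mandatory.
  Three implementations ship: `InMemoryRemote` (dense arrays, the
  reference semantics), `FileChunkRemote` (the on-disk dialect of
  `docs/formats.md`), and `HttpRemote` (client for the REST dialect,
  served by the bundled reference server over any other Remote).
- **Resource** — an addressable data unit: the hierarchical
  collection/experiment/channel form or a flat data-instance. Volume
  resources carry a dtype (`uint8`/`uint16` images, `uint64` annotation
  labels — never silently cast), and a `CoordinateFrame` with voxel
  extents, a resolution pyramid, and physical voxel size.
- **Service** — a computation over Remote data that lists the
  capabilities it requires. `capability_check` is a subset test; any
  Remote passing it can run the Service, and the output depends only on
  the voxels. The bundled `MeshService` delegates to a Remote that
  declares `mesh_server_side` and otherwise runs the local marching-cubes
  surrogate, so server-backed and local meshing share one call site.

Coordinate conventions, fixed once: API ranges are X, Y, Z half-open
0-based intervals; arrays are indexed (z, y, x) so x varies fastest.
Resolution level r halves X and Y extents per level (ceil division), with
Z exempt by default — the anisotropic EM convention where section
thickness is much coarser than in-plane resolution; `downsample_z=True`
switches to an isotropic pyramid. Writes are last-writer-wins; there is
no version history (a data-instance `version` tag is accepted as an
opaque label only).

## Chunk decomposition and the periphery effect

Chunked stores serve fixed cuboids, so a request box touching a chunk
obliges the client to download the whole chunk and crop. `decompose`
splits a request into a deterministic plan (k-major, then j, then i)
whose intersection boxes tile the request exactly; `chunks_touched` is
the closed form `prod_axes(floor((stop-1)/c) - floor(start/c) + 1)` and
always equals the plan length. `periphery_fraction` quantifies the
cropped overhead: (downloaded − requested) / downloaded, with chunks
clipped to the volume extents first, because a chunk truncated by the
volume boundary transfers nothing extra — so extent-clipping is not
periphery. `stitch` reassembles full (zero-padded) chunk arrays into the
request box and is order-independent, which is what licenses parallel
fetching: plan entries may be fetched by any number of workers (default
4) with bit-identical results, asserted in tests with 1 vs 4 workers.

The default chunk shape is (512, 512, 16) voxels in (X, Y, Z), the
common cloud-store cuboid for anisotropic EM; it is configurable per
remote and recorded in each resource's metadata. The test suite uses
(32, 32, 8) so that modest volumes straddle many boundaries.

## The mesh service

Meshing binarizes one label (`voxel == label`) and contours the mask at
iso-level 0.5 with linear interpolation using the classic 256-case
marching-cubes lookup table (scikit-image's `marching_cubes` with
`method="lorensen"`, degenerate faces disallowed; shared vertices are
welded by the extractor, which is what makes edge-incidence topology
checks meaningful). Vertices are interpreted at voxel centers (index +
0.5), scaled by the per-axis physical voxel size at the request's
resolution, and offset by the box origin, so meshes land in global
physical (nanometer) coordinates regardless of which box they came from.

By default the mask is padded with one layer of zeros before contouring,
so an object touching the box face still closes into a watertight
surface; `pad=False` preserves a deliberately clipped, open surface.
Fixtures (balls, tubes, boxes) avoid the classic table's ambiguous
saddle configurations; no asymptotic decider is implemented, a known
limitation for adversarial masks.

`mesh_stats` provides the verification surface: vertex/edge/triangle
counts, Euler characteristic V − E + F, watertightness as an
edge-incidence census (every undirected edge on exactly two triangles),
and enclosed volume as the absolute signed tetrahedron sum
|Σ v₁·(v₂×v₃)|/6, meaningful for watertight meshes. For voxelized balls
of radius r ∈ {5, 10, 20} the meshes are watertight with Euler
characteristic 2 and enclosed volume converging to 4/3·π·r³ as r grows
(the suite asserts < 5% error, decreasing in r). The independent
cross-check in the tests is trimesh, which must agree on watertightness,
Euler number and volume for the same vertex/triangle sets.

Export formats — Wavefront OBJ and the Neuroglancer legacy precomputed
fragment — are specified bit-exactly in `docs/formats.md`. The
precomputed writer emits the single-fragment legacy dialect (no sharding,
no multi-LOD), units nanometers.

## HTTP service and the caching relay

The reference server and HTTP client are built on the Python standard
library (`http.server`, `urllib`): the dialect is small enough that a
framework adds nothing, and it keeps the dependency surface to packages
the scientific stack already carries. Idempotent GETs retry with
exponential backoff (default 3 retries, 50 ms base); POSTs never
auto-retry.

The relay is a Remote wrapping any upstream Remote with an LRU chunk
cache. Cache granularity equals the *upstream's* chunk shape (read from
its metadata), so cache keys align with the server's storage cuboids —
the same alignment argument as the periphery effect, applied to caching.
Per request, cache hits + misses equals `chunks_touched`. Eviction is
least-recently-used with recency refreshed on both reads and writes; a
single chunk larger than the entire capacity is passed through uncached.
Writes through the relay invalidate intersecting cached chunks before
forwarding upstream; writes that bypass the relay are out of contract.
Because the relay serves the same REST dialect it consumes, relays
daisy-chain (client → relay → relay → store) and the chain remains
byte-transparent; an unreachable upstream still serves fully-cached
requests and fails loudly — never partially — otherwise.

## Transfer

`transfer_subvolume` streams a box from one remote into another, block by
block along the *destination's* chunk grid (minimising destination
read-modify-write amplification), with strict dtype equality checked
before the first write. Failed blocks are recorded and the rest proceed,
so a re-run completes an interrupted job and a completed job re-runs to a
no-op (verified by content hashes of destination chunk files).
`verify_transfer` re-reads a seeded deterministic sample of blocks (or
all of them at fraction 1.0) and names any mismatching block.

## Synthetic fixtures

The generators stand in for real EM data so every operation is testable
offline and deterministically: bytes are a pure function of (spec, seed),
with one seeded RNG per call and no global state.

- **Ramp**: voxel(x, y, z) = (x + 10y + 100z) mod 251 — every sub-box is
  recomputable in closed form, making it the ground-truth oracle for all
  cutout, stitching, relay and transfer round-trips. Modulus 251 keeps
  uint8 values below wrap-around.
- **Balls/tubes/boxes**: inside/outside tests place voxel centers at
  integer + 0.5, which keeps voxelized ball volumes unbiased against
  4/3·π·r³ (within 2% for r ≥ 8) and makes mesh volume tolerances
  meaningful; balls require a one-voxel background margin so surfaces
  close.
- **Random labels**: n seeded Voronoi sites, each voxel taking its
  nearest site's label — connected label supports resembling a crude
  segmentation.

What these fixtures do *not* emulate: EM texture and noise, anisotropic
segmentation boundary roughness, label fragmentation, or realistic object
morphology. Passing tests therefore demonstrate the correctness of data
movement, decomposition, caching and meshing machinery — not biological
fidelity of any derived measurement.

## Problem sizes and numerical choices

The suite runs on ~100×90×40-voxel volumes with (32, 32, 8) chunks —
large enough that random requests straddle many chunks in every axis,
small enough that the full randomized matrix (hundreds of requests across
three remote kinds, relays and transfers) completes in seconds. The
acceptance script uses the same scales with 200-step interchangeability
scripts, 1000 random partition cases, and 100-request relay/stitch
checks.

Tolerances: mesh translation equivariance is compared at 1e-4 (float32
export precision dominates); OBJ round-trips at 1e-5 relative (6
significant digits written); ball volume at 5% (discretisation error,
decreasing in r). Everything else — cutouts, stitching, relay responses,
transfers, precomputed round-trips — is compared bit-exactly, which is
the point of the toolkit.

## Known limitations

- No authentication, TLS, or production BossDB/DVID/CloudVolume byte
  protocols; the architecture, not the wire formats, is reproduced, and
  the bundled server is the reference peer.
- No version history or branching on data instances.
- No mesh simplification, smoothing, multi-LOD or skeletonization.
- The relay offers no TTL expiry or prefetching, and no coherence against
  writers that bypass it.
- Marching cubes uses the classic table without an ambiguity decider.
- `InMemoryRemote` allocates dense arrays at creation; it is a test
  double and reference semantics, not a large-volume store.
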