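# voxelkit

Unified, extensible access to large chunked volumetric neuroimagery —
electron-microscopy image stacks and segmentation label volumes — for
connectomics researchers and tool builders.

Large-volume datastores (cloud cutout services, on-disk chunk trees,
plain arrays) all answer the same conceptual question — *give me this 3D
box of voxels* — but through incompatible interfaces, and capabilities
like server-side mesh generation exist in some ecosystems and not
others. voxelkit standardises in abstraction: a trait-based architecture
of **Remotes** (storage backends declaring capability sets), **Resources**
(addressable data units with dtype, channel kind and a physical
coordinate frame) and **Services** (computations that run server-side when
a Remote offers them and as a local surrogate otherwise), so one line of
code decides where the voxels come from and nothing else changes.

The toolkit provides:

- interchangeable Remotes: in-memory, an on-disk chunked-file store
  (documented dialect), and an HTTP client plus bundled reference server
  speaking a cutout REST dialect;
- a chunk-aligned cutout engine: requests decompose into chunk-aligned
  blocks (`chunks_touched = prod_axes(floor((stop-1)/c) - floor(start/c) + 1)`),
  fetch serially or in parallel, and stitch back bit-exactly, with the
  cropped-periphery overhead quantified by `periphery_fraction`;
- a local marching-cubes **MeshService**: per-label isosurfaces at level
  0.5 in physical (nanometer) coordinates, watertightness / Euler /
  enclosed-volume metrics, and OBJ + Neuroglancer legacy precomputed
  writers;
- a daisy-chainable caching **relay**: an HTTP service answering the same
  cutout dialect from an LRU chunk cache, fetching misses from any
  upstream (including another relay);
- remote-to-remote **transfer** with streaming chunk plans, idempotent
  re-runs and seeded verification;
- seeded **synthetic fixtures** (balls, tubes, ramps, Voronoi label
  fields) so every operation is exercisable offline.

## Worked example

Create a chunked-file store, drop a synthetic segmentation into it, and
mesh a neuron-like object — all through the `vk` CLI (a thin layer over
the library):

```sh
cat > voxelkit.toml <<EOF
[remotes.local]
type = "file"
root = "store"
chunk_shape = [64, 64, 16]
EOF

vk fixture ball --shape 64,64,64 --radius 20 --remote local --out bosslike://demo/l1/seg
vk cutout local bosslike://demo/l1/seg --box 0:64,0:64,0:64 --out seg.npy
vk mesh local bosslike://demo/l1/seg --label 1 --box 0:64,0:64,0:64 --out neuron.obj
```

which prints:

```
wrote ball fixture shape=(64, 64, 64) seed=0 -> bosslike://demo/l1/seg
shape=(64, 64, 64) dtype=uint64 -> seg.npy
vertices=7584 triangles=15164 watertight=True enclosed_volume=33510.7
```

The mesh is watertight and its enclosed volume, 33510.7 cubic units,
sits within 0.002% of the continuous ball volume 4/3·π·20³ ≈ 33510.3 —
the discretisation error of marching cubes on a radius-20 voxelized
ball. The same library calls run unchanged against an in-memory remote
or an HTTP endpoint (`vk serve local` starts the reference server;
`vk relay --upstream ...` starts a caching relay in front of it), e.g.:

```python
import voxelkit as vk
remote = vk.HttpRemote("http://127.0.0.1:8680")
block = remote.cutout("bosslike://demo/l1/seg", (0, 64), (0, 64), (0, 64))
mesh = vk.marching_cubes(block, label=1)
print(vk.mesh_stats(mesh))
```

See `docs/methods.md` for the model and its assumptions and
`docs/formats.md` for the bit-exact on-disk and wire formats.

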