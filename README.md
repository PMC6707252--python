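# stereogold

Quantitative analysis of hair-cell stereocilia electron microscopy:

1. **3D immunogold bead density mapping** — given a labeled FIB-SEM volume
   (one integer label per stereocilium) plus gold-bead observations (mask
   volume or centroid table), the pipeline extracts per-cilium surface point
   clouds, estimates each cilium's axis, tip, taper, height and diameter,
   projects bead centroids onto the nearest cilium surface by k-nearest-
   neighbor voting (k = 10, 100-nm discard cutoff), aligns and height-
   normalizes all cilia per staircase row (opening the bundle's V so every
   cilium faces the mechanosensitivity direction), and accumulates bead
   counts into ~200-nm height segments x 4 radial sectors, normalized to
   beads / µm² / cilium.
2. **Membrane coat-staining profilometry** — staining profiles across the
   stereociliary membrane from TEM images (~200 x 200 nm boxes, inner
   leaflet on the midline), background subtraction, 1-nm regridding,
   actin normalization (140–200 nm window), per-group averaging and a
   two-tailed Student's t comparison of coat and membrane window means.

Because no raw volumes are publicly deposited, the package ships a
first-class synthetic phantom generator (`stereogold.synthetic`) producing
bundle volumes and TEM coat images with exact ground truth, used throughout
the test suite for parameter-recovery checks.

## Layout

| module | contents |
| --- | --- |
| `stereogold.io` | TIFF/CSV/JSON readers and writers, `AnnotatedVolume` validation |
| `stereogold.morphometry` | surface extraction (in-plane 1:4 pooling, border voxels, 10% subsample), PCA axis, tip/taper, height/diameter |
| `stereogold.mapping` | bead connected-component centroids, kNN projection with cutoff |
| `stereogold.atlas` | azimuth correction, canonical frame, height normalization, segment/sector binning, density map, representative surface |
| `stereogold.coat` | profile extraction, normalization, averaging, group comparison |
| `stereogold.synthetic` | bundle and coat phantom generators with ground truth |
| `stereogold.pipeline` | `map_bundle`: volume -> density map in one call |

## CLI

```bash
# synthetic data
stereogold simulate bundle --config bundle.yaml --out phantom/ --seed 1
stereogold simulate coat   --config coat.yaml   --out coat_phantom/

# step by step
stereogold morphometry --labels phantom/labels.tif --meta phantom/meta.json --out geometry.csv
stereogold map-beads   --labels phantom/labels.tif --beads phantom/beads.csv \
                       --meta phantom/meta.json --k 10 --cutoff-nm 100 \
                       --out projected.csv --geometry-out geometry.csv
stereogold density     --projected projected.csv --geometry geometry.csv \
                       --meta phantom/meta.json --out density.csv

# or everything at once
stereogold analyze --labels phantom/labels.tif --beads phantom/beads.csv \
                   --meta phantom/meta.json --resize-factor 1 --out analysis/

# coat profiles
stereogold coat --images coat_phantom/ --rois coat_phantom/rois.csv \
                --pixel-size-nm 1.92 --out coat_out/
```

A bundle config YAML may set any `BundlePhantomSpec` field; the bead density
is either a scalar (uniform beads/µm²) or
`{base_rate: ..., top_rate: ..., top_extent_nm: 300}` for tip enrichment.

## Conventions

- All physical coordinates are nanometres in `(z, y, x)` order, 0-based,
  voxel-center convention (voxel `(k, j, i)` at `(k·sz, j·sy, i·sx)` nm).
- The metadata sidecar (JSON) carries `spacing_nm`, `apical_direction`,
  `mechano_direction` (unit vectors, `(z, y, x)`) and the label -> row table.
- Azimuth is measured from the positive mechanosensitivity direction,
  counterclockwise viewed from the tip; sectors are the quadrants at
  ±45°/±135° (anterior faces the tallest row).

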