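# morphoct

Quantification of irregular 3D plant morphology from micro-CT volumes:

* **extraction** — a mask-based pipeline that isolates the binary plant
  body from a scene containing a high-intensity pedestal and tube-case
  artifacts (high-intensity mask → subtraction → binarization → edge/rim
  noise mask → 3D flood-fill component selection → final binarization);
* **hull_descriptors** — iso-surface meshing of the binary body, 3D convex
  hulls, and the two shape descriptors
  *convexity* `C = Ac / A` (hull surface area over object surface area) and
  *solidity* `S = V / Vc` (object volume over hull volume);
* **classify** — two-class linear discriminant analysis in
  (solidity, convexity) space with accuracy, Cohen's kappa, Student's
  t-tests, and reference-group normalization;
* **phantoms** — synthetic thallus bodies (flat and twisted/undulating
  sheets, plus analytic reference solids) and full micro-CT-like scenes
  with known ground truth, so the whole pipeline is testable without
  external data;
* **volume_io** — multi-page TIFF volumes/masks with voxel-spacing
  metadata, and CSV descriptor tables;
* **cli** — a `morphoct` entry point wiring everything together.

## CLI

```sh
# generate a synthetic scene (TIFF stack + ground truth)
morphoct simulate --spec scene.yaml --out-dir scenes/demo

# extract the plant body (auto Otsu-family thresholds by default)
morphoct extract --in scenes/demo/scene.tif --out plant.tif \
    [--config extraction.yaml] [--seed-point z,y,x] [--debug-dir debug/]

# measure descriptors (and optionally export the hull as ASCII PLY)
morphoct measure --in plant.tif --out descriptors.csv --hull-out hull.ply

# LDA on (solidity, convexity); boundary line y = a*x + b, accuracy, kappa
morphoct classify --train train.csv [--test test.csv] --out report.json

# per-descriptor t-tests and normalization against a reference group
morphoct compare --in descriptors.csv --reference WT --out compare.json

# full pipeline on two phantom populations (bundled demo config: 2 x 18
# individuals, simulate -> extract -> measure -> classify, seed 7)
morphoct run-all --out-dir results/demo
```

A scene YAML looks like:

```yaml
plant:
  shape: twisted_slab
  length: 60
  width: 30
  thickness: 5
  twist: 180.0      # degrees about the long axis
noise_sd: 5.0
seed: 1
```

See `src/morphoct/data/demo.yaml` for the `run-all` config schema.

## Conventions worth knowing

* Volumes are indexed `(z, y, x)` with TIFF page order as `z`; spacing is
  isotropic and stored in the TIFF metadata (missing metadata ⇒ spacing
  1.0 and voxel units, with a warning).
* Binary masks are written as 8-bit 0/255; any nonzero voxel reads back
  as foreground.
* `V`/`A` come from a marching-cubes iso-surface (with optional Gaussian
  anti-staircase smoothing, σ=1 by default in `measure`), not voxel-face
  counting; the hull is taken over mesh vertices, which makes `S ≤ 1` a
  theorem rather than a hope.
* `C` is not clamped: flat bodies with in-plane concavities can exceed 1
  (e.g. a plus-pentomino prism, C ≈ 1.075).
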