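# spadfuse

Computational sensor fusion for time-resolved imaging: combine a
**low-spatial-resolution, time-resolved** measurement from a SPAD
(single-photon avalanche diode) array with a **high-spatial-resolution,
time-integrated** image from a conventional CCD/CMOS camera, and
reconstruct a transient data cube with the spatial resolution of the
camera and the temporal resolution of the SPAD.

This matters wherever the full cube *I(x, y, t)* is needed quickly:
flash LIDAR depth imaging, light-in-flight capture, and fluorescence
lifetime imaging microscopy (FLIM) of living cells, where SPAD arrays
offer picosecond timing but only tens-of-pixels spatial resolution and
~1% fill factor.

## The model

The SPAD measurement `d` (an `m x n x τ` photon-count cube) is modeled
per time bin as a linear projection of the unknown high-resolution cube
`i_HR` (`M x N x τ`, with `M = f·m`):

    A = P · S · B,        d = A_τ · i_HR

* `B` — Gaussian defocus blur (the sensor is deliberately out of focus so
  light from every scene point reaches a photosensitive area),
* `S` — the sparse sampling mask of the array's active areas and dead pixels,
* `P` — `f x f` block summation down to the SPAD grid.

The cube is recovered by the convex program

    i_HR = argmin  ‖A_τ i − d‖₂ + α‖T i − c‖₂ + β‖K_h i − K_l d‖₂
                   + γ‖i‖₁ + δ‖∇₂D i‖₁      subject to  i ≥ 0

where `c` is the CCD image, `T` integrates over time, `K_h`/`K_l` are
spatial integrals (the temporal-histogram prior), and `∇₂D` is the
per-frame anisotropic total variation. Published weight presets:
`lidar` (α=1, β=1e-4, γ=1e-2, δ=0) and `flim` (α=1, β=1e-3, γ=1e-7,
δ=1e-5). The solver is a Chambolle–Pock primal–dual method that treats
the unsquared norms exactly, with Morozov discrepancy stopping for
photon-limited data (see `docs/methods.md`).

On top of the reconstruction the package provides depth-map extraction
(per-pixel strongest return), single-exponential fluorescence-lifetime
fitting (bounded tail fit, 1–7 ns), and a synthetic-scene generator
(LIDAR step/slant/letter scenes, FLIM cell scenes) with Poisson noise,
instrument response, low fill factor and dead pixels, so the whole
pipeline is testable end to end without any downloads.

## Worked example

Reconstruct a simulated three-step LIDAR scene (36×36 CCD grid, 12×12
SPAD, 3×3 upsampling, defocus σ = 6 CCD pixels, Poisson noise):

```python
import numpy as np
import spadfuse as sf

spec  = sf.preset_scene("steps")                       # 3 depth plateaus
truth = sf.render_ground_truth(spec)
geom  = sf.FusionGeometry(M=36, N=36, m=12, n=12, blur_sigma=6.0)
d, c  = sf.render_measurements(truth, geom, seed=1)    # SPAD cube + CCD image

res = sf.reconstruct(d, c, geom, sf.WEIGHT_PRESETS["lidar"])
dm  = sf.depth_map(res.cube)
exact = (dm.values == spec.depth)[dm.valid_mask].mean()
print(f"{res.solver_status} after {res.n_iter} iterations")
print(f"depth exact-match: {exact:.1%}")
```

prints

```
discrepancy after 430 iterations
depth exact-match: 96.8%
```

i.e. the solver stopped when the data residual reached the Poisson noise
floor, and the reconstructed per-pixel depth (argmax time bin) agrees
exactly with the ground-truth depth map on 96.8% of the 36×36 pixels —
compared with about 85% for nearest-neighbour upsampling of the raw
12×12 SPAD argmax, which cannot localize the step edges.

The same pipeline is available from the shell:

```sh
spadfuse simulate --preset cells --geometry geom.yaml --seed 1 --out-prefix scene_
spadfuse reconstruct --spad scene_d.tif --ccd scene_c.tif \
    --geometry geom.yaml --weights flim --out ihr.tif
spadfuse lifetime --cube ihr.tif --out tau.tif --report tau.json
```

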