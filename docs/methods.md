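# Methods

## Measurement model

A high-resolution frame reaches the SPAD array through defocus blur
`B`, the photosensitive-area mask `S`, and block summation `P`; the
composite `A = P·S·B` is applied independently to every time bin.

**Blur.** `B` is a separable normalized Gaussian whose standard
deviation is expressed in high-resolution (CCD) pixel widths; the
depth-imaging default is 6. It is built from explicit 1-D operator
matrices (kernel truncated at 4σ, renormalized) so the forward
operator, its adjoint, and the dense-matrix test oracle share one
definition. Boundary handling is half-sample reflection by default: a
symmetric kernel with symmetric extension yields an exactly symmetric
matrix, so `B` is self-adjoint and mass-conserving, and no unmeasured
mass is injected at the field-of-view edge. A zero-padding mode
(`constant`) is available; it loses edge mass and is the main source of
corner artefacts when a synthetic blur is used.

**Mask and sampling.** Each SPAD pixel covers an `f × f` block of the
fine grid but is photosensitive only at the offsets in
`active_offsets` — by default the single central sub-pixel, a
low-fill-factor idealization; `disc_active_offsets` builds a circular
footprint for a given diode-radius/pitch ratio. Dead SPAD pixels zero
their entire block inside `S`: they are simply absent from the
measurement, and the model's zero rows attach no fidelity penalty to
them, which is what lets the reconstruction fill them in from blurred
light in neighbouring pixels. `P` **sums** over blocks rather than
averaging, preserving photon-count semantics (`d` is counts).

## Reconstruction

The objective is the five-term convex program quoted in the README,
with **unsquared** 2-norms (each data term is a second-order-cone
atom). Design choices where the formulation leaves room:

* **Histogram normalization.** Normalizing `K_h i` by the mass of `i`
  itself would make the term nonconvex. Instead `K_h i` is divided by
  the total of the rescaled CCD image (a constant ≈ the expected mass
  of `i`) and `K_l d` by the total of `d`, so both histograms are
  approximately unit mass, β is scale-free, and the term stays linear
  in `i`.
* **Cross-sensor gain.** The CCD and SPAD have unrelated gains and
  exposures. `rescale_ccd` multiplies `c` by the scalar that makes the
  total of `A·c` equal the total counts in `d`; this deterministic
  rescale always precedes the objective.
* **Nonnegativity** is a hard constraint, enforced by the primal
  projection, never a penalty.
* A **squared-L2 variant** of the data terms exists behind
  `squared=True`, clearly labelled as a deviation from the cone form.

### Solver

The default solver is Chambolle–Pock PDHG. Every `w‖K x − b‖₂` term's
dual update is a Euclidean-ball projection of radius `w`; the TV dual
is an ℓ∞ clip at δ; with `i ≥ 0` the ℓ₁ penalty is the linear term
`γ·1ᵀi`, absorbed into the primal prox `max(x − τ(K*y) − τγ, 0)`.
Initialization is the adjoint back-projection `Aᵀd` — deterministic;
no randomness enters the reconstruction. The global step bound comes
from a 30-iteration power iteration on `KᵀK`.

Two numerical choices matter in practice:

* **Step balance.** The duals live on unit-order balls while the
  primal lives on the photon-count scale; balanced steps stall. The
  dual/primal step ratio defaults to `1/‖Aᵀd‖₂`, which equalizes the
  two scales.
* **Stopping.** For photon-count data the residual `‖A_τ i − d‖₂` has
  expected value `sqrt(total counts)` at the true cube (Poisson
  variance = mean). Iterating the program past that floor fits shot
  noise: with the depth-imaging preset's strong sparsity weight
  (γ=1e-2), late iterations visibly reshape per-pixel temporal mass
  that the data terms no longer constrain, and depth accuracy decays
  monotonically (semi-convergence). The solver therefore stops, by
  default, once the data residual has stayed at or below the noise
  floor for a 100-iteration confirmation window (Morozov's discrepancy
  principle), or once the residual stagnates above it (relative
  improvement < 0.2% per 100 iterations). Pass `discrepancy=None` for
  noiseless or pre-denoised data, in which case iteration continues to
  the relative-step tolerance (default 1e-9) or `max_iter`. The
  lifetime-imaging preset's priors are tiny (γ=1e-7, δ=1e-5) and its
  converged optimum is the best estimate, so the pipeline disables the
  discrepancy stop in FLIM mode and solves to convergence.

A second, independent route (`solver="lbfgs"`) minimizes a smoothed
surrogate (`‖r‖ → sqrt(‖r‖² + ε²)`, ε = 1e-6·‖d‖) under bound
constraints with L-BFGS-B. It exists to cross-check the primal–dual
solution; the two routes agree to well under 0.1% in objective on small
instances whose optimum is away from the all-residuals-zero kink (at
that kink the smoothed gradient is degenerate and L-BFGS stalls — one
reason the cone-exact PDHG is the default).

## Analysis

**Depth.** Per-pixel argmax over time bins. Pixels whose total counts
fall below `snr_threshold` (default 0.02) times the maximum per-pixel
total are flagged invalid rather than zero-filled.

**Lifetime.** A single-exponential `a·exp(−t/τ)` is fitted to the tail
of each pixel's histogram, starting at the per-pixel peak bin, which
sidesteps modeling the instrument-response rise. The fit is bounded
nonlinear least squares (trust-region reflective), seeded by a
log-linear regression, with τ clipped to the bound interval (default
1–7 ns). The estimate is scale-invariant and deterministic; decays
with fewer than 3 bins after the peak, or no counts, are invalid.
Plain (unweighted) least squares is used deliberately: reconstructed
cubes truncate the lowest-count late-time bins, and Poisson-weighted
(Neyman) fitting, which up-weights exactly those bins, is biased low
by ~25% on reconstructed data.

**Lifetime distributions.** Summaries report the mean and standard
deviation over valid pixels and a histogram on a fixed 0.1-ns grid
spanning the bounds. Bimodality is quantified by a two-component
Gaussian mixture (deterministic quantile initialization); its component
means are far more stable mode estimates than argmax over histogram
bins when a class has a few hundred pixels.

**Comparisons.** `bin_cube` block-sums a reconstruction down to the
reference resolution and `pixelwise_lifetime_difference` reports the
signed lifetime difference on the joint valid mask, mirroring the
standard low-resolution-versus-reconstruction comparison.

## Synthetic scenes

The generator emulates the two experimental regimes:

* **LIDAR** — a Gaussian temporal pulse per pixel centred at the depth
  bin (σ = `irf_sigma`, default 1 bin, standing in for system jitter;
  the illumination pulse itself is sub-bin), scaled by a reflectivity
  map with deterministic multiplicative texture so the CCD image
  carries the high-frequency structure the fusion is supposed to
  transfer. Presets: `steps` (three plateaus with distinct
  reflectivities), `slant` (linear ramp), `letters` (two foreground
  shapes at distinct depths). Default desk scale: 36×36 grid, 16 bins,
  exposure 2×10⁵ expected signal photons (≈2×10⁴ reach the SPAD through
  the 1/9 fill factor — a realistic photon budget for a sub-second
  exposure).
* **FLIM** — a single-exponential decay per pixel convolved with a
  Gaussian instrument response, scaled by a brightness map. The
  `cells` preset places elliptical cell-like regions of two lifetime
  classes (2 ns and 4 ns) on a dark background (3% brightness) — 48×48
  grid, 75 bins of 160 ps, 4×4 upsampling, exposure 3×10⁶ photons
  (~1.3×10³ per CCD pixel). The synthetic FLIM defocus default is
  σ = 4 (one SPAD pitch), enough to guarantee coverage of the inactive
  area without destroying cell-scale structure.

The CCD path is rendered **without** blur or mask — it has its own
focused optics — with a `share_blur` flag for ablations. Noise is pure
Poisson per voxel; dark counts fold into `ambient_rate`; afterpulsing
and crosstalk are not modeled. SPAD and CCD draws use independent
child streams of one seed; identical seeds give bit-identical scenes.

What the generator does **not** emulate: real optical PSF tails,
multipath returns, detector timing jitter beyond a Gaussian IRF,
afterpulsing, and sensor-specific fixed-pattern noise. Passing the
round-trip tests therefore demonstrates the correctness and
conditioning of the fusion pipeline under its own measurement model,
not performance on any particular hardware.

## Problem sizes and tolerances

The validation study runs at desk scale — 36×36×16 (LIDAR, ~2×10⁴
variables) and 48×48×75 (FLIM, ~1.7×10⁵ variables) — where a full
reconstruction takes seconds to about a minute on one CPU; the same
code path scales to larger cubes with iteration counts as the only
knob. Key tolerances: adjoint identity to 1e-10 relative;
explicit-matrix equivalence to 1e-12 absolute on all grids with
`M·N ≤ 576`; degenerate recovery to 1e-6 relative; depth round trip
≥95% exact match; lifetime class means within 5%; mixture modes within
0.2 ns; fitter median over 200 Poisson realizations within 0.1 ns.

## Known limitations

* The dense-matrix oracle is guarded to `M·N ≤ 10⁴`; beyond that only
  the operator form exists.
* The discrepancy stop assumes Poisson statistics; strongly
  pre-processed (variance-stabilized) data should set an explicit
  residual target or disable it.
* Hot-pixel rejection in `preprocess_spad` is a robust-median rule
  standing in for an unspecified vendor denoising chain; it flags
  bright outliers only.
* Single-exponential fitting only; multi-exponential and phasor
  analyses are out of scope, as is IRF deconvolution.
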