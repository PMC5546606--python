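# Methods

## Model and estimation

`cryogtm` fits a generative topographic mapping to single-particle images
in Fourier space. The latent space is a regular grid of K nodes s_k with
unit spacing and a uniform delta-sum prior p(s) = (1/K) Σ_k δ(s − s_k); each
node corresponds to one 2D class. The mapping into data space is the basis
expansion A(s; W) = Φ(s) W with M_NL Gaussian basis functions
φ_m(s) = exp(−‖s − μ_m‖²/2σ²) plus one constant basis (the bias). An image
is modelled componentwise as t_ij = CTF_ij A_j(s_k; W) + n_ij with Gaussian
noise of precision β_ij and a Gaussian prior on W with precision α.

Estimation is maximum a posteriori by EM:

* E-step: R_ki = softmax_k(−δ_ki/2) with
  δ_ki = Σ_j β̄ (t_ij − CTF_ij A_kj)². The uniform latent prior and the
  likelihood normaliser cancel across nodes once β is pooled, so only the
  exponent is evaluated; computation is in the log domain with per-image
  max subtraction, and responsibilities below 1e−300 are flushed to zero
  before renormalisation.
* W update: for each Fourier component j independently,
  (β̄ Φᵀ diag(Σ_i R_ki CTF_ij²) Φ + α I) w_j = β̄ Φᵀ (R (CTF⊙t))_{:,j}.
  The J solves are batched (chunks of 512) through a dense symmetric solve;
  with α = 0 a singular system falls back to least squares with a warning.
* β update: 1/β_ij = Σ_k R_ki (t_ij − CTF_ij A_kj)², pooled to
  β̄ = N·J / Σ_ij (1/β_ij). The pooled scalar replaces every β_ij in the
  next E-step. A fully per-component β mode exists behind a flag; in
  practice it collapses (components the current model fits perfectly get
  unbounded precision and dominate the posterior), which is the concrete
  reason the pooled mean is the default.
* The monitored loss L = Σ_ijk R_ki (t_ij − CTF_ij A_kj)² equals
  Σ_ij (1/β_ij), so β̄ = N·J/L comes for free each iteration.

Convergence: the run is declared converged at the first iteration where the
relative change of L stays below `tol` (default 0.1 %) for `patience`
(default 6) consecutive iterations. By default the loop stops there; with
`stop_on_convergence=False` it continues to `max_iter` (default 30) with
the convergence iteration still recorded. The benchmark experiments use the
fixed 30-iteration protocol so runs with different seeds are directly
comparable; desk-scale benchmark fits typically converge at iteration
12–15.

Class averages use the Wiener-type expression
A_kj = Σ_i R_ki β̄ CTF_ij t_ij / (Σ_i R_ki β̄ CTF_ij² + α); empty classes
yield near-zero averages and are flagged blank. Hard assignment is the
responsibility argmax with ties resolved to the smallest node index.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| latent shape | user-set, 1–3 dims | K = prod(shape) classes; 1D chain unless stated |
| M_NL | round(0.8 K) | number of Gaussian basis functions; fewer smooths the manifold more |
| σ (basis width) | inter-center spacing | latent units; controls coupling between neighbouring nodes |
| α | 0.01 | weight-prior precision; penalises peaky W |
| β0 | auto = N·J/Σ(t−mean)² | initial pooled noise precision (reciprocal mean component variance) |
| init_radius | 0.25 | initial manifold perturbation, fraction of the RMS data amplitude |
| max_iter / tol / patience | 30 / 0.001 / 6 | EM budget and loss-plateau rule |

The printed closed forms for μ_m and σ in the original algorithm listing
are typographically corrupted; this implementation places the M_NL centers
evenly across the closed latent extent per axis and ties σ to the
inter-center spacing (the largest per-axis spacing in >1D), both
configurable. In >1 dimension the centers are a Cartesian product of
per-axis even spacings with counts proportional to the latent shape,
trimmed from the last axis so the product never exceeds the request.

Initialisation: the constant-basis row of W carries the data mean, so every
mapped point starts at the mean of the stack; the Gaussian rows receive
seeded i.i.d. normal entries scaled so the mapped-point perturbation has
RMS amplitude init_radius × RMS data amplitude. Because adjacent nodes
share basis support, the perturbation is smooth along the grid. Recovery
experiments here, like the published sensitivity analyses, show little
dependence on init_radius or β0 over wide ranges.

## CTF handling

The weak-phase CTF −√(1−A²)·sin χ − A·cos χ with
χ = πλΔz(θ)k² − (π/2)C_sλ³k⁴ + φ_shift is evaluated on the exact Fourier
packing of the data (λ relativistic, Δz astigmatic). Internally defocus is
micrometres with underfocus negative; STAR I/O converts from RELION's
positive-underfocus Ångströms. No envelope decay is modelled and the data
are never phase-flipped — CTF correction lives entirely inside the E-step,
the W update and the Wiener averaging.

## Data space

Images are packed as real vectors: the rfft2 half-plane is reduced to its
Hermitian-unique coefficients, each contributing a real and (unless
self-conjugate) an imaginary component, so J = box² exactly at full
resolution. The packing records per-component multiplicities, giving an
exact Parseval identity used as a test invariant. An optional resolution
cutoff truncates the packing for speed.

In-plane alignment (supplied externally or by simulator ground truth)
applies rotation by −θ about the geometric box centre followed by
translation by (−r_x, −r_y), bilinear interpolation, out-of-field samples
set to the image mean. Optional per-image normalization subtracts the mean
and divides by the background (r > 0.45·box) standard deviation; it is off
by default in the library but used in the benchmark experiments, matching
standard single-particle preprocessing, so that the fixed α = 0.01 operates
on a consistent data scale.

## Synthetic benchmark

The simulator emulates the structure of a projection benchmark:

* Phantom: 8 Gaussian blobs placed uniformly in a sphere of radius
  0.4 × box, amplitudes 0.5–1.5, widths 3–6 % of the box, seeded —
  asymmetric by construction. Any external volume can be substituted;
  `stretch_phantom` builds a length-variant for demixing experiments.
* Orientations: centres quasi-uniform on the upper hemisphere (Fibonacci
  spiral); per centre, views whose angular distance to the centre is
  Rayleigh with standard deviation `spread_deg` (default 2°, a value the
  source protocol leaves unstated) and uniform azimuth; in-plane angle
  uniform in [0°, 360°).
* Projection: trilinear volume rotation and summation along the ray axis.
* Corruption: Fourier phase-ramp shift (uniform within ±2 px per axis),
  CTF multiplication (defocus uniform in −1.0 to −3.5 μm, 300 kV, C_s
  2.0 mm, amplitude contrast 0.1), then white Gaussian noise of variance
  var(post-CTF signal)/SNR. The SNR convention (post-CTF signal variance)
  is configurable to pre-CTF.
* Ground truth records centre ids, views, ψ, shifts and defocus, plus the
  exact (θ, r_x, r_y) triple that `apply_alignment` must apply to undo the
  simulated pose.

What the simulator does *not* emulate: structured/non-white noise, ice
gradients and amplitude-decay envelopes, alignment errors (ground-truth
alignment is exact up to interpolation), particle-picking contamination,
and a realistic macromolecular density. Passing recovery tests therefore
demonstrate correctness and noise robustness of the estimator, not
end-to-end performance on experimental micrographs.

## Benchmark problem sizes and observed behaviour

Desk-scale experiments use 20 orientation centres × 100 projections at
box 48 (J = 2304) with K = 20, and 2 × 150 images for the hierarchical
demixing test — sizes chosen so the full suite and the acceptance script
each run in well under a minute of compute per experiment while keeping
100 images per class, the per-class density of the full-scale protocol.

At these conditions the fitted model converges (rule triggers at iteration
12–15 of 30), populates all 20 classes, and pools within-class angular
distances to ≈ 0.32 of the random-assignment mean. Majority-vote purity is
0.66–0.76 across seeds. The purity ceiling is a genuine property of
exact-K topographic clustering on well-separated view clusters: the EM
fixed points can hold one node across two distant view-islands while a
pair of nodes splits another island, and no local move escapes. The data
themselves are fully separable (assigning images to their nearest
ground-truth class centroid scores > 99 %), and k-means with k-means++
restarts scores only ≈ 0.52 on the same images, so the mapping
substantially outperforms centroid clustering under noise, consistent with
the approach's motivation. At full scale (hundreds of centres a few
degrees apart) the view manifold is quasi-continuous and this island
pathology does not arise. Hierarchical demixing of two length-variants
(SNR 1/20) separates at sub-level purity ≈ 1.0.

## Numerical choices and degenerate inputs

* Responsibility exponents are max-subtracted per image; a uniform column
  results when all mapped points coincide.
* Zero total residual (perfect fit) caps β̄ at 1e30 with a warning instead
  of dividing by zero.
* Blank classes (responsibility mass < 1e−8) produce zero averages and are
  flagged; at α = 0 their 0/0 average is defined as 0.
* An all-zero stack, non-finite residuals, inconsistent counts and invalid
  configurations raise structured errors naming the offending quantity.
* All randomness flows from explicit integer seeds; hierarchical sub-runs
  derive child seeds from (master seed, class id) so parallel sub-runs are
  independent yet reproducible.

## Known limitations

* No orientation or shift search inside the E-step: alignment must be
  supplied (by an external aligner or simulator ground truth).
* The pooled-β̄ replacement makes the iteration a generalised EM on a
  surrogate; the loss is monitored rather than guaranteed monotone
  (exact-EM monotonicity holds in the frozen per-component-β regime and is
  tested there).
* Exact-K clustering of widely separated view clusters can merge/split
  islands (see above); increasing K beyond the expected cluster count, or
  hierarchical re-clustering, is the practical remedy.
* Bilinear interpolation in alignment and projection attenuates the
  highest frequencies slightly; acceptable for classification, not for
  high-resolution reconstruction.
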