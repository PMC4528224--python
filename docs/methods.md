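# Methods

## Outline model

A wing silhouette is modelled as a single, simply connected dark region on a
light background (either polarity is accepted; the object class is detected
as the Otsu class in the minority along the image border, since the
background surrounds the object). Its boundary is an 8-connected closed
pixel path, encoded as a Freeman chain: codes 0–7 at angles `k·π/4`
counterclockwise from +x, with step lengths `Δt = 1` (even codes) or `√2`
(odd codes). Image `(row, col)` pixels are mapped once to mathematical
coordinates `x = col`, `y = (height − 1) − row`; all downstream mathematics
is y-up. Traversal is canonicalized counterclockwise starting at the
topmost-then-leftmost boundary pixel; the starting choice is arbitrary
because descriptor normalization removes it, but fixing it makes every stage
bit-reproducible.

The closed curve `(x(t), y(t))`, parameterized by arc length `t` over one
period `T`, is expanded in elliptic Fourier harmonics `(a_n, b_n, c_n,
d_n)`. Because the chain is piecewise linear, every Fourier integral has a
closed form per segment; we evaluate those sums exactly (vectorized over
harmonics and segments) rather than resampling and using an FFT, so the
coefficients carry no resampling error. The DC terms `(A0, C0)` are the
exact centroid of the piecewise-linear curve.

### Normalization

Kuhl–Giardina normalization applies (i) a parameter-origin rotation to where
the first-harmonic ellipse crosses its semi-major axis, (ii) a spatial
rotation by the semi-major axis angle, (iii) division by the semi-major
magnitude, and drops the DC terms. Afterwards `a1 = 1, b1 = 0, c1 = 0`
exactly (the zeroing of `b1`/`c1` follows from the orthogonality of the
position and velocity vectors at a radius extremum; the three values are
then set exactly to remove ~1e−16 float residue). Two deliberate choices:

* **Axis-end ambiguity.** Starting at the opposite end of the major axis
  negates every even harmonic and nothing else. We pick the variant in
  which the first even-harmonic coefficient of appreciable magnitude
  (>1e−7 of the largest coefficient, scanned in `(a, b, c, d)` order from
  harmonic 2) is positive. This is deterministic and invariant to the input
  trace start, which is what makes the ≤1e−6 starting-point invariance hold.
  For shapes whose even harmonics are all negligible, the two variants
  coincide within tolerance anyway.
* **Reflection is not removed.** Mirror-imaged outlines (e.g. left vs right
  wings) keep distinct descriptors; callers should digitize one side or
  mirror images beforehand.

A consequence worth knowing: descriptors depend on the *parameterization*,
not just the point set. A 2:1 ellipse traced at uniform speed has a
first-harmonic axis ratio of ≈0.587, not 0.5, because arc-length tracing is
not the elliptic-angle parameterization. All pipeline descriptors use arc
length consistently, so this is invisible in practice, but any external
ground truth must be computed in the same parameterization (see the
synthetic generator below).

### Harmonic-selection diagnostics

Per harmonic we report the rotation-invariant magnitude
`CE_i = sqrt((a_i² + c_i²)/2) + sqrt((b_i² + d_i²)/2)` (default; the
harmonic power `(a_i² + b_i² + c_i² + d_i²)/2` is available via
`ce_formula=power` — both flatten identically in practice) and the
variation of the cumulative CE between consecutive harmonic counts. The
reconstruction error `ε_n` is the mean Euclidean distance between the `K`
original outline points and the truncated series evaluated **at the same
arc-length parameters** `t_k`; this makes `ε_n` a matched point-pair
statistic, non-increasing in `n` up to discretization jitter and exactly
zero at the band limit of a band-limited curve. The shipped default of 30
harmonics (config key `n_harmonics`, file `config.txt`) sits well past the
flattening knee of every shipped fixture while keeping the feature vector at
`4·30 − 3 = 117` values (the constants `a1, b1, c1` are dropped; flattening
order is `a2..aN, b2..bN, c2..cN, d1..dN`).

## Image preprocessing defaults

The cleaning chain is: remove 8-connected components below 0.1% of the image
area; one erosion followed by one dilation with a 3×3 square (a single
morphological opening, hence idempotent as a chain); fill interior holes;
keep the largest component (ties broken by raster-scan order, with a logged
warning). Structuring element, speckle threshold and the choice of Otsu
thresholding are declared defaults, all overridable in code: they suit
high-contrast silhouettes and are not claimed optimal for textured or
low-contrast photographs. A component touching the image border is rejected
rather than silently clipped.

## Classifier

Features are standardized by training-set mean/scale (persisted inside the
model), then fed to a one-vs-one C-SVC with RBF kernel. `(C, γ)` come from
a real-coded GA over `log2 C ∈ [−5, 15]`, `log2 γ ∈ [−15, 3]`: population
20, 30 generations, tournament size 3, arithmetic crossover 0.8, Gaussian
mutation 0.1 (sd = 10% of box width), elitism 1. Fitness is stratified
5-fold CV accuracy on the training split, with folds fixed per run so all
genomes are scored on identical splits. The initial population always
contains the conventional default `(C=1, γ=1/n_features)`, so the GA result
can never score below that baseline. All GA settings are config keys; the
defaults trade a thorough search against a few seconds per run at these
sample sizes.

Validation repeats, per run: fresh stratified 1:1 split (odd class counts
send the extra specimen to training), GA, fit, test. Reported are per-run
CV and test accuracy with their means, per-species accuracy pooled over
runs, and the misidentification matrix `P_e(A→B) = 100 · ΣE_AB / S_A` with
`E` summed over runs. The divisor `S_A` is the total number of A specimens
tested across runs — the only reading under which per-species accuracy plus
misidentification rates partition exactly 100%; a whole-sample divisor is
available via `misid_denominator=global`. The full per-specimen prediction
log is retained so every aggregate can be recomputed independently.

Hierarchical mode takes a user-supplied species→group map (standing in for a
character judged by eye, such as a compound-eye feature) and trains one
independent model per group; at prediction time the caller supplies the
specimen's group. Cross-group misidentification is zero by construction —
the rescue mechanism for species whose outlines overlap. A single-species
group degenerates to a constant assigner and is flagged in the log.

PCA of the feature table is centered but not re-scaled (the descriptors are
already dimensionless and on comparable scales after normalization); the
first-two-component scatter is the overlap diagnostic.

## Synthetic families

Each synthetic species is a prototype coefficient set (band-limited at ≤8
harmonics, verified numerically to be a simple closed curve via Shapely at
generation time) plus per-specimen variation: every coefficient is perturbed
multiplicatively, `c · (1 + ε)` with `ε ~ N(0, coeff_noise_sd)` — so noise
is relative to each coefficient's magnitude and structural zeros stay zero —
then the outline is rotated and scaled uniformly within configured windows.
Defaults: 16 specimens per family (within the 12–25 range typical of museum
series), noise sd 0.04, free rotation, scale 0.8–1.25. Five prototypes ship:
`broad`, `slender`, `falcate`, `notched` are mutually well separated;
`notched_ii` deviates from `notched` by about one noise-sd on six low-order
coefficients, a deliberately overlapping pair. `default_family_specs()`
returns two separated plus the overlapping pair; `separable_family_specs()`
four separated families.

Because generation coefficients live in a non-arc-length parameter, the
recoverable ground truth of a specimen is defined as the arc-length EFD of
its exact generating curve, computed from a 4096-point sampling
(`ground_truth_efd`) — far denser than any raster the pipeline sees. The
render → extract → digitize round trip recovers these values to ≤0.02 per
normalized coefficient at a 512 px canvas (measured ≤0.012 across all
shipped prototypes; the bound corresponds to ~4 px of boundary
discretization on a ~210 px semi-major axis).

What the generator does **not** emulate: venation, texture, lighting
gradients, shadows, damaged or hairy margins, and perspective distortion.
Passing tests therefore demonstrate the correctness of the digitization and
classification machinery and the claimed invariances — not robustness to
photographic artefacts, which real deployments must assess on real images.

## Determinism and numerical choices

Every stochastic stage (family generation, splits, CV folds, GA) consumes a
`numpy` Generator seeded from explicit integers; per-run seeds derive from
the master seed via `SeedSequence.spawn`. Identical seeds give
bitwise-identical outlines, splits, models and reports. Degenerate inputs
fail loudly: uniform images, empty foregrounds, border-touching components,
outlines shorter than 8 px, branching pixel paths, first-harmonic magnitude
below 1e−12, and single-specimen classes all raise typed exceptions naming
the offender. Problem sizes used by the test suite (families of 10–16
specimens, canvases of 128–512 px, GA budgets from 6×3 to the full 20×30)
were chosen so the whole suite exercises the full default configuration at
least once while individual unit tests stay small.

## Known limitations

* Outline-only features: species separated by colour, venation or size
  (size is normalized away by design) are invisible to the classifier.
* One object per image; no automatic wing detachment from whole-specimen
  photographs, and no repair of cracked outlines.
* Reflection sensitivity (see above).
* The misidentification divisor follows the per-species reading; rates
  computed under the global reading differ by a constant factor per row.
* GA optimality is stochastic; with elitism and the seeded default genome it
  is guaranteed no worse than the standard default parameters, not globally
  optimal.
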