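# Methods

`helixtrace` locates helical assemblies (filaments) in electron
cryo-micrographs by tile-based reference correlation, extracts per-helix
trace coordinates, quantifies ensemble flexibility through the
persistence length, and scores tracing results against ground truth.
This note records the model, the parameters that matter, the numerical
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Tracing model

Within a window of 350–500 Å a helix is well approximated by a straight
line, so its position in a tile is fully described by the in-plane angle
θ of the helix axis and the signed offset Δ of the axis from the tile
centre along the normal. The micrograph is normalized, binned
(block averaging), high-pass filtered and cleaned of extreme dark pixels,
then cut into overlapping tiles (80 % overlap ⇒ effective steps of
70–100 Å, comparable to the half-width of typical specimens). Each tile
is mean-subtracted and multiplied by a circular Gaussian mask of
σ = 1.41 × step to improve separation of closely packed helices.

The (θ, Δ) search is factorized. Because helical specimens show layer
lines and the power spectrum is invariant to translation, θ is found by
rotationally correlating the tile's power spectrum against the
reference's; Δ and a normalized cc-score then come from a single
real-space cross-correlation of the tile rotated by −θ against the
vertical reference, of which only the component normal to the axis is
kept.

Angle convention: θ ∈ [0°, 180°), axis direction (sin θ, cos θ) in
(x = column, y = row); θ and θ + 180° are indistinguishable because
power spectra of real images are Friedel-symmetric.

### Numerical choices in the angle search

* Angular sampling 1° by default; ties go to the smaller angle.
* Rotation of the (log-compressed) power spectrum uses bilinear
  interpolation **about the zero-frequency pixel**. After `fftshift`
  the DC of an even-sized spectrum sits at (n/2, n/2), half a pixel off
  the geometric array centre; rotating about the wrong point translates
  the whole spectrum at large angles and produced systematic ~10° errors
  near θ ≈ 180° before the fix.
* The correlation annulus excludes a 2-pixel low-frequency disc (no
  orientation information) and everything beyond radius n/2 − 1, so the
  ring never samples the padding for any rotation angle.
* The reference stack and tile spectra receive the same 1-px Gaussian
  blur. Without it the unrotated stack entry is systematically sharper
  than its interpolated neighbours, which biases noise tiles toward
  0°/90°.
* The spectrum estimate is coarse (±2–3° at 50-px tiles), so the final
  angle is polished by evaluating the real-space cross-correlation at
  ±3 steps around it and keeping the best score. This makes the
  factorized search land on the same optimum as an exhaustive joint
  (θ, x, y) search (verified against a brute-force oracle) at a small
  constant cost.
* The Δ peak is taken at integer precision; among equal maxima the
  smallest |Δ| wins. A zero-variance tile scores (Δ, cc) = (0, 0).

## Correlation map, null model, thresholding

Each tile draws a line of its cc-intensity into a micrograph-shaped map:
direction θ, centre displaced Δ along the normal, amplitude = cc-score,
with a Gaussian falloff of σ = 2 × tile step **along** the line from the
adjusted centre (so helix ends fade rather than overshoot) and a sharp
transverse profile (σ = 2 px). Contributions add: tiles that agree on a
path reinforce into a continuous ridge, incoherent noise tiles do not.
An early variant applied the 2-step σ transversely as well; the summed
halos of overlapping tiles then raised the background median to the same
order as the ridge and thresholding removed everything, so the narrow
transverse profile is load-bearing.

Helix-free map values follow an exponential distribution. Its scale λ
is estimated robustly as median/ln 2 (the median of an exponential of
scale λ is λ ln 2); the median tolerates the minority of high ridge
values. A pixel is kept when its upper-tail p-value exp(−x/λ) is below
the user significance α, i.e. x > λ ln(1/α). On pure exponential noise
the above-threshold fraction equals α by construction (calibration
verified to binomial tolerance at 10⁶ pixels).

## Skeleton, branch points, traces

The binary map is thinned to a one-pixel, 8-connectivity-preserving
skeleton (`skimage.morphology.thin`, the same lookup-table family as the
classic bwmorph port). Crossing helices meet at branch points:
skeleton pixels whose 3×3 neighbourhood has ≥ 3 emanating branches
(maximal runs of cyclically consecutive set ring neighbours) and ≤ 4 set
neighbours (5+ cannot survive thinning). Detection convolves the
skeleton with a 3×3 kernel of powers of two — every pixel receives a
unique code in [0, 511] — and looks the code up in the precomputed
branch set; this equals per-pixel run counting exactly.

Enumerating all 256 centre-set neighbourhoods, the three-branch junction
patterns reduce to exactly **seven** classes under the four 90°
rotations and mirrors; the detection set additionally contains the two
perfectly symmetric four-branch crossings ('+' and 'X'), each invariant
under every rotation and mirror. A disc of radius helix-width is erased
around each branch point, splitting crossing helices; traces are not
re-linked across the erased region. Residual junction pixels (rare, at
erased-disc rims) are removed before path extraction so every component
is an open chain; the extra fragments fall to the minimum-length filter.
Closed loops are cut at their smallest pixel and flagged.

Components are ordered endpoint-to-endpoint, converted to Å, filtered by
a minimum length (removes contamination) and split into near-equal
pieces no longer than the maximum length. Each path is rotated into its
principal-axis frame (so the fit is single-valued even for vertical
traces), fitted with a polynomial — order 1 below 500 Å, 2 for
500–2000 Å, 3 above, user-overridable — and resampled at equal
arc-length steps (default 70 Å, the lower end of typical tile steps);
the final point is the curve end, so the last interval may be shorter.
Fitting in the rotated frame approximates a tilted parabola to a few Å
(sub-pixel), which is the accuracy the tests assert.

## Flexibility

Two estimators are exposed side by side:

* **Per-trace**, from end-to-end distance R and contour length L:
  λ = −ln(2 (R/L)² − 1)/L and p = 1/λ. R = L gives the rigid sentinel
  p = ∞. For R/L ≤ 1/√2 the logarithm leaves its domain; such traces
  are flagged "maximally flexible" (p = 0 sentinel) instead of raising
  mid-pipeline, and are always pruned.
* **Ensemble**, from tangent correlations: unit tangents of the
  equidistant segment coordinates, mean dot product per contour
  separation, fitted by exp(−s/p). When all correlations are positive
  the fit is the weighted no-intercept regression of ln⟨cos⟩ on s
  (weights = pair counts, separations with < 10 pairs dropped);
  otherwise a nonlinear least-squares fit. Ensembles without measurable
  decay return the rigid sentinel.

The worm-like-chain simulator is constructed to be the exact inverse of
the ensemble estimator: planar chains whose successive tangent angles
receive i.i.d. normal increments of variance 2 × segment/p, giving
⟨t(u)·t(u+s)⟩ = exp(−s/p) exactly in expectation. A 2-D/3-D convention
is thereby fixed operationally: p *is* the decay length of the planar
tangent correlation. With 1000 chains of 3000 Å at 20 Å segments the
fit recovers generating values of 1.27, 33.9 and 325 µm (the
flexible-to-rigid range of real specimens) to within a few percent; the
stiff case is the noisiest because the total decay over 3000 Å is below
10⁻³.

Population pruning models ln p as normal with location = median and
scale = 1.4826 × MAD (the normal-consistency constant; the histograms
are log-normal) and discards traces more than n_sigma (default 2)
scales below the location, plus all maximally-flexible-flagged ones.
Pruning needs ≥ 5 defined values, else it is skipped with a warning.

## Evaluation

Result and ground-truth trace sets are rasterized onto 25 Å binary
grids. Precision is the fraction of result cells inside the truth grid
inflated by one helix width; recall is the fraction of truth cells
inside the inflated result grid; F1 is their harmonic mean (empty
result ⇒ P = R = F1 = 0 by convention, the ratio being 0/0). A 400 Å
boundary margin and discs of one helix width (= two helix radii) around
every endpoint of either set are excluded from both grids, removing
boundary effects and end-definition ambiguity. Grid cells are half-open
squares; polylines are sampled at quarter-cell steps.

The optimizer grid-searches the α-threshold (decade steps by default)
and minimum helix length (100 Å steps up to the tile size) for maximal
pooled F1, re-running only the cheap extraction stages on stored
correlation maps. Ties prefer larger α, then smaller minimum length.

## Synthetic scenes: what they emulate and what they do not

`generate_synthetic_scene` renders worm-like-chain centrelines as
soft-edged ribbons (transverse Gaussian, σ = width/4) with a sinusoidal
axial modulation of the given repeat — the periodicity that produces
layer lines — plus additive Gaussian white noise scaled so that
(signal-layer variance)/(noise variance) equals the requested SNR over
the whole image. Truth centrelines are returned alongside; everything
is reproducible bit-exactly from the parameters and seed.

The scenes emulate the geometry and statistics the tracer relies on:
elongated modulated densities, curvature at a controllable persistence
length, crossings, low SNR. They do **not** emulate CTF oscillations,
structured background (carbon, ice gradients, ethane blobs), radiation
damage, or the non-white noise of real detectors. Passing benchmarks
therefore demonstrate the correctness and calibration of the algorithm,
not picking performance on any particular real dataset.

Benchmark conditions (chosen once): 20 images of 4000 × 4000 Å at
4 Å/px, 10 filaments each of 1300 Å contour at ParM-like stiffness
(33.9 µm), width 100 Å, axial repeat 50 Å, SNR 0.1; tracing at tile
400 Å, 80 % overlap, 2× binning. With grid-search-optimized α and
minimum length the pooled F1 exceeds 0.9; at α = 0.001, ≥ 95 % of
pure-noise micrographs yield zero traces (a single noise tile can draw
at most one tile-length line, which the minimum-length filter removes).

## Degenerate inputs and edge cases

* Constant image: normalization defines SD = 1 (output all zeros);
  outlier suppression returns the input (MAD = 0).
* Binning drops remainder rows/columns; the last tile of each row and
  column is clamped to end on the image edge, so edge helices stay
  traceable.
* MRC I/O is a minimal MRC2014 subset (modes 0/1/2/6, single 2-D
  images); stacks are rejected. gemmi serves as an independent reader
  oracle in the tests.
* All randomness flows through explicit integer seeds; repeated runs on
  identical inputs are bit-identical.

## Known limitations

* Single reference; no multi-reference matching or polymorph
  classification (distinct assemblies are rejected implicitly by low
  cc-scores).
* Δ is integer-precision; no sub-pixel refinement.
* Split traces are not re-linked across erased branch regions.
* The per-trace and ensemble persistence estimators can differ by a
  model-dependent constant on real data; pruning uses only relative
  values and is unaffected.
* The evaluation margin (400 Å) makes micrographs smaller than
  ~1 × 1 µm mostly margin; synthetic benchmarks place filaments in the
  interior.
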