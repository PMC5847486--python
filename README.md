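# helixtrace

Automated tracing of helical assemblies — filaments, tubes, viruses —
in electron cryo-micrographs, with built-in flexibility analysis and a
picker-evaluation harness.

Helical specimens (e.g. TMV, ParM, p62-PB1 filaments) are long,
continuous objects: their location in a micrograph reduces to a trace
of equidistant segment coordinates. Interactive tracing of the
thousands of micrographs of a modern dataset is the bottleneck this
tool removes, and the trace coordinates it produces feed directly into
helical reconstruction workflows (EMAN box files, RELION-readable
coordinates). Along the way it measures the persistence length of the
polymer ensemble — a direct readout of the mechanical stiffness of the
assembly and of its prospects for high-resolution reconstruction.

## Method

The micrograph is normalized, binned, high-pass filtered (half-maximum
at 4 % of Nyquist), cleaned of extreme dark pixels (median/MAD model),
and cut into overlapping tiles of 350–500 Å in which a helix is locally
straight. For each tile the in-plane axis angle θ comes from a
rotational correlation of power spectra (layer lines make the spectrum
orientation-sensitive; its translation invariance removes the shift
search), and the normal offset Δ plus a normalized cc-score come from a
single real-space cross-correlation against a vertical reference helix.

Per-tile results are accumulated into a continuous correlation map:
each tile draws a line of its cc-intensity at (θ, Δ) with a Gaussian
longitudinal falloff of σ = 2 × tile step. Background map values
follow an exponential law f_λ(x) with λ estimated robustly as
median/ln 2; pixels with upper-tail p-value below a user significance α
are kept. The binary map is thinned to a one-pixel skeleton, crossing
helices are split at branch points (found by a 3×3 powers-of-two
convolution response against a precomputed template set), and the
resulting paths are length-filtered, polynomial-fitted and resampled to
equidistant coordinates.

Per trace, the flexibility λ = −ln(2 (R/L)² − 1)/L (end-to-end distance
R, contour length L) gives the persistence length p = 1/λ; the
log-normal population of p is pruned of kinked outliers
(median/MAD on ln p, default 2 σ). Ensemble stiffness is measured
independently by fitting exp(−s/p) to tangent–tangent correlations, and
a worm-like-chain simulator with exactly that decay law provides
parameter-recovery validation. Tracing quality is scored against
ground truth on 25 Å binary grids: precision P, recall R, F1 = 2PR/(P+R),
with a grid search over α and minimum helix length for maximal F1.

See `docs/methods.md` for the full model, parameter defaults and
numerical choices.

## Worked example

Everything below runs from scratch in about a minute; no external data
is needed. Generate a synthetic micrograph set with known ground
truth, trace it, and score the result:

```bash
helixtrace synthesize --n-images 1 --n-filaments 8 --snr 0.1 \
    --image-size 4000 --pixel-size 4 --seed 11 --out-dir demo
helixtrace trace 'demo/scene_000.mrc' --reference demo/reference.mrc \
    --tile-size 400 --binning 2 --helix-width 100 \
    --min-length 600 --max-length 1500 --alpha 1e-5 --segments \
    --out-dir demo
helixtrace evaluate demo/scene_000.box demo/scene_000_truth.box \
    --pixel-size 4 --helix-width 100 --extent 4000 4000
```

which prints

```
demo/scene_000.mrc (8 filaments, snr=0.1)
demo/scene_000.mrc: 12 traces -> demo/scene_000.box
precision=0.9583 recall=0.7626 f1=0.8493
```

Eight worm-like filaments were rendered at a signal-to-noise ratio of
0.1; the tracer reports 12 traces (crossing filaments are split at
branch points), of which 96 % of the traced area lies on true
filaments and 76 % of the true filament area is recovered — on a
single image with default-ish parameters. Pooled over 20 images with
the `optimize` subcommand choosing α and the minimum length, F1
exceeds 0.9 (this is one of the acceptance checks below).

Ensemble flexibility from a simulated bundle:

```bash
helixtrace simulate --persistence 339000 --n-chains 1000 \
    --contour 3000 --segment 20 --seed 1
```

```
generating p = 339000 A; recovered p = 352393 A (35.24 um)
```

i.e. the tangent-correlation fit recovers a 33.9 µm persistence length
(a ParM-like stiffness) to within 4 % from 1000 chains of 3000 Å.

The same functionality is available as a library:

```python
from helixtrace import (TracingParams, generate_synthetic_scene,
                        render_reference, trace_micrograph, evaluate)

scene = generate_synthetic_scene(8, 33.9e4, 100.0, 50.0, 0.1,
                                 4000.0, 4.0, seed=11)
ref = render_reference(100.0, 50.0, 50, 8.0)
params = TracingParams(tile_size_A=400, binning_factor=2,
                       helix_width_A=100, min_helix_len_A=600,
                       max_helix_len_A=1500, alpha=1e-5)
traces = trace_micrograph(scene.rendered, ref, params)
result = evaluate(traces.traces, scene.truth_traces, 100.0, (4000.0, 4000.0))
```

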