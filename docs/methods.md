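# Methods

This note documents the models, conventions and numerical choices behind
`fuzzedge`, in the order data flows through the package.

## Image handling

All processing operates on `GrayImage`: a 2-D float grid with an explicit
declared value range (1.0, 255 or 65535) so 8-bit, 16-bit and normalized
data coexist without silent rescaling. Coordinates are row-major and
0-based with (0, 0) at the top-left. Color input is reduced with the
ITU-R BT.601 luma weights 0.2989 R + 0.5870 G + 0.1140 B (the MATLAB
`rgb2gray` convention), rounded to the nearest integer for integer ranges.
Non-square images are zero-padded to a square with the original anchored at
the top-left — padding on the right/bottom only is a convention chosen for
determinism; nothing downstream depends on where the black pixels sit.
Resizing is bilinear with anti-aliasing when downsampling. Membership maps
are written to disk as 8-bit with round-half-away-from-zero, so μ = 0.5
becomes pixel 128. JPG output is supported but warned against (lossy).

## Synthetic phantoms

The phantom module generates square images whose edges and region labels
are known analytically, standing in for clinical MRI slices:

* **step** — a vertical intensity step; the truth is the two step-adjacent
  columns;
* **disk** — a filled disk; the truth is every pixel within distance 1 of
  the ideal circle;
* **tissue** — nested concentric ellipses (semi-axes 0.49·side and
  0.46·side) whose annuli split the ellipse into equal areas, so the 2–6
  intensity regions have comparable pixel populations; this mimics nested
  tissue compartments (edema around a tumor core) while keeping clustering
  well-posed.

Noise is additive Gaussian, clipped to [0, 255], with a per-phantom seed;
default noise levels in tests are σ = 5 (clustering) and σ = 8–10 (edge
robustness). The phantoms are piecewise constant: they exercise edge
localization, linking and intensity clustering, but deliberately omit MRI
physics (bias fields, Rician noise, partial-volume ramps). Passing tests
therefore demonstrate correctness of the algorithms, not clinical
performance on real scans.

## Classical edge detection

Gradient operators use the standard Prewitt/Sobel 3×3 and Roberts 2×2
kernel pairs with replicate-edge padding (avoiding spurious border
responses). The automatic binarization threshold is 4 × mean gradient
magnitude, mirroring the familiar MATLAB `edge` heuristic. Canny is
implemented explicitly — Gaussian smoothing (default σ = √2), Sobel
gradient, non-maximum suppression along the 4-way quantized gradient
direction, and hysteresis keeping weak pixels (≥ low) only in 8-connected
components that contain a strong pixel (≥ high). Automatic thresholds:
high = the 70th percentile of nonzero suppressed magnitudes,
low = 0.4 · high (the common default ratio). A final morphological
thinning pass guarantees 1-pixel-wide output (quantized suppression alone
can leave 2×2 corner blocks). The enhancement filters use the 4-neighbor
Laplacian kernel [[0,1,0],[1,−4,1],[0,1,0]], sharpen strength k = 1, and
σ = 1.0 for the smoothed Sobel gradient; response-type filters are rescaled
to the image's value range.

## Ant colony edge extraction

The colony walks the pixel grid: each of n ants (default ⌊√(m·n)⌋ — the
side length for square images, the convention of the classical ACO
edge-detection literature) takes one step per iteration to an 8-neighbor
sampled with probability ∝ τ^α · η^β. Defaults: 4 stages × 1536
iterations, τ₀ = 10⁻⁴, (α, β) = (1, 0.01), local evaporation ρ_l = 0.1,
global decay ρ_g = 0.001; the stopping criterion is exhausting the
iteration budget. The heuristic η is the maximum absolute intensity
difference over the four symmetric 8-neighborhood pixel pairs, normalized
by its global maximum — invariant to intensity offsets, and identically
zero on flat images (in which case the run short-circuits with a
"flat image" diagnostic and a uniform τ₀ field).

Four kernels reshape the normalized variation x before the transition rule
(all with f(0) = 0, non-decreasing, λ = 10): `kh` f(x) = λx, `pow`
f(x) = (λx)², `sin` f(x) = sin(πx/2), `chi` x·e^(−x²/2λ) rescaled to peak
1. The kernel interface is deliberately pluggable: these shapes are
reasonable members of the operator families they name, and alternative
forms can be swapped in without touching the colony.

Design choices where the procedure was genuinely open: the four stages are
sequential restarts of ant positions sharing one pheromone field; each ant
keeps a tabu list of its last 8 pixels and teleports to a uniform random
pixel when every admissible neighbor is excluded; the local update relaxes
a visited pixel toward τ₀ (applied once per visiting ant), and the global
update moves this iteration's visited pixels toward η — depositing η rather
than a constant makes the field edge-selective. τ is clamped below at
τ₀·10⁻³. A single seeded NumPy generator drives ant initialization, step
sampling and teleports in a fixed draw order, so runs are bit-reproducible.

Binarization uses the iterative mean-split threshold: T₀ = mean τ, then
T ← ½(mean of τ below T + mean of τ above T) until |ΔT| < 10⁻⁸ or 100
rounds; a constant field yields an empty map with a warning.

Problem sizes: the validation suite runs reduced budgets (1 stage × 100
iterations on 64×64 phantoms), where pheromone on the true edge set already
exceeds the off-edge mean by a factor ≫ 3; the full 4 × 1536 budget is
exercised as a smoke test on a 32×32 phantom.

## Fuzzy edge map and linking

The fuzzy edge map is S(g̃) where g̃ is the Sobel magnitude of the
Gaussian-smoothed image (σ = 1.5) normalized to [0, 1], and S is the
standard two-piece quadratic S-function with lower knee a = 0.05 and upper
knee b = mean + std of the positive g̃ (capped at 1) so the saturation
point adapts to image contrast. Endpoints are pinned (g̃ = 0 → 0,
g̃ = 1 → 1). Linking is deterministic: hysteresis with defaults
t_low = 0.3, t_high = 0.7, then endpoints of the kept set (pixels with ≤ 1
kept neighbor) within Chebyshev distance ≤ 3 are joined by the discrete
line between them, bridged pixels receiving the smaller endpoint
membership. Kept memberships are never amplified, and bridging cannot
increase the number of strong components. A probabilistic linking rule
would be a drop-in replacement; the deterministic bridge was chosen for
reproducibility.

## Fuzzy C-means

Clustering uses intensity as the single feature (spatial variants are out
of scope). Defaults: k = 4 classes, fuzzifier 2, tolerance 10⁻⁵ on the
largest center shift, 200 iterations max. Updates run on the unique
intensity values weighted by their pixel counts — algebraically identical
to per-pixel FCM (verified against a brute-force per-pixel implementation
in the tests) and far cheaper. Centers initialize at evenly spaced
intensity quantiles with a ±1 % of range seeded jitter to break symmetry;
a pixel coinciding exactly with a center gets crisp membership there.
Cluster ids are sorted by ascending center so outputs are stable. The
objective trace is recorded each iteration and is non-increasing by the
alternating-minimization structure. Contrast enhancement before clustering
is a percentile stretch (defaults 1–99 %) to the full value range.

## Evaluation layer

Fuzzy confusion uses the fuzzy intersection FTP = min(Ni, Nd) and bounded
differences FFP = max(0, Ni − Nd), FFN = max(0, Nd − Ni), with scalar
cardinalities as grid sums (computed with compensated summation). Two
identities follow pointwise and are enforced by tests: |FTP| + |FFP| = |Ni|
and |FTP| + |FFN| = |Nd|. With Ni the reference, "FFP" is reference mass
unmatched by the detection — the naming tracks the formulas rather than the
everyday false-positive reading, and we keep it that way for consistency
with the metric family the package implements. Percent summaries are
100·|X|/(m·n); note cardinalities of graded maps can make these exceed 100.

The fuzzy index weights the true-positive mass by Σ 1/(1 + FD), where FD is
the Euclidean distance transform of the detected support (membership >
support threshold, default 0) divided by the grid diagonal maxD. FI = 1
exactly at all-ones perfect agreement and decreases with any added false
mass. The distance-transform path is verified against brute-force
nearest-support search in the tests.

Crisp metrics follow standard definitions with these conventions: ratio
metrics are 1 when both masks are empty and 0 when exactly one is; SSIM
uses an 11×11 Gaussian window (σ = 1.5), K₁ = 0.01, K₂ = 0.03 and the
declared value range; max NCC searches all integer shifts with ≥ 25 % grid
overlap, re-normalizing each overlap window (O(shifts · pixels) — intended
for modest image sizes).

## Alpha-cut statistics

A metric collected over several detection methods is summarized by its
mean, sample standard deviation and variance (n − 1 denominator, zero
spread at n = 1). Uncertainty is expressed two ways: the alpha-cuts of a
triangular fuzzy number centered at the mean with spread std —
[mean − std·√(1−α), mean + std·√(1−α)], degenerate at α = 1 — and the
two-sided Student-t confidence interval with n − 1 degrees of freedom.
Grouping is explicit (per case study) rather than implicit pooling.

## Known limitations

* The ACO kernel shapes are conventional stand-ins behind a stable
  interface, not calibrated operator definitions.
* Phantoms omit MRI physics; evaluation numbers on phantoms do not predict
  clinical values.
* max NCC is exhaustive over shifts and not intended for large images.
* No DICOM/NIfTI, multi-slice volumes or color-space management.
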