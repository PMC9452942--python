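# Methods

This note records the modelling choices behind `sccnn`: what the model
assumes, which parameters matter and why their defaults are what they are,
what the synthetic scenes do and do not emulate, and the numerical
conventions used throughout.

## Colour model and stain separation

Brightfield H&E imaging is modelled by the Beer–Lambert law: transmitted
intensity decays exponentially with the amount of absorbing dye, so the
per-channel optical density `OD_c = −log10(I_c / I0_c)` is linear in stain
concentration.  We use base-10 logarithms throughout, so a pixel passing
one tenth of the incident light has OD exactly 1; the exponential form of
the law is read as the equivalent base-10 expression.  The incident
intensity defaults to 255 per channel (8-bit sensors) and is configurable.

Each stain is a row of absorbance coefficients; rows are normalized to
unit Euclidean norm before unmixing (normalization is idempotent, and the
deconvolution is therefore invariant to any positive rescaling of the raw
rows).  With stains as rows of the normalized matrix `A`, a pixel's OD
vector is `od = Aᵀ c` and concentrations are recovered as `c = D od` with
`D = pinv(Aᵀ)`.  For three independent stains `D` is the ordinary inverse;
for the usual two-stain H&E case the Moore–Penrose pseudo-inverse performs
the least-squares projection onto the stain plane and satisfies
`D Aᵀ = I₂` exactly.  A widely reproduced printed H&E "deconvolution
matrix" in the literature is *not* the pseudo-inverse of the H&E absorbance
rows shipped here; we always compute `D` from the supplied stain matrix
rather than hard-coding any published inverse.

Numerical conventions: intensities are clamped at `I0·10⁻⁶` before the
logarithm, bounding OD at 6 on saturated dark pixels; recovered
concentrations may be slightly negative on noisy pixels and are *not*
clipped by default (an optional flag clips for visualization), which keeps
the linear-algebra identities exact for testing.

## Probability-map targets

The detector regresses the surface

    y_j = 1 / (1 + ‖z_j − z_m*‖²/2)   if ‖z_j − z_m*‖ ≤ d,   else 0,

with m* the nearest annotated center.  The kernel constant 2 is the halved
squared Euclidean distance that also defines the distance weight; the
support radius defaults to d = 4 px, enough to cover a nucleus center
region without neighbouring kernels merging at realistic spacings.
Conventions fixed once: coordinates are 0-based `(row, col)` with pixel
centers at integer positions; the support test uses the closed disc
(`≤ d`); equidistant ties go to the lower-index center, making the map a
deterministic function of the ordered annotation list.  The production
builder is vectorized but must agree *exactly* (bitwise) with an
exhaustive per-pixel evaluation; the test suite enforces this on maps up
to 64×64 with up to 10 centers.

## The spatially constrained network

The trunk follows the reference architecture exactly: 27×27×1 input,
4×4×1×36 valid convolution (→24×24×36), 2×2 max pool, 3×3×36×48
convolution (→10×10×48), 2×2 pool, then 512- and 512-unit fully connected
layers, all ReLU.  Two custom layers replace the usual output head:

- **Parameter estimation** maps the 512-vector to M candidates
  `(u_m, v_m, h_m)`.  The sigmoid squashing makes `u ∈ [1, H′]`,
  `v ∈ [1, W′]`, `h ∈ (0, 1)` *by construction* — candidate sets cannot be
  invalid regardless of the weights.  Outputs are 1-based map coordinates
  (the `+1` in the affine rescaling); the spatial layer subtracts 1 to get
  to the 0-based pixel frame.  The sigmoid is the standard increasing
  `1/(1+e^{−x})`; a decreasing variant would be incompatible with its role
  of mapping features onto the `[1, H′]` interval.
- **Spatial constraint** renders the candidates analytically:
  `ŷ_j = h_m* /(1 + ‖z_j − ẑ_m*‖²/2)` inside radius d of the nearest
  candidate, else 0.  The height factor is essential: it is what lets
  `h = 0` disable a candidate so the model can represent 0…M nuclei per
  patch.  The layer is differentiable in `(u, v, h)` away from the
  measure-zero support and assignment boundaries; the backward pass treats
  the nearest-candidate assignment as locally constant.  M defaults to 1
  (a 27×27 patch barely exceeds one nucleus support) and is configurable
  up to 5.

**Loss.**  Weighted cross-entropy `Σ_j (y_j + ε) H(y_j, ŷ_j)` with
`H(y, ŷ) = −y log ŷ − (1−y) log(1−ŷ)`.  ε is computed per training batch
as the ratio of nonzero- to zero-probability target pixels (floored at
10⁻³ for all-background batches); it keeps the ~40 support pixels of a
positive target from being drowned out by the ~80 background pixels while
still penalizing false structure.  Predictions are clamped to
`[10⁻⁷, 1−10⁻⁷]` before the logarithms.  Analytic gradients of both custom
layers and of the loss are validated against central finite differences at
10⁻⁵ tolerance.

**Training.**  Plain mini-batch SGD with momentum 0.9, batch 32, 30
epochs.  The learning rate defaults to 0.005: the map-regression loss has
an early plateau (candidates must traverse flat zero-gradient regions
before locking on), and larger rates can oscillate around it; 0.005
descends smoothly across seeds.  Everything — weight init and shuffling —
derives from one integer seed, and equal seeds give bitwise-identical loss
traces.

**Inference.**  Images larger than the 27×27 input are scanned with a
sliding window.  The 11×11 output map of a window sits at the symmetric
offset (27−11)/2 = 8; the default stride of 11 tiles the interior exactly,
and overlapping windows (denser strides, or the flush windows at the right
and bottom edges) are averaged.  The 8 px border of an image is outside
every window's output frame and stays 0 — nuclei annotated there are not
detectable, which the scene generator's placement margin respects.

## Detection scoring

Peaks are 8-neighbourhood local maxima at or above a threshold (default
0.5, the midpoint of the map range), kept greedily by descending value
(ties row-major) with suppression below a minimum separation (default d =
4 px, preventing duplicate hits on one nucleus).  Predictions match ground
truth one-to-one, greedily by ascending center distance within a matching
radius (default 6 px, slightly above the support radius); the Hungarian
optimal assignment is available as an option and agrees with the greedy
rule on well-separated instances.  Per-image precision/recall/F1 lists are
summarised by max, min, mean, and the *population mean squared deviation
about the mean* — the "mean square error" row of the standard report
tables is read as this dispersion statistic, since no external reference
value exists for a per-image score.

## Classification and adjacent-set prediction

The classifier reuses the detector trunk with a K-way softmax head (K = 4:
epithelial, inflammatory, fibroblast, miscellaneous by convention; the
model sees only indices).  Adjacent-set prediction averages a nucleus's
probability vector (weight 1) with those of all detections within a
radius (default 30 px, a few nucleus diameters; neighbour weight default
1) and renormalizes — a convex combination, so outputs remain valid
probability vectors.  The aggregation rule is an interpretation fixed by
config, not canon.  The refinement helps exactly when neighbourhood class
purity is high and the solo classifier's errors are independent across
neighbours; a systematically biased solo classifier (e.g. one trained on
class-imbalanced data) has *correlated* neighbourhood errors that
averaging amplifies, which is why the canonical experiment trains on
non-clustered, class-balanced tiles and evaluates on clustered ones.
Multi-class AUC is the macro average over classes present in the labels of
the one-vs-rest ranking AUC with midrank tie handling (a constant
classifier scores exactly 0.5).

## Synthetic scenes

Nuclei are anisotropic Gaussian hematoxylin-density blobs (scale σ per
class, truncated at 3σ so supports are compact), composited additively in
OD space over a uniform eosin background of density 0.3, with Gaussian OD
noise (σ = 0.02) added *before* conversion to RGB — keeping the
Beer–Lambert inverse linear-Gaussian so recovery bounds stay analytic —
then quantized to 8 bits.  Centers sit on the integer pixel grid (like
point-click annotations) with a minimum separation and a placement margin
of 9 px so every nucleus lies inside the sliding window's covered
interior.  The four class appearances (σ ≈ 1.7–2.6 px, peak OD ≈ 0.6–1.25,
eccentricity 0.05–0.55) overlap deliberately: classes are separable but
not trivially, so classifier accuracy is meaningfully below 1.

Default detection tiles are 71×71 (= 8 + 5·11 + 8, so stride-11 inference
covers the interior exactly) with 8 nuclei at ≥ 16 px separation.  The
classification experiment uses 151×151 tiles with 30 nuclei at ≥ 14 px;
training tiles draw classes i.i.d. (class-balanced), evaluation tiles
assign classes by the nearer of two random cluster seeds, making
neighbourhoods within the 30 px radius mostly single-class.

What the generator does *not* emulate: tissue texture, touching and
overlapping nuclei, out-of-focus blur, stain variability between slides,
scanner/compression artifacts.  Passing tests therefore demonstrate the
correctness of the algorithms and the learnability of the model under the
stated forward model — not performance on real slides, which depends on
annotation quality and appearance variation outside this model family.

## Experiment sizes

The canonical experiments are sized for a single CPU: the detection
experiment trains on 12 tiles (~192 patches, half background) for 30
epochs and evaluates on 6 held-out tiles (~48 nuclei), reaching held-out
F1 ≈ 0.91–0.98 across seeds; the classification experiment trains on 10
tiles (~280 patches) for 30 epochs and evaluates ~170 nuclei on 6
clustered tiles, where adjacent-set refinement typically adds 1–10
accuracy points over the solo classifier.  Each experiment runs in well
under a minute per seed.

## Known limitations

- M > 1 candidate training works mechanically but the default patch/map
  geometry rarely contains two nuclei, so multi-candidate behaviour is
  exercised far less than M = 1.
- The greedy matcher can differ from the optimal assignment when detections
  are denser than twice the matching radius; use the Hungarian option for
  crowded scenes.
- The 8 px inference border is blind; callers should pad images whose
  margins contain nuclei of interest.
- Checkpoints store flat float64 arrays; models are small (~1 M params) so
  no compression or partial loading is provided.
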