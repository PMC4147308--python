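# Methods

This note documents the measurement model, the synthetic-scene
generator, the numerical conventions, and the design choices that were
genuinely open. Every number quoted here is recomputed by the test
suite or by `scripts/acceptance.py`; none is asserted from memory.

## Measurement model

### Background subtraction

Each channel has a single scalar background, estimated as the channel
median by default (mode and user-fixed values are supported), subtracted
and clipped at zero; the scalar is recorded in the image metadata. The
median is appropriate for sparse fields where most pixels are
background; once a majority of pixels are exactly zero the operation is
idempotent. Whether the DAPI nucleus threshold is applied before or
after subtraction is configurable (`threshold_after_subtraction`,
default after) and always recorded, because raw-count thresholds are
equally defensible and the choice shifts the effective cutoff by the
background level.

### The three masks

Cell outlines are supplied (label mask or polygons); polygons are
rasterized by **center sampling** — pixel (r, c) belongs to a polygon
iff its center (c + 0.5, r + 0.5) lies inside — the same rule the
generator uses, so planted truth and measurement share one convention.
Overlapping or self-intersecting outlines are rejected.

The **membrane ring** is the cell mask minus its binary erosion by a
square (default) or disk element of radius `ring_width` (default 3 px,
≈ 0.6 µm at the default 0.2 µm/px). Erosion treats out-of-frame pixels
as background, so border-touching cells still get a full ring. Cells
thinner than twice the ring width become all membrane and their nucleus
is empty by construction.

The **nucleus** is the set of cell pixels with DAPI strictly greater
than the threshold (default 60 counts — note the strict inequality:
a uniform 60-count cell has no nucleus), minus any ring pixels (the
masks must be disjoint; the ring wins because it is defined first), then
reduced to the largest 8-connected component (the analysis assumes
mononucleate cells). A cell with an empty nucleus is flagged and its
nucleus-based metrics are reported missing, not zero.

### Intensity ratios

Compartment intensities are **sums**, not means; the distribution
statistics are `I_membrane / I_cell` and `I_nucleus / I_cell`. Because
numerator and denominator share the acquisition, any positive gain g
cancels exactly; `gain_invariance_check` verifies this to 1e−9. The
size-normalized total is `I_cell / area` with "size" interpreted as
pixel area — the only mask-derivable scalar used consistently; perimeter
or diameter normalization would be alternatives and the interpretation
is kept in one place should it need changing. Zero-total cells yield
missing ratios so that group means are not dragged toward zero by empty
cells.

### Perimeter and contact

Digital perimeters are convention-dependent, so the estimator is
explicit and recorded:

* **chain** (default): the Moore-traced 8-connected boundary chain,
  straight steps 1, diagonal steps √2; a single-pixel cell is 4 by
  convention; one-pixel-wide protrusions are traversed out and back.
  A 10×10 square gives 36 (4 × 9 steps). On smooth shapes this
  estimator carries the well-known positive bias of (1, √2) weights:
  a digitized disk of radius 20 measures ≈ 5% above 2πr.
* **crofton**: the 4-direction Crofton estimator
  (`skimage.measure.perimeter_crofton`), within 3% of 2πr on the same
  disk; preferable when absolute lengths matter.

All group comparisons use one estimator throughout, and percent contact
uses the same estimator for numerator and denominator, so the estimator
bias largely cancels in the ratio.

The **shared perimeter** of cell k is the chain length restricted to
boundary pixels lying within Chebyshev distance `contact_distance`
(default 2 px) of any other cell — a deterministic surrogate for the
manually traced "contacted membrane". The 2-px default tolerates
1-px rasterization gaps between abutting outlines; with two 10×10
squares abutting along a full edge and distance 1 the shared length is
9 chain steps (10 contact pixels). Percent contact is
`100 × shared / total`, bounded in [0, 100] by construction.

**Axis lengths** are the moment-ellipse major/minor axes
(`regionprops`), floored at 1 px so degenerate line-like masks give a
finite ratio; "longitudinal/horizontal" means major/minor irrespective
of image axes. Feret max is available as an alternative major axis.

### Co-localization

Split Manders coefficients with co-occurrence threshold 0 on
background-subtracted channels (configurable): M1 is the fraction of
channel-A intensity at pixels where B exceeds the threshold, M2
symmetric. The region (nucleus, membrane, or whole cell) is always an
explicit argument. PDM is the per-pixel product of deviations from the
regional means; its regional mean equals the A–B covariance by
definition, and the 64×64 linear-binned frequency scatter histogram
conserves pixel count exactly. Costes thresholding and
randomization-based significance are deliberately out of scope.

### Statistics

The unit of replication is the individual cell; image-level clustering
is ignored — a known limitation of the per-cell convention, kept
deliberately rather than corrected silently. The default test is the
classic equal-variance two-tailed Student's t (Welch by flag), reported
as mean ± SEM with `*` P < 0.05 and `**` P < 0.01. When both groups
have zero variance and equal means the p-value is reported as undefined
(NaN) rather than fabricated. No multiple-testing correction is applied
by default; a Benjamini–Hochberg toggle exists. Monte-Carlo calibration
(1000 null draws, n = 15 per group) puts the empirical type-I error at
α = 0.05 within [3.5%, 6.5%].

## The synthetic generator

### What it emulates

Sparse adherent cells on a uniform background: superellipse cell bodies
(exponent 5 "cuboidal", 2 "elongated"), a nucleus obtained by scaling
the cell polygon about its centroid by `nucleus_axis_fraction` (default
0.5), the same erosion-defined membrane ring the measurement uses, and
per-channel intensity split between ring, nucleus and cytoplasm.
Channel textures are sparse gamma fields (30% empty pixels, shape 2) for
punctate markers and flat for DAPI. Noise is Poisson shot noise on the
clean counts followed by additive Gaussian read noise (default sd 2
counts), clipped at zero.

**Budgeted rendering.** Each compartment's texture is renormalized to
sum exactly to its planted share of `cell_amplitude × area` counts, so
the clean-image compartment ratios equal the planted f_m, f_n to
floating-point precision (1e−9) and total cell signal is conserved
exactly — the recovery tests measure the pipeline's error, not the
generator's. When a compartment is degenerate (no nucleus pixels, no
cytoplasm), its budget is rerouted inward/outward and the realized
fractions are what the truth table records.

**Adjacency.** Shared boundaries are geometric: coincident polygon
edges.

* *isolated*: jittered grid with ≥ 8 px clearance; shared length 0.
* *chained*: a closed chain of annulus sectors around a ring. Every
  cell has exactly two neighbors and radial edge length
  dr = c·s/(1 − c) (s the arc width), so each cell's true contact
  fraction equals the target c exactly — a linear chain's end cells
  would bias the mean downward. The seam edge reuses bitwise-identical
  vertices so truth extraction (shapely boundary intersection) sees it.
* *clustered*: staggered mini-chains of four rectangles; the vertical
  stagger sets the shared-edge overlap from c (clamped at the geometric
  maximum h/(w+h)); realized per-cell fractions are recorded.

**Co-localization planting.** Within each compartment, each pixel of
channel B copies channel A's raw texture with probability ρ and
otherwise draws an independent texture with the same marginal; both are
then budget-renormalized. This makes expected nuclear M1 ≈ ρ + (1 − ρ)q
(q the marginal co-occurrence rate), i.e. strictly increasing in ρ; at
ρ = 1 the channels are proportional within each compartment (globally
proportional when both channels share compartment fractions, as in the
tests), and at ρ = 0 they are independent, so the expected PDM is zero.
A convex per-pixel blend ρ·A + (1 − ρ)·indep was rejected because any
ρ > 0 would make B positive wherever A is, saturating M1 at 1 and
destroying the monotone mapping the recovery tests rely on.

**Determinism.** All randomness flows from one
`numpy.random.default_rng(seed)` in a fixed draw order (cells ascending,
channels in declaration order, compartments membrane→nucleus→cytoplasm),
so a fixed seed fixes the scene bit-for-bit; the pipeline adds no
randomness, and CSV outputs are byte-stable.

### What it does not emulate

No point-spread function or optical blur, no 3D structure, no organelle
texture, no photobleaching, no cell-to-cell amplitude variation beyond
texture noise, no irregular real-cell outlines. Passing recovery tests
therefore shows that the *measurement conventions are unbiased under
the model's assumptions* (compartmentalized signal, known outlines,
scalar background, Poisson–Gaussian noise) — not that the pipeline is
robust to segmentation error or optical artifacts on real micrographs,
where outline quality will typically dominate.

## Numerical choices and problem sizes

* Default pixel size 0.2 µm/px (typical 60× confocal); a labeling
  convention only — all computation is in pixels.
* Contact recovery uses chained scenes with cell_size 100 px: the
  Chebyshev contact neighborhood picks up a few boundary pixels past
  each shared-edge corner (~2–3 px per corner), a fixed overhead that
  must stay small against the shared-edge length; at 100 px cells the
  measured mean stays within ~2 points of the planted 0/25/50%.
* Intensity recovery sweeps f_m ∈ {0.1, …, 0.9} at 30 cells per level:
  exact (≲ 1e−15) noise-free, ≲ 0.03 mean error under shot noise plus
  10%-of-amplitude read noise.
* The ρ = 0 PDM check pools ≥ 10⁴ nuclear pixels (30 cells, cell_size
  48) so the 3-SE band is meaningful; the power check (Δf_m = 0.3,
  20 cells/condition, 200 replicates) uses 24-px cells to keep the
  simulation cheap.
* Scale covariance (2× upscaling doubles perimeters within 2%) is
  exercised on rectilinear clustered scenes: nearest-neighbor upsampling
  of *diagonal* boundaries genuinely lengthens the digital staircase
  (both chain and Crofton measure ×2.1–2.3 on sector cells), so on such
  shapes only the contact *ratio* is scale-stable (within ±2 points),
  which is what the biology uses.
* Tie-breaks: pixels whose center falls exactly on a shared polygon
  edge belong to the lower cell id (first claim); the largest-component
  rule breaks nucleus ties by `argmax`, i.e. the component discovered
  first in raster order.

## Known limitations

Manual/real outlines are taken as given — no automatic whole-cell
segmentation. One nucleus per cell is enforced. The shared-perimeter
definition is a fixed-radius surrogate, not an intensity-based junction
detector; its small positive corner bias is visible in the recovery
numbers. Cell-level pseudoreplication is inherited from the per-cell
convention. The Manders co-occurrence threshold defaults to 0 after
background subtraction; noisy backgrounds inflate M1/M2 toward the
co-occurrence floor, which is why the monotonicity checks compare
conditions at a fixed noise level.
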