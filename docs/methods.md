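# Methods

This note documents the models, conventions and parameter choices behind
`adhesivect`, and what the synthetic tests do and do not demonstrate.

## The measurement model

The object of study is the adhesive film between a tooth cavity wall and a
composite restoration. Its local width/thickness *w* (mm) is defined by the
standard wall-thickness measure used in micro-CT software: the thickness at
a point is the diameter of the largest sphere that fits entirely inside the
film and covers that point. This definition is orientation-free and needs
no surface normal estimate.

On a voxel grid we use the convention

    thickness(v) = 2 · vs · max{ d(c) : c ∈ film, |v − c| ≤ d(c) }

where `vs` is the isotropic voxel size and `d(c)` is the Euclidean distance
from the centre of voxel `c` to the nearest background voxel centre
(voxels outside the grid count as foreground, so a film spanning the field
of view behaves as if it continued). All comparisons are carried out on
exact integer squared distances, so the fast implementation (distance
transform → distance-ridge extraction → sphere marking in decreasing
radius order, ties broken by scan order) is bit-for-bit identical to an
exhaustive search over all covering spheres, which the test suite verifies
on random masks up to 32³.

Discretization: a film of even voxel count k reads exactly k·vs; odd
counts read (k+1)·vs. Every reading is therefore within one voxel of the
continuous film height wherever the film roof is locally flat. No single
discrete convention reproduces the continuous inscribed-sphere diameter
for all degenerate shapes: here an isolated voxel and a 2×2×2 block both
read 2·vs. We chose the convention that is exact for films (the object of
interest) rather than for point-like artifacts.

Where the film roof slopes steeply (|∇h| of order 1), the inscribed-sphere
reading is systematically below the film height, and near thin valleys
adjacent to thick domes it is above it. This is a property of the measure,
not of the implementation; it matters for the phantom presets (below).

## S(w) and the volume statistic

The area-width distribution S(w) assigns to each width bin the interface
area carried by film of that width: each tooth-side interface face (a film
voxel whose 6-neighbour toward the tooth is background) contributes
voxel_size² mm² to the bin of its own local width. Face counting conserves
total interface area exactly under re-binning, which gives the
model-fitting stage a closed-form oracle. The default bin width is
0.01 mm, the resolution apparent in published area-width curves; presets
whose whole width span is below 0.05 mm use 0.002 mm so at least six bins
are occupied. Half-open bins [e_i, e_{i+1}); per-area (vestibular / oral /
pulpal) splits of S(w) are out of scope in v1.

Two volume-like quantities are computed and reported side by side:

* **V (the ranking statistic)** = ∫ S(w) dw over the fitted piecewise
  model, from the first knot to w_max. Because S is a *per-bin area*, this
  integral is approximately (bin width) × (total interface area) and is
  meaningful as a relative index between groups measured with the same
  binning, not as a physical volume.
* **physical (thickness-weighted) volume** = Σ areaᵢ × (bin centre)ᵢ, the
  layer-cake volume of a film with that area-at-width histogram. On
  phantoms whose roof slope is small this recovers the exact ground-truth
  film volume to a few percent.

## Anchor points and the piecewise model

A curve is summarized by four anchors: onset (w₀, S₀) — the first occupied
bin; peak (w_M, S_M) — the argmax of a centred moving average (default
window 3 bins; window 1 disables smoothing and is appropriate for
noise-free curves); tail knot (w_I, S_I); terminal (w_max, S_m). All S
values are read from the smoothed curve. The tail knot is located at the
post-peak minimum of the smoothed curve's gradient magnitude — the
hand-over point where a descending parabola meets a shallow linear tail.
(A fixed "5% of peak gradient" threshold undershoots the knot even on
exact curves, because the crossing necessarily happens before the gradient
minimum; the argmin rule recovers the knot of an exactly synthesized
sharp-peak curve within half a bin.) The trailing window of bins is
excluded from the argmin because the moving average's edge padding
artificially flattens it.

Two template shapes, three pieces each, C0-continuous at interior knots
(the published curve shapes are not derivative-continuous, so only C0 is
enforced):

* **Template A** (broad, late peak; groups without field exposure): an
  S-shaped rise made of two parabolas — vertex at (w₀, S₀) and at
  (w_M, S_M), meeting at the interval midpoint at height (S₀+S_M)/2 —
  then a quadratic tail through the peak, tail knot and terminal. If that
  interpolating quadratic dips negative (its roots bracket the interval
  when S_I and S_m are both near zero), the tail falls back to the
  monotone parabola with vertex at the terminal point: S(w) ≥ 0 is part of
  the model contract.
* **Template B** (early sharp peak; field-exposed groups): a pure rising
  parabola a·w² with a = S_M/w_M², a descending parabola with vertex at
  the tail knot, and a straight line to the terminal.

Automatic template choice: A when w_M ≥ 0.05 mm, else B.

`fit_model` performs equality-constrained linear least squares of the
template's polynomial pieces against bin centres/areas (constraints: C0 at
interior knots), solved by null-space substitution. An interval with fewer
occupied bins than free coefficients is pinned to the anchor-built piece
and flagged in the result. On noise-free synthesized distributions the fit
recovers generating coefficients to better than 1e−6 relative; at 2% of
S_M i.i.d. noise the median per-coefficient relative error stays below 5%
(the tail slope coefficient alone is signal-to-noise limited to ~10% under
those conditions — an intrinsic bound, not an estimator defect).

V is evaluated as the exact piecewise antiderivative; the tests check
agreement with adaptive quadrature to 1e−10 relative.

## Rank tests

`wilcoxon_signed_rank` (paired; zero differences dropped, midranks for
ties) and `mann_whitney_u` (independent arms, pooled midranks) report rank
counts, mean ranks and rank sums in the conventional table layout, with
two-sided p-values at α = 0.05. The asymptotic variant uses the
tie-corrected normal approximation without continuity correction, matching
the conventional statistics-package output the source tables follow. For
small samples (≤ 12 retained pairs, or pooled n ≤ 12) the exact null
distribution is computed by dynamic programming over doubled midranks
(integer subset-sum counting), with the two-sided p defined as
P(|T − E T| ≥ |t_obs − E T|); the tests verify equality with exhaustive
enumeration over all sign assignments / group labelings. No
multiple-testing adjustment is applied.

## The phantom generator

A phantom is a slab cavity: tooth below a flat interface plane (6 voxels
of margin), an adhesive film of laterally varying thickness t(row, col),
composite above, grayscale levels (90, 140, 200) plus Gaussian noise
(σ = 8 by default; levels are required to be > 4σ apart so the phantom is
segmentable by construction). Voxel centres sit at (i + 0.5)·vs; the film
occupies the voxels whose centres fall inside [z₀, z₀ + t). Ground truth
records the film mask (volume = count × vs³, exact), the realized
per-column film height, and the three area labels (column thirds of the
interface standing in for the vestibular / oral / pulpal walls).

The thickness field is white noise smoothed by a Gaussian kernel of width
`correlation_length` (periodic boundary), standardized, mapped through the
normal CDF and then through the Beta(2, b) quantile function with
b chosen so the field's mode sits at `peak_thickness`; the unit-interval
field is scaled to [base − amplitude, base + amplitude]. A plain affine
map of the symmetric Gaussian field cannot produce the strongly skewed
width distributions the study groups exhibit, which is why the quantile
map replaces it. Two small Gaussian bumps at fixed opposite corners of the
interface imprint one thinnest and one thickest spot, so every realization
attains the configured range endpoints exactly — mirroring the fact that a
reported per-group range *is* the observed min/max of a real sample. The
thick spot carries a half-voxel allowance so the discretized film still
reaches the maximum after voxel flooring.

### Group presets

The four presets encode the published study conditions: per-group width
ranges (1: 0.020–0.40, 2: 0.017–0.40, 3: 0.013–0.31, 4: 0.011–0.032 mm)
and predominant widths (≈0.1, 0.08, 0.02–0.03, 0.01–0.025 mm). Free
geometry parameters were fixed once as follows:

| group | grid (d×r×c) | voxel (mm) | corr. length (mm) | field mode (mm) |
|---|---|---|---|---|
| 1 | 128×128×128 | 0.005 | 0.10 | 0.100 |
| 2 | 128×104×104 | 0.005 | 0.10 | 0.060 |
| 3 | 128×104×104 | 0.004 | 0.06 | 0.020 |
| 4 | 64×128×128  | 0.001 | 0.02 | 0.018 |

* Voxel sizes keep the thinnest film in each group at ≥ ~3 voxels while
  the deepest film still fits the grid.
* Lateral grid extents scale the total interface area per group in the
  proportions of the published volume statistics (the per-bin integral V
  is area-driven, so groups must differ in interface area for V to rank
  them, exactly as the published curves differ in their total areas);
  Group 4's area is bounded by its fine-voxel grid.
* The internal field modes of Groups 2–3 sit below the target measured
  peaks because the inscribed-sphere reading of a rough film is shifted
  relative to the film-height marginal (steep-roof underestimation and
  dome-into-valley cross-talk); the values above were calibrated once so
  the *measured* S(w) argmax lands at the published predominant widths.
* Correlation lengths are chosen of the order of the film thickness scale;
  shorter values make the inscribed-sphere reading underestimate the film
  volume badly, longer ones leave too few independent patches per field
  for a stable histogram.

### What the phantoms do and do not show

The phantoms share the real data's statistical structure — three-material
contrast with noise, skewed width distributions over the published ranges,
group-wise area/width differences — but not its physics: no X-ray
projection, reconstruction artifacts, beam hardening, partial-volume
blur, or irregular cavity geometry (the slab keeps surface normals
well-defined for the ground truth; a curved-cavity variant is not
implemented). Passing tests therefore demonstrate the correctness of the
measurement and modelling chain under the stated geometry, and the
reproducibility of the published *ordering* of group volumes under those
conditions — not instrument-level accuracy on real scans. The published
V₁–V₄ magnitudes themselves are not reproduced: the published piecewise
coefficients are internally inconsistent (they neither interpolate the
published anchor parameters nor integrate to the published volumes), so
models here are always derived from anchors or data, and the ordering is
the comparison surface.

At desk scale a genuine limitation applies: representing a 0.4 mm-wide
inscribed sphere requires a thick patch of ≥ 0.4 mm lateral extent, more
area than a 0.64 mm-wide interface can devote to a rare tail width. The
measured S(w) of Group 1–2 phantoms therefore reaches w_max ≈ 0.15–0.35 mm
rather than 0.40 mm, while the generator's ground-truth field does span
the full published range (which is what the range-realization tests
check).

## Numerical and procedural choices

* Segmentation cleanup: radius-1 opening (erosion treats out-of-grid as
  foreground so the film's continuation is not eroded), largest
  26-connected component, then binary hole filling. Hole filling is
  essential for thickness work: at the default noise level ~0.2% of film
  voxels misclassify into isolated interior holes, and each hole caps
  every inscribed sphere through its neighbourhood, collapsing the S(w)
  curve toward the hole spacing. Opening necessarily planes off isolated
  single-voxel roof steps of a stepped discrete film (~1e−5 of voxels),
  so noiseless segmentation is checked to Dice > 0.9999 rather than bit
  identity.
* Virtual microscopy: widths are measured along the local in-plane normal
  at 10 equally spaced centreline points per interface area (a
  reproducible stand-in for an operator's "characteristic points"); the
  sampling scheme is recorded with the results.
* All pipeline randomness derives from one seed via `numpy` SeedSequence
  spawning (stream 0: phantom generation); identical configs produce
  identical reports, and re-running onto an existing output directory
  refuses unless overwrite is requested.
* Problem sizes in the test suite and acceptance script (128³-scale
  phantoms, 20 replicate sets for the ordering check in the tests, 5 in
  the acceptance script; oracle masks ≤ 32³) were chosen as the smallest
  sizes at which the checked statistics are stable.

## Known limitations

* Isotropic voxels only (enforced at load); no anisotropic support in v1.
* The inscribed-sphere/height discrepancy on steep roofs means the
  physical-volume recovery guarantee (±5%) holds for films whose
  amplitude-to-correlation-length ratio is modest (≲ 0.2), not for the
  extreme Group 1–2 presets.
* Area accounting is voxel-face counting; a marching-cubes surface area
  option is out of scope in v1.
* The rank tests implement the SPSS-style output of the source tables;
  no effect-size measures or multiple-testing control are provided.
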