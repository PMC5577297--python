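# Methods

`fcquant` re-implements, as a tested pipeline, a focal-contact segmentation
and quantification analysis for cultured podocytes under cyclic mechanical
stretch: talin-1-positive focal adhesions are detected per cell, their shape
and fluorescence activities measured, per-cell statistics compared between a
control and a fascin-1-knockdown condition, fluorescence gradients profiled
along radial stress fibers, and adherent cells counted across microscopic
fields. Because no imaging data are deposited for this kind of study, the
package ships a synthetic scene generator with complete ground truth; every
claim the test suite makes is a *recovery* property measured against that
truth, not a reproduction of the original micrographs.

## Synthetic scenes

A scene is one podocyte-like cell (default) in a 512×512 field at
0.2 µm/pixel — a typical 63× confocal sampling; neither pixel size nor bit
depth is a property of the analysis, so both live in the configuration.

**Cell footprint.** A smoothed random star-convex polygon (base radius
42 µm, low-order Fourier perturbation of ±~10%). Podocytes in culture are
large, flat cells; a star-convex outline reproduces their irregular but
unbranched silhouette well enough for per-cell bookkeeping.

**Focal contacts.** Rendered as anisotropic Gaussian spots whose half-peak
contour is exactly the drawn ellipse, so the recorded true area π·a·b is an
analytic property of the render and matches a rasterized half-peak mask to
within rasterization error. Per-cell count and per-contact area follow
truncated normal laws; the two study conditions are

| condition  | contacts/cell | contact area (µm²) |
|------------|---------------|--------------------|
| control    | 196 ± 15      | 1.48 ± 0.30        |
| knockdown  | 125 ± 12      | 1.19 ± 0.25        |

with axis ratio 3.0 ± 0.6 (truncated ≥ 1). Contacts are placed in the
peripheral band of the footprint (outer 30% by distance transform, the
region where talin-positive contacts concentrate) and aligned radially with
~9° jitter. Placement enforces an anisotropic minimum center separation of
1.45× the summed directional Gaussian extents: focal adhesions are discrete
structures, and without this the summed tails of collinear neighbours merge
at any threshold, making the drawn per-cell count unrealizable as a count
of resolvable objects. Slightly connected pairs still arise through noise
bridging; separating them is the splitting stage's job.

**Fibers.** In `stretched` mode, straight radial polylines from a single
actin-rich center (ARC, the most interior footprint point) to the boundary;
in `unstretched` mode, parallel chords. Fibers are stamped ~3 px wide; each
painted pixel carries the intensity of its own projected arc-length
position, so the noiseless on-axis intensity equals the linear
ARC-to-periphery law `base + slope·d` exactly (±1 unit from rasterization).
Defaults emulate opposite gradients: actin 100 → 20 (slope −80), fascin
20 → 100 (slope +80), per unit normalized distance along each fiber.

**Noise.** Poisson shot noise at camera gain 9.0 plus additive Gaussian
read noise (sd 10) on top of a uniform cytoplasmic background of 100. At
the default contact peak of 1000 this gives a peak signal-to-noise ratio of
10. The partition matters: the model is shot-noise dominated, so the
*relative* background fluctuation (σ≈31 on 100) stays small enough that a
background region is distinguishable from a dim object by contrast. What
the generator does **not** model: optical PSF beyond the Gaussian spot
shape itself, uneven illumination, autofluorescence texture, out-of-focus
light, 3-D structure, photobleaching. Passing recovery tests therefore
demonstrate correctness of the measurement chain under a fair noise model,
not robustness to every artefact of real microscopy.

Determinism: all randomness flows from one `numpy` `SeedSequence`; a spec
plus seed reproduces a scene bit-exactly, and group seeds are spawned from
a single root seed.

## Focal-contact detection

Three pure stages over a config dataclass (all parameters exposed in YAML):

1. **Gradient-seeded local threshold.** A pixel is a candidate iff it
   exceeds the local mean + `local_k`·(local sd) in a circular window
   (radius `window_radius_px`, mirrored borders), and its connected
   component contains at least one gradient seed — a pixel whose 3×3 Sobel
   magnitude lies above the `gradient_seed_percentile` of the image. With
   zero additive background the decision is invariant under intensity
   rescaling (mean and sd scale together). A constant image yields an empty
   mask.
2. **Center/periphery specificity.** For each candidate component, the mean
   over its core (erosion by `core_erosion_px`; whole component if the
   erosion empties it) divided by the mean over a ring `ring_width_px` just
   outside (candidate pixels excluded) must reach `specificity_ratio_min`,
   and the component must reach `min_area_px`. A zero/empty periphery
   counts as infinite contrast (retained, logged). Retained components keep
   their pixel sets.
3. **Splitting.** Marker-based watershed on the negated Euclidean distance
   transform. Markers are h-maxima of the distance transform (depth
   `split_h`); marker regions closer than `split_min_separation_px` within
   one component are merged, so an isolated convex object keeps one marker
   and passes through unchanged. The output is an exact partition of the
   input foreground.

Defaults (window 9 px, k 1.25, percentile 90, ring 2 px, erosion 1 px,
ratio 1.9, min area 10 px, marker separation 5 px, h 1.0, 8-connectivity)
were fixed in a single calibration pass against the synthetic study
conditions and then frozen. The governing trade-offs: the threshold window
must be small enough that the detection contour is set by each spot's own
flux rather than by scene crowding (which differs between conditions), yet
`k` low enough that the contour sits near half-peak so measured areas match
the half-peak truth; the specificity ratio must sit between the contrast of
selected noise clusters (≈1.5–1.7 under this camera model) and that of true
contacts (≳2.5); and the marker-merge radius must exceed the distance
between spurious h-maxima of one elongated contact (≲5 px) while staying
below the separation of genuinely distinct overlapping objects. The
original tool's parameter values were never published; these are declared
substitutes, not recovered values. Likewise the ordering — specificity
filter before splitting — is this package's choice.

## Cells, assignment, quantification

*Semi-automatic* cell segmentation takes one user seed per cell and finds
boundaries by seeded watershed on the smoothed (σ = 3 px), inverted
intensity restricted to an Otsu foreground support. In the synthetic
recovery experiments the generator's footprints stand in for the
user-drawn cell regions, isolating contact-detection error from
cell-boundary error.

Contacts are assigned to the cell containing their (rounded) centroid
pixel; the distance to the cell edge is the cell region's Euclidean
distance transform at that pixel, in µm. Shape parameters are the standard
moment set — area (pixel count × pixel size²), centroid,
moment-equivalent-ellipse axes (4·√eigenvalue of the coordinate
covariance), eccentricity, orientation (from the +col axis, (−π/2, π/2],
horizontal = 0) — plus mean/integrated intensity and the same
center/periphery contrast used in detection. Per-cell summaries report
contact count, mean and total contact area; cells without contacts report
a missing mean. Both per-cell means and pooled-contact statistics can be
derived from the records; the experiments weight cells equally, matching
the per-cell reporting convention of the source assay.

Adherent-cell counting normalizes each nuclei field to its max (making
counts scale-invariant for zero background) and runs a
Laplacian-of-Gaussian blob detector at the expected nucleus radius.
Relative adhesion is 100·mean(test)/mean(control) with the two field-mean
SEMs propagated through the ratio.

## Fiber profiles

A fiber path is an ordered polyline starting at the ARC. Channels are
sampled every 0.25 px of arc length with bilinear interpolation and
averaged into `n_bins` (default 20) equal-arc-length bins. `distances` is
the bin coordinate pinned to 0 (ARC) … 1 (periphery); `bin_centers` holds
the mean sampled position per bin and is the correct abscissa for slope
estimation (regressing against the pinned coordinate compresses slopes by
(n−1)/n). Profiles are reported raw; per-fiber max normalization is
optional, since whether the original measurements were background-corrected
is unknown. Aggregation is the per-bin mean ± SEM across fibers and is
permutation-invariant.

## Group statistics

Summaries are mean ± SD with SEM = SD/√n. Percent reduction is computed as
`100 − 100·test/control` (exact identity). The unpaired t-test defaults to
the pooled-variance Student form (the source analysis says only "unpaired
t test"); Welch is a flag. Two zero-variance groups with equal means give
t = 0, p = 1. The Mann-Whitney U uses midrank ties and U = min(U₁, U₂);
for combined n ≤ 12 the two-sided p is the exact permutation probability
P(U ≤ U_obs) by full enumeration, otherwise a tie-corrected normal
approximation with continuity correction. All p-values are two-sided and
uncorrected for multiple testing, as in the source analysis. The "±" on a
percent reduction is reported as a bootstrap SE over cells — the original
derivation of that error bar is unstated, so ours is labelled for what it
is.

## Problem sizes and numerical choices

The recovery experiments run 50 cells per condition (full detection
pipeline), 40 nuclei fields per condition, and 15 gradient cells × 5
fibers; these sizes give group-mean standard errors comfortably below the
tolerances being asserted while keeping a full run on a laptop-class CPU
around a minute. Degenerate inputs are defined, not special-cased ad hoc:
empty label maps propagate to empty record lists; a contact-free cell
reports a missing mean area; a constant image thresholds to nothing and a
blank field counts zero nuclei; a periphery mean of zero retains the
component with infinite contrast. Oracle mode (`oracle_mode: true`)
bypasses segmentation and quantifies the generator's truth tables directly,
separating statistical from segmentation error; on it, the pipeline's
reduction equals the truth-table reduction exactly.

## Known limitations

* Detected areas carry a size- and crowding-dependent bias of up to ±9%
  relative to half-peak truth (threshold-level physics, see above); counts
  are recovered to ~1%. Because the per-group area biases have opposite
  sign (control slightly under-segmented, knockdown slightly over-grown),
  the *detected* mean-area reduction between conditions is compressed
  relative to the generating 19.6%; area-based reductions are therefore
  read from truth tables / oracle mode, while the detected per-group means
  themselves stay within the stated 10%.
* The original tool is undescribed beyond a few sentences; behavioural
  equivalence cannot be claimed, only functional equivalence of the
  published outputs (per-cell counts, areas, reductions, significance).
* The cell-segmentation stage assumes seeds from a human; it is not a
  confluent-monolayer segmenter.
* Published intensity histograms from the original imaging are figure-only
  and are not reproduced numerically; the profile stage asserts slope
  recovery and monotonicity on generated data instead.
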