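# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic scenes do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Coordinate and unit conventions

Pixel indices are 0-based, coordinates refer to pixel centers, y grows
downward, and physical lengths are pixel counts × `pixel_size_um`.
Polylines are `(N, 2)` arrays of `(x, y)`; image arrays are
`(channel, [z,] y, x)` with channels addressed by name only. All metrics
are reported in µm / µm³ at the pixel sizes provided by the caller
(defaults correspond to a 100× objective at 0.065 µm/px). Loaders clamp
negative intensities to zero and log the count; no denoising or
deconvolution is performed — the pipeline assumes restored input.

## Basal mRNA fraction

**Model.** The BM-attached layer (binary mask plus basal/apical boundary
polylines) receives a normalized depth `u(p) = d_b(p) / (d_b(p) + d_a(p))`
where `d_b`, `d_a` are Euclidean distance transforms of the rasterized
boundaries. On a rectangle with flat horizontal boundaries this reduces
exactly to the row fraction; on curved bands it approximates the
normal-offset fraction (verified to RMS < 0.02 against the analytic
geometry of the sinusoidal generator band). The ratio form was chosen
over per-column vertical distance because tongue sections are curved; a
depth definition that survives curvature and degenerates to the obvious
answer on rectangles is the least surprising option.

**Binning.** Bin *i* of *n* collects pixels with `u ∈ [(i−1)/n, i/n)`,
the last bin closed. An exact edge value joins the upper bin; edge hits
are measure-zero for distance-ratio depths, so the choice is cosmetic but
is fixed and tested. Empty bins contribute 0, not NaN. The basal fraction
sums the basal-most `cutoff · n` bins; the cutoff must align with the bin
grid (0.3 with 10 bins) and misalignment raises.

**Background.** "Uniform background subtraction" defaults to `auto`: the
median intensity of non-mask pixels in the mask's bounding box, falling
back to all non-mask pixels when the mask fills its box. A scalar
override exists for parity experiments. Subtraction clamps at zero; a
fully clamped channel raises "zero total intensity" downstream rather
than silently returning 0/0.

## DEJ variation (Ra)

The band is resampled perpendicular to its centerline at unit-arclength
steps with bilinear interpolation; row `width_px / 2` is the centerline
exactly, so an axis-aligned band reproduces the raw crop bit-for-bit.
The band image is binarized (Otsu on the band only — the band's
membrane/dermis bimodality is the modeling assumption; scalar override
available), connected objects smaller than `min_object_px` (default 10)
are discarded so that isolated noise pixels cannot enter the trace, and
the result is skeletonized to 1-px curves. Per column, the mean row of
skeleton pixels gives the offset; several pixels in a column average
symmetrically (a nearest-to-previous-column tracker was rejected as
order-dependent). Columns without skeleton pixels are flagged invalid
and skipped, not interpolated — the metric normalizes by the number of
columns actually measured. Coverage below 0.5 raises. The metric is
`mean |offset| × pixel size`; defaults (width 120 px, 0.065 µm/px) match
the 7.8 µm band the tissue protocol uses. An optional `max_offset_px`
keeps only skeleton pixels near the centerline to suppress suprabasal
staining branches; it defaults to off.

Noise-free sine scenes of amplitude 2–10 px recover `2A/π` within 5%
end-to-end, and additive noise at SNR 5 moves the sine metric by < 10%.

## Cortical ratio and PDI

The normalized boundary coordinate is `r = 1 − d_edge / max d_edge` with
`d_edge` the distance transform inside the cell mask. "Peripheral 15%"
is interpreted as `r ≥ 0.85` and "central 65%" as `r ≤ 0.65` — a
distance-percentile (erosion-like) reading that is scale invariant and
keeps the zones topologically annular, matching how band selections
shrink in common raster tools; an area-percentile alternative is
available via `mode="area"` for sensitivity analysis. Cells below 50 px
area are rejected to keep zone discretization error small.

PDI is implemented as the second-moment ratio
`PDI = (Σ I |p−c|² / Σ I) / (Σ |p−c|² / N)` with `c` the unweighted mask
centroid. A literal difference-of-centroids statistic normalized by a
uniform reference is degenerate — a uniform signal's intensity-weighted
centroid coincides with the cell centroid, so the reference is zero —
and only the moment form satisfies the defining property that
homogeneous signal scores exactly 1, peripheral > 1, perinuclear < 1.
The moment form yields 1 identically for uniform signal on any mask
shape, ≈ 0 for a point mass at the centroid, and → 2 for signal on the
rim of a disk.

## Fiber volume

Transparent voxel pipeline: `intensity ≥ threshold` → 26-connected
components → per-component volume (voxel count × voxel volume), surface
area (exposed voxel faces, per-axis face areas for anisotropic voxels),
sphericity `ψ = π^{1/3}(6V)^{2/3}/A` → remove components that are BOTH
smaller than `min_volume_um3` AND more spherical than `max_sphericity` →
sum kept volumes. The conjunction matters: large spheres and small
elongated fragments survive. Volume is conserved exactly across the
filter split, and the unfiltered total volume is monotone non-increasing
in the threshold; the debris filter itself is deliberately not monotone
(a merged blob can be removed while its fiber part alone would be kept).

The voxel-face surface estimate overestimates A on curved surfaces by up
to ~1.5×, so ψ sits below its continuum value: voxelized spheres measure
ψ ≈ 0.64–0.69 (continuum 1) and 5:1 capsules ≈ 0.43–0.46. The defaults
`min_volume_um3 = 0.2`, `max_sphericity = 0.55` are calibrated against
the generator's capsule/sphere geometry to separate those populations;
they are configuration values to be held fixed across the conditions of
an experiment, not universal constants. Commercial surface-rendering
pipelines use unpublished meshing parameters; parity with them is not
claimed — only the described logic is implemented. Region restriction
(e.g. DEJ-proximal dermis) is honored via an optional ROI mask input
rather than computed automatically.

## ROI statistics

Epithelial thickness is the mean, over 200 equally spaced arclength
positions on the basal boundary, of the minimum Euclidean distance to
the apical polyline — averaging along the basal line is robust where a
symmetric Hausdorff-style statistic would be dominated by outliers.
Coincident polylines give 0; properly crossing polylines raise.
Double-positive density counts cells whose per-channel mean intensities
meet both thresholds, per µm of DEJ arclength; positivity thresholds are
user configuration (positives are called against markers by the
experimenter), and the defaults used in tests are generator-calibrated,
not tissue-derived.

## Synthetic scenes: what they emulate, and what not

Each generator is seeded (`numpy.random.default_rng`), bit-reproducible,
and records closed-form expectations with their derivation names.

* **Layer sections.** RNA is a sum of isotropic Gaussian spots
  (default σ = 2 px, the standard forward model for diffraction-limited
  puncta) whose normalized depth follows `uniform`,
  truncated-`exponential(τ)` or `point_mass(u0)` laws; expected basal
  fractions are `0.3`, `(1−e^{−0.3/τ})/(1−e^{−1/τ})` and `1[u0 < 0.3]`.
  On flat layers the spot blur uses reflecting boundaries at the layer
  edges so blur cannot carry mass across the basal boundary and bias the
  depth law the scene is supposed to realize. The curved variant is a
  sinusoidal band of constant thickness whose analytic normal-offset
  depth serves as the oracle for the distance-transform depth field.
  The default 200 spots/scene is an arbitrary but documented choice; the
  tissue literature gives no per-ROI spot-count distribution.
* **Membrane bands.** The ridge is the set of pixels within half the
  line thickness of the continuous membrane polyline (no integer
  quantization before thickening); waveforms flat/sine/square have
  roughness 0, 2A/π, A.
* **Cells.** Disks with uniform, `ρ^p`, or two-zone radial profiles; the
  two-zone profile writes contrast `c` into the same peripheral zone the
  cortical-ratio stage measures, so recovery is exact by construction.
* **Fiber stacks.** Randomly oriented capsules (length ≥ 5× diameter)
  plus spherical debris, placed by rejection sampling (1000 attempts,
  then an error — silent density bias is worse than failure); geometry
  lives in voxel-index space and ground truth records per-object voxel
  counts, so volume recovery is exact up to noise.

The scenes deliberately omit PSF anisotropy, autofluorescence gradients,
segmentation error, and spot clustering. Passing the recovery suites
therefore demonstrates correctness of the measurement operators under
their stated assumptions, not robustness to every property of real
tissue; noise-robustness contracts (additive Gaussian at SNR 5) cover the
first-order deviation only.

## Orchestration and problem sizes

A single pydantic-validated config (unknown keys rejected) carries every
threshold, bin count and seed; runs write a metrics CSV plus a provenance
JSON (config hash, seed, version) sufficient to reproduce any output, and
per-sample failures are isolated and flagged in the table's `status`
column rather than aborting the batch. The metric CSV gains this
`status` column beyond the core six so that excluded ROIs/cells remain
auditable.

Test and demo problem sizes — 10⁵ spots on ~260×220 px layers for
depth-law recovery, 360-px bands, radius 22–50 px cells, 24×96×96 voxel
stacks with 3 fibers and 5 spheres over 5 seeds — were chosen as the
smallest scenes at which discretization error sits comfortably below the
stated tolerances (0.01 per bin, 5% roughness, 5% volume).
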