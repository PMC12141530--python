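# epiquant

Quantification of subcellular mRNA/protein localization and
dermal-epidermal-junction (DEJ) architecture in fluorescence microscopy
images of stratified epithelium.

Many mRNAs in epithelial tissue are not distributed uniformly within
cells: transcripts such as *Net1* concentrate at the basal side of the
basement-membrane (BM)-attached keratinocyte layer, near protrusion-like
structures at the DEJ. Studying this requires turning fluorescence images
into a handful of reproducible per-layer, per-membrane, and per-cell
statistics. `epiquant` implements those statistics as a tested, reusable
Python library for image analysts working on RNAscope/smFISH and
immunofluorescence data of stratified epithelia — together with seeded
synthetic-scene generators whose closed-form ground truth makes every
stage verifiable without any raw microscopy data.

## The metrics

* **Basal mRNA fraction.** The segmented BM-attached layer gets a
  per-pixel normalized depth `u = d_b / (d_b + d_a)` (distance-transform
  ratio to the basal and apical boundaries, 0 = basal, 1 = apical), is
  divided into 10 evenly spaced depth bins, and background-subtracted
  RNA intensity is summed per bin. The basal fraction is the intensity
  share at `u < 0.3`; depth-uniform signal gives exactly 0.30.
* **DEJ variation.** A band ROI (default 120 px wide ≙ 7.8 µm at
  0.065 µm/px) centered on the Itga6-stained basal membrane is
  straightened along its centerline; the membrane is Otsu-thresholded and
  skeletonized, and its per-column offset `y(x)` from the centerline is
  traced. The metric is `mean |y(x)|` in µm over measured columns — the
  image-analysis analogue of average roughness Ra.
* **Cortical ratio.** Mean protein intensity in the peripheral 15% of a
  cell (outer band of the normalized boundary-distance coordinate)
  divided by the mean in the most central 65%.
* **Peripheral distribution index (PDI).** The intensity-weighted second
  moment about the geometric cell centroid, normalized by the same moment
  of a uniform signal: exactly 1 for homogeneous signal, > 1 peripheral,
  < 1 perinuclear.
* **Cumulative fiber volume.** A 3D fibrillin-2 stack is thresholded
  (one threshold per experiment), labeled with 26-connectivity, and
  components that are both small and spherical (`V < V_min` and
  sphericity `ψ = π^{1/3}(6V)^{2/3}/A > ψ_max`) are removed as debris;
  the kept volumes are summed in µm³.
* **ROI statistics.** Epithelial thickness between boundary polylines,
  mean channel intensity over a mask, and double-positive cell density
  per µm of DEJ length.

## Worked example

```python
import epiquant as eq

image, layer, truth = eq.generate_layer_section(
    shape=(260, 220), depth_law="exponential", tau=0.2,
    n_spots=50_000, seed=42,
)
depth = eq.compute_depth_field(layer)
rna = eq.subtract_background(image.channel("rna"), layer.mask, 0.0)
profile = eq.bin_intensity_profile(rna, depth, n_bins=10)
print(eq.basal_mrna_fraction(profile, basal_cutoff=0.3))
```

This prints `0.7805`: 78% of the RNA fluorescence sits in the basal-most
30% of the layer, against the closed-form expectation
`(1 − e^(−1.5))/(1 − e^(−5)) ≈ 0.7821` for a truncated-exponential depth
law with τ = 0.2. The scripts in `examples/` walk through each metric the
same way; `examples/pipeline_demo.py` prints the full
expected-vs-measured table, e.g.

```
            scene          metric  expected  measured
    layer/uniform  basal_fraction  0.300000  0.301465
        band/sine dej_variation_px 6.366198  6.387187
     cell/uniform             pdi  1.000000  1.000000
    cell/two_zone  cortical_ratio  3.000000  3.000000
     stack/fibers cumulative_..um3 1.018000  1.018000
```

A thin CLI mirrors the library (`epiquant simulate | basal-fraction |
dej-variation | cell-metrics | fiber-volume | thickness | roi-intensity |
double-positive | run | demo`); `epiquant run --config cfg.yaml --outdir
out/` executes a sample manifest and writes a metrics CSV plus a
provenance JSON.

## Inputs

TIFF images (single/multi-page; channel-first axis), binary/label masks
(TIFF), polyline ROIs (CSV with `x,y` columns or GeoJSON LineString), and
per-axis pixel/voxel sizes in µm. Coordinates are 0-based pixel centers
with y increasing downward; all reported metrics are in µm/µm³ unless
pixel units are requested. Images are assumed already denoised and
deconvolved upstream.
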