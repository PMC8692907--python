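# vasoquant

Quantitative analysis of skin microvascular networks in
hemoglobin-contrast microscopy images.

Label-free optoacoustic (photoacoustic) microscopy images the dermal
vasculature over centimetre-scale fields at capillary resolution: pulsed
532 nm light absorbed by hemoglobin generates ultrasound, so perfused
vessels appear as bright curvilinear structures on a dark background.
Studies of angiogenesis — for example comparing wild-type skin with
VEGF-A-overexpressing hypervascular skin, or following wound
revascularisation over time — need those images turned into numbers.
`vasoquant` implements the full analysis chain from raw volumes to
group statistics, for imaging scientists and vascular-biology labs.

## The pipeline

For each imaged location:

1. **MIP** — the 3D scan is collapsed by a maximum intensity projection
   along depth.
2. **Hb content** = Σ raw intensity / imaged area (a.u./mm²), computed
   on the *unenhanced* projection so contrast adjustment cannot bias it.
3. **Enhancement** — CLAHE (tile-wise dynamic-range equalisation with a
   clip limit) followed by Gaussian smoothing specified in µm, so scans
   at 5, 20 and 50 µm pitch behave comparably.
4. **Binarization** — Otsu's global threshold by default; a local-mean
   adaptive threshold with adjustable sensitivity is available for
   images where a global threshold fragments dim vessels.
5. **Skeleton graph** — topology-preserving thinning, clustering of
   junction pixels into branch nodes, ordered centerline segments,
   spur pruning, and per-point radii from the Euclidean distance
   transform.
6. **Per-image metrics** —
   * fill fraction (%) = vessel area / imaged area,
   * vessel count = metric-eligible centerline segments,
   * diameter (µm) = 2 × mean centerline radius per segment,
   * tortuosity (°/µm) = Σ |turning angle| / arc length on an
     arc-length-resampled centerline,
   summarised per image as medians across segments.
7. **Group statistics** — per-location or per-mouse medians compared
   between groups with an unpaired two-tailed t-test (Student's pooled
   variance by default, Welch optional), reported as mean ± SD, fold
   change and p-value.

Because no public dataset accompanies this kind of instrument, the
package ships a first-class synthetic phantom generator
(`vasoquant.phantom`) producing vascular images with exact analytic
ground truth (centerlines, widths, tortuosity, fill), used throughout
the test suite and the acceptance script.

## Worked example

Generate two phantom cohorts (3 sparse "WT-like" and 3 dense, tortuous
"VEGF-like" images) and run the full pipeline:

```bash
vasoquant generate --out-dir demo --n-per-group 3 --seed 7
vasoquant run --manifest demo/manifest.csv --out-dir demo_out
```

which prints (group **a** = `vegf_like`, group **b** = `wt_like`;
fold change = mean_b / mean_a):

```
analyzed 6 images (0 failed) -> demo_out/report.json
                   parameter  mean_a   sd_a  mean_b   sd_b   p_value  fold_change
       hb_content_au_per_mm2    9124  118.6    6584  210.8 5.365e-05       0.7215
           fill_fraction_pct    20.5 0.7666   11.02  0.848 0.0001365       0.5374
                vessel_count   138.3  4.619   20.67  9.018 3.606e-05       0.1494
          median_diameter_um   23.13  2.205   33.72  2.066  0.003717        1.458
median_tortuosity_deg_per_um   1.926 0.1201   1.656 0.1598   0.07986       0.8601
```

Reading the table: the dense cohort has ~1.9× the fill fraction
(20.5 % vs 11.0 %, p ≈ 1e-4), far more distinct vessel segments,
narrower vessels (23 vs 34 µm) and higher centerline tortuosity —
the direction and rough magnitude of every generated contrast is
recovered by the pipeline. `demo_out/` also contains per-image and
per-segment CSVs, binary masks, centerline/branch-point/edge overlay
TIFFs, and a JSON run report embedding the full configuration.

Real data enter the same way: a manifest CSV with columns
`path,group,mouse,location,pixel_size_um,modality` pointing at
grayscale TIFF stacks (`lsom`) or 2D images (`whole_mount`; Hb content
is skipped for fluorescence data). The library API mirrors the CLI:

```python
from vasoquant import (read_volume, compute_mip, enhance, binarize,
                       skeletonize_mask, build_graph, summarize_image)

vol   = read_volume("scan.tif", lateral_spacing_um=20, axial_spacing_um=50)
mip   = compute_mip(vol)
mask  = binarize(enhance(mip))
graph = build_graph(skeletonize_mask(mask), mask)
record = summarize_image(graph, mask, raw=mip)
```

## Documentation

`docs/methods.md` describes the model and estimator choices, the
phantom's design and its limits, parameter defaults with units, and
known limitations.
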