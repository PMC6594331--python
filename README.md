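# leukoseg

Quick white-blood-cell (leukocyte) nucleus segmentation for stained
blood-smear micrographs, built around a single cheap statistic: the
saturated per-pixel difference between the blue and green channels
(**B−G**) of an 8-bit RGB image.

In Wright–Giemsa-stained smears, dyed nuclei and platelets carry B−G values
above ~110 while erythrocytes, background, pale cytoplasm and dye
precipitate ("stains") stay below ~50, so a *fixed* empirical threshold
T0 ∈ [50, 100] separates nuclear material with one 8-bit subtraction and no
per-image threshold search. The full method is:

1. extract B and G, compute the saturated difference `max(B − G, 0)`;
2. binarize at the fixed threshold T0 (inclusive, default 80);
3. remove platelets by size filtering (components < `min_nucleus_area_px`);
4. label connected regions;
5. group lobes of multilobed nuclei: regions with area ≤ S0 merge when their
   centroids lie within D0 of each other (single-linkage closure); bigger
   regions are whole nuclei on their own;
6. localize each nucleus by projecting its mask onto the axes (nonzero
   extents of the column/row projections give the closed bounding box,
   integer midpoint gives the center);
7. reject nucleus-colored artifacts: cytoplasm is segmented from
   Otsu-thresholded saturation and blue channels around the nucleus, and an
   object whose cytoplasm/nucleus area ratio is **smaller than 0.26** is
   flagged as an artifact (flagged, not deleted — counting honors the flag).

An Otsu-based saturation-and-blue (SAB) comparator, a detection/count
evaluator, and a synthetic smear generator with exact ground truth make
every stage testable without real micrographs.

## Coordinate & box conventions

`x` is the column index, `y` the row index, both 0-based, `y` grows
downward. Bounding boxes are **closed** (`x_l..x_r`, `y_t..y_b` inclusive),
so `w = x_r − x_l` is 0 for a single column; `x_c = (x_l + x_r) // 2`.

## CLI

```sh
# generate synthetic scenes with ground truth
leukoseg synth --n 3 --seed 1 --leukocytes 5 --out scenes/

# segment one image (B-G method; --method sab selects the comparator)
leukoseg segment scenes/scene_000.png --out dets.csv --debug debug/

# segment many images
leukoseg batch scenes/*.png --out-dir results/

# score detections against ground truth
leukoseg evaluate --truth scenes/scene_000_truth.json --detections dets.csv

# differential count from a type-label column
leukoseg count --labels labels.csv

# parameter-spanning scene gallery with manifest
leukoseg gallery --out gallery/ --n 10 --seed 0
```

Parameters load from a flat YAML/JSON config (unknown keys are rejected):

```yaml
t0: 80                  # B-G threshold, compliant band [50, 100]
min_nucleus_area_px: 500
connectivity: 8
s0_px: 2500             # max lobe area
d0_px: 60               # max lobe centroid distance
ratio_min: 0.26         # cytoplasm/nucleus artifact floor (strict)
roi_margin_factor: 2.0
cyto_method: sb_union   # or sb_intersection
method: bg              # or sab
```

Defaults are tuned to a nominal 1024×768 capture; area/distance parameters
are scale-dependent.

## Layout

| module | contents |
| --- | --- |
| `leukoseg.bg_core` | difference map, binarization, labeling, size filter |
| `leukoseg.grouping` | region extraction, lobe grouping, projection bbox |
| `leukoseg.artifact_filter` | saturation, cytoplasm segmentation, ratio rule |
| `leukoseg.sab_baseline` | exact Otsu, SAB comparator |
| `leukoseg.smearsim` | synthetic scene generator + ground truth + gallery |
| `leukoseg.eval_count` | matching, accuracy, differential counts, pixel F1 |
| `leukoseg.image_io` | PNG/TIFF/BMP/JPEG input, mask/detection serialization |
| `leukoseg.pipeline` / `leukoseg.cli` | orchestration, config, CLI |
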