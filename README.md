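# autoroot

Fully automated, threshold-free phenotyping of plant root systems in
multi-well growth-plate images.

Seedlings grown in transparent, agar-filled multi-well strips develop
essentially two-dimensional root systems that can be photographed from the
side by a robotic imaging platform. Classical image analysis would
binarise such images — every pixel declared root or background by an
intensity threshold — which is brittle for thin, dim lateral roots and
bright noise. This package instead assigns every pixel a *likelihood* of
being root material and measures all traits as likelihood-weighted image
statistics, so no hard classification is ever made. It is aimed at
high-throughput screening: whole directories of plate images are processed
unattended into one CSV of per-well trait records.

## Method

For each well (a fixed pixel rectangle supplied by configuration, since
plates are positioned robotically):

1. The grayscale image is contrast-stretched by one fixed `(low, high)`
   range per batch onto 0–255.
2. **Seed points** — per-row local intensity maxima in the top 5% strip of
   the well, where seeds are always sown — act as sources.
3. The well becomes an 8-connected pixel graph with edge weights

       w(p, q) = 1 − α · I(p) · I(q),   α = 1 (orthogonal), √2 (diagonal)

   where `I ∈ [0, 1]` is normalised intensity, so travel across pairs of
   bright (root-like) pixels is nearly free and travel over background
   costs ≈ 1 per step. A multi-source Dijkstra search gives every pixel
   the cheapest path cost `d(x, y)` from any seed point.
4. The **likelihood map** is

       L(x, y) = (1 − d(x, y) / d_max)^n,   clamped to [0, 1]

   with `n = 1` by default. Bright specks disconnected from the root score
   low automatically: every path to them crosses background.
5. **Proxy traits** per well: likelihood-weighted centroid and mass;
   bounding extremities `argmax L·x` (and mirrored/vertical analogues);
   boxes enclosing 95%/99% of likelihood; mass in four stacked depth bands
   Q0–Q3; likelihood mass in ten orientation brackets from 0° (horizontal
   material) to 90° (vertical), from Sobel gradients; the 4×4
   quadrant-orientation cross; and, from paired top-down images, leaf area
   (pixels with HSV saturation > 20%) and circular mean leaf hue.

Traits are in pixel units ("arbitrary units"); they are *proxies* meant to
correlate with classical measures (proxy-depth with root length, oblique
orientation mass with lateral spread), which is sufficient for screening
comparisons between treatments.

## Worked example

No image set ships with the package; the `autoroot.synthetic` module
generates wells with known ground truth. `examples/02_trait_extraction.py`
builds one well and prints its record:

```
true primary length 400 px, 4 laterals, true max depth 406 px

centroid        (145.2, 291.2)  likelihood-weighted centre of mass
mass            145763  total likelihood (per-pixel 0.708)
width/depth (M) 249 / 404 px  extremities scored by L x position
width/depth p95 274 / 585 px  box enclosing 95% of likelihood
depth p99       654 px
quadrant mass   Q0=44560  Q1=45770  Q2=40327  Q3=15106  (four stacked bands, top to bottom)
orientation     oblique brackets 3-5 2958, vertical brackets 8-9 2757 (0 deg = horizontal material, 90 deg = vertical)
```

The proxy depth (404 px) tracks the true tip depth (406 px); the mass is
dominated by the smooth background likelihood field, which is why traits
are interpreted comparatively, not absolutely. The other examples build a
likelihood heat map and separate a control from a growth-inhibited
population with a two-sample test and a 2-component PCA.

## Command line

```
autoroot fixtures --out demo --n-plates 3 --seed 1   # synthetic dataset + config
autoroot run --config demo/config.yaml               # batch -> demo/traits.csv
autoroot heatmap demo/plate_000.png --config demo/config.yaml
```

`autoroot run` processes every image matching the configured glob in
lexicographic order, never prompts, quarantines unreadable images, and
writes the CSV atomically (one row per well, fixed column order:
`image_id, well_index, empty_flag, centroid_x, centroid_y, mass,
mass_norm, width_m, depth_m, width_p95, depth_p95, depth_p99, q0_mass …
q3_mass, orient_0 … orient_9, q0_orient_0 … q3_orient_3, leaf_area,
leaf_hue`). Wells with no detectable seed points yield flagged all-zero
rows. See `src/autoroot/config.py` for the YAML schema.

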