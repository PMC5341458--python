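# Methods

## Model

The method treats root detection as a connectivity problem rather than a
classification problem. Its assumptions are:

- plants grow from seeds sown in a known thin strip at the top of each
  well, so candidate root origins can be found there as per-row local
  intensity maxima;
- root material is brighter than the agar background under fixed
  illumination, so a fixed contrast-stretch range per batch is enough to
  normalise intensities;
- root systems are connected to their origin, so the cheapest path from an
  origin to a root pixel runs along root material, while any path to a
  bright noise speck must cross background.

Each well is an 8-connected pixel graph with edge weights
`w(p,q) = 1 − α·I(p)·I(q)` (`α = 1` orthogonal, `√2` diagonal, accounting
for centre-to-centre distance). A multi-source Dijkstra search from all
seed points yields per-pixel costs `d`, and the likelihood map is
`L = (1 − d/d_max)^n` clamped to `[0, 1]`. All traits are L-weighted image
statistics.

### Negative diagonal weights

The raw weight formula goes negative for diagonal steps between very
bright pixels (`I(p)·I(q) > 1/√2`), which would break Dijkstra's
non-negativity precondition. The default resolves this by clamping at
zero — travel through saturated root material is free, which is consistent
with the formula's own orthogonal limit `w(1,1) = 0`. An alternative
reading `w = α·(1 − I(p)·I(q))`, non-negative by construction and
identical for orthogonal steps, is available as `weight_mode: scaled` for
experimentation. The weight product is grouped as `α·(I(p)·I(q))` so the
two directions of an edge are bitwise identical.

### Normalisation of the likelihood map

Two modes for `d_max`:

- `theoretical` (default): `height + width`, an upper bound on any path
  cost (every pixel is reachable in at most H+W steps of cost ≤ 1). It is
  deterministic per image and needs one pass.
- `empirical`: the mean of per-well maximum observed distances over the
  batch, computed in a first pass. This is the calibration appropriate for
  *population* studies, where all wells must share one scale.

The choice matters more than it first appears. In a sparse well the
background likelihood decays linearly below the root tip at rate
`1/d_max` per row, so the depth-(M) score `L·y` of a background pixel at
depth `y` peaks near `(d_max + tip)/2`. With a large `d_max` the argmax
therefore sits *below* the tip and saturates toward the bottom of tall
wells; with the batch-empirical `d_max` the peak stays an affine, strictly
monotone function of true tip depth, which preserves rank order and
correlation even when the argmax is a background pixel. The package's
population validations consequently run with the empirical normalisation;
single-well diagnostics may use the per-well observed maximum, which
pins depth (M) to the tip itself. The 95%/99% boxes and the centroid are
insensitive to this choice.

### Trait conventions

- Depth (M) is the row of the bottom extremity (`argmax L·y`), i.e. the
  distance grown from the top of the well — the proxy for root length.
  The left/top extremities use mirrored coordinates (`W−1−x`, `H−1−y`).
  Argmax ties break toward the smallest row-major pixel index.
- The 95%/99% boxes take depth one-sided from the top (roots grow
  downward from seeds at the top); the width trims `(1−f)/2` of mass from
  each side of the column marginal. Quantile boundaries carry a relative
  slack of 1e-9 so exact fractions are not missed to rounding.
- Quadrant bands are `H//4` rows tall; remainder rows join the bottom
  band (deterministic, documented).
- The orientation at a pixel is the *structure* angle: the complement
  `90° − φ` of the Sobel gradient direction `φ = atan2(|Gy|, |Gx|)`, so
  vertical root material scores 90° and horizontal material 0°. The raw
  gradient direction is perpendicular to a line's axis; reporting it
  uncomplemented would label vertical roots "horizontal". Pixels with zero
  gradient magnitude have no orientation and contribute to no bracket
  (assigning them to bracket 0 would let flat background dominate).
  Brackets are half-open, the last closed at 90°; only likelihood weights
  are used, not gradient magnitude.
- Leaf pixels are HSV saturation strictly above 0.20 of full scale; leaf
  hue is a circular mean (an arithmetic mean would average the red hues
  10° and 350° to cyan).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| strip_fraction | 0.05 | of well height | seed-search strip; seeds are sown above this line |
| seed min_intensity | 0.2 | normalised intensity | suppresses seeding on background noise in empty wells; 0 restores plain local maxima |
| stretch (low, high) | per batch | 8-bit counts | fixed once per batch under constant lighting |
| exponent n | 1 | – | sharpens L when > 1; little effect on comparative results |
| norm_max_mode | theoretical | – | see above |
| weight_mode | clamped | – | see above |
| orientation brackets | 10 (and 4×4) | over [0°, 90°] | equal width |
| saturation threshold | 0.20 | fraction | leaf mask, strict inequality |

## Implementation notes

The Dijkstra kernel is a numba-compiled array binary heap with lazy
deletion; the priority is the pair (distance, row-major pixel index), so
expansion order — and with it every output — is reproducible across runs
and platforms. Each node relaxes at most eight times, bounding the heap at
8N entries. The kernel is cross-checked in the test suite against a
networkx shortest-path oracle on random grids, where agreement is exact
(bitwise), not approximate. Seed plateaus (runs of equal maximal
intensity) contribute their centre pixel; border pixels compare against
their single existing neighbour.

Empty wells — no local maximum above the seed threshold in the strip —
produce flagged all-zero trait rows rather than aborting a batch. The
batch CSV is written atomically (temporary file, then rename) and reruns
are byte-identical. The empirical-normalisation mode costs a second pass
over the batch, recomputing distances rather than caching 200k-pixel maps
per well.

## Synthetic data

`autoroot.synthetic` generates the study conditions for all validation:
wells of 290×710 px (the acquisition geometry the method targets) with a
sinuous primary root (arc-length parametrised, wavelength 300 px) starting
inside the top strip from a bright seed blob, straight oblique laterals
(35–65° from vertical, 50–120 px) branching below 20% of the primary's
extent, a Gaussian-blurred stroke cross-section (half-width 2 px) to
emulate out-of-focus agar imaging, background 20 and root 200 on the 8-bit
scale, additive Gaussian noise (σ = 6) and sparse bright salt speckle
(density 5·10⁻⁴) at root intensity. Sharp binary strokes and zero noise
are options for exact-mask tests. Top-down rosettes are saturated discs of
one hue on white. Two population conditions emulate an osmotic-stress
growth-inhibition experiment: control (primary 350–650 px, 2–7 laterals)
versus inhibited (120–320 px, 0–3 laterals).

What the generator does *not* emulate: reflections and meniscus artefacts
at well walls, root-hair halos, overlapping plants within a well,
illumination gradients, condensation droplets, or curved/occluded laterals.
Passing validations therefore demonstrate the pipeline's correctness and
its behaviour under idealised noise, not robustness to every real imaging
artefact; on real plates the stretch bounds and the seed threshold are the
knobs that absorb most of the difference.

Validation problem sizes: 200 random grids (10–20 px square) for the
oracle check; 200 wells with true lengths uniform in [100, 600] px for
proxy validity; two populations of 100 wells for condition separation;
20 fixtures for noise suppression; 23 plates of 8 wells (120×260 px) for
the batch contract.

## Known limitations

- Depth (M) is the noisiest depth proxy (see the normalisation discussion
  above); the 95%/99% boxes and centroid-Y are the stabler length proxies.
- The mass trait is dominated by the smooth background likelihood field;
  it is meaningful comparatively (same well geometry, same normalisation),
  not absolutely, and is also reported per-pixel as `mass_norm`.
- Wells are analysed independently; plants are not separated within a
  well, and no root topology (individual root paths, branch points) is
  extracted.
- Bright noise close to the root system, or inside the seed strip, is not
  suppressed — a strip speck is indistinguishable from a true seed by
  construction.
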