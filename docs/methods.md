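# Methods

## The measurement problem

An exclusion-zone migration assay reports how fast a confluent monolayer
repopulates a circular cell-free zone of nominal diameter 5 mm stamped by a
well-plate insert. The raw data are per-well brightfield time-lapse frames
(24-bit RGB TIFF, pixel scale 0.3525 px/µm, 3 h cadence over 96 h). The
quantity of interest is the percent cell-free area
`%A(t) = 100 · A(t) / A(t₀)` per well, compared across treatments.

## Segmentation chain

Brightfield monolayers are edge-rich (cell borders) while the cell-free
zone is smooth; the chain classifies *smoothness*, not intensity:

1. **Grayscale**: unweighted channel mean, `(r + g + b) // 3` (integer
   truncation). No luminance weighting — the chain is calibrated against the
   plain average.
2. **Crop**: centred square, side = `crop_fraction` × the shorter image
   side (default 0.8). The crop focuses the histogram on the zone and its
   surrounding monolayer so the threshold is not dominated by well-edge
   artefacts.
3. **Edges**: 3×3 Sobel gradient magnitude √(Gx²+Gy²), replicated-edge
   border convention (no spurious frame response), clipped to [0, 255] and
   truncated to 8 bit.
4. **Threshold**: Kapur maximum-entropy split of the 256-bin edge
   histogram — the T maximising H_low(T) + H_high(T), the Shannon entropies
   of the two class distributions each renormalised by its class
   probability. Candidates that leave a class empty are skipped. ψ(T) is
   constant between occupied bins, so the scan visits occupied bins only;
   this simultaneously implements the lowest-T tie rule exactly and avoids
   floating-point ties across empty histogram gaps. Degenerate histograms
   (< 2 occupied bins) raise; the batch pipeline downgrades this to a
   zero-area frame with a warning.
5. **Binarise**: pixels above threshold are edge/cell pixels; the mask is
   complemented so that **foreground = cell-free** throughout the package.
   The original interactive workflow expressed the same polarity by a
   display-level LUT inversion; making it an explicit complement removes
   hidden state from the morphology that follows.
6. **Morphology**: one binary erosion with the full 3×3 structuring
   element (border pixels treated as background-adjacent), then hole
   filling (background components not 4-connected to the border become
   foreground). Erosion severs thin bridges between the zone and smooth
   intra-monolayer pockets; filling recovers debris-induced holes inside
   the zone.
7. **Particle filter**: 8-connected components are calibrated as
   `count / scale²` µm² and kept if within [10⁵, 7·10⁸] µm², i.e.
   0.1–700 mm². The bounds are interpreted in calibrated µm² (≈12.4 kpx
   minimum at 0.3525 px/µm): only calibrated units make the bounds
   physically meaningful. Surviving components are unioned, not reduced to
   the largest, matching particle-analysis summation.

The chain is deterministic: identical input bytes give identical results.

## Kinetics and statistics

Percent area normalises each well to **its own first frame** — not to the
theoretical 19.6 mm² — because inhibitor wells legitimately exceed 100 %
(zone growth through margin cell death), which only self-normalisation can
represent. Values are not clamped.

Aggregation reports mean, sample SD (n−1) and SEM per (treatment, time).
The test battery mirrors a standard assay analysis:

* paired t-test (closed form on differences, p from Student t);
* one-way ANOVA (closed-form sums of squares);
* balanced two-way treatment × time ANOVA with interaction, computed from
  the classical balanced decomposition. Degenerate layouts are guarded
  explicitly: a zero effect mean-square gives F = 0, p = 1; a zero residual
  mean-square with a non-zero effect gives F = ∞, p = 0 (regression-based
  routes return NaN here). Sums of squares below 1e−12 of the total are
  snapped to zero so these guards fire despite floating-point residue.
  Unbalanced layouts raise — the implementation is deliberately
  balanced-only.

Post-hoc comparisons: at every timepoint, every treatment pair is tested
with the pooled residual mean square of the two-way fit (df = ab(r−1)) and
corrected over the whole family (all pairs × all timepoints) by the Šidák
rule `p_adj = 1 − (1 − p)^m` (Bonferroni available). The pooled error term
keeps single-timepoint comparisons stable at triplicate sample sizes; the
family-wide correction is the conservative reading of "multiple
comparisons" for this design. α = 0.05 throughout.

## Cell tracking

Velocity analysis consumes per-frame centroid lists (µm); image-based cell
detection is intentionally out of scope, keeping the velocity estimate
honest and testable. Linking is greedy nearest-neighbour per frame pair
with a maximum-displacement gate (candidate pairs in ascending distance,
each track/detection used once; unmatched tracks end, unmatched detections
start new tracks). For well-separated cells this equals the optimal
bipartite assignment, which the tests verify.

**Average cell velocity** is path length / elapsed time per track,
averaged over tracks (mean ± sample SD); the net-displacement variant is
exposed as well. Positional jitter inflates path-length speed upward by
construction; with per-step jitter ≤ 20 % of the per-step displacement the
bias stays below 10 %.

## Synthetic assay generator

The simulator emulates the assay's raw data with exact ground truth:

* **Monolayer texture**: seeded jittered-grid Voronoi mosaic. Each grid
  cell of side one `texture_cell_diameter_um` (default 30 µm, an epithelial
  cell size) owns one seed; per-pixel nearest/second-nearest seed distances
  give per-cell shading and bright boundary lines — the edge-rich
  appearance that drives the Sobel + threshold chain on real data.
* **Zone**: smooth low-intensity disc of radius
  `r(t) = max(0, r₀ − v · max(0, t − lag))`. `v` is the signed front
  velocity (µm/h, positive = closure); `lag_h` (default 0) delays front
  motion. The front is blended over a soft ramp of width 2 cell diameters
  centred on r(t), so segmentation accuracy is realistic rather than
  artificially perfect.
* **Nuisance terms**: bright Gaussian debris specks inside the zone
  (default 2 /mm², ~3 µm σ — far below the size-filter minimum), a lateral
  illumination ramp (default ±5 %), additive Gaussian pixel noise (default
  σ = 2 on the 8-bit scale). All randomness derives from the single
  `rng_seed`; identical configs render bit-identically.
* **Truth channel**: the mask is exactly the disc of radius r(t) (empty
  once fully closed); truth areas are pixel counts / scale², the same
  calibration the measurement uses, so truth and measurement are directly
  comparable. Simulated tracks move along fixed random headings at
  `speed · interval` per step plus isotropic jitter.

**Treatment presets** map the five assay conditions to front kinetics with
a 24 h response lag — treated monolayers show no significant area change in
the first day — and velocities chosen so a well reaches the characteristic
96 h endpoint percentages: DMEM 88.8 %, FBS 78.1 %, EGF 48.9 %,
colchicine 103.3 %, doxorubicin 110.7 % (promoters positive v, inhibitors
negative). For scaled-down zones the velocity is rederived from the
endpoint so the percent trajectory is preserved. Preset single-cell speeds
for track simulation are 0.15 / 0.52 / 0.69 / 0.04 / 0.05 µm/h
respectively. The statistical-emulation table generator perturbs truth
areas with 4 % multiplicative measurement noise, matching the few-percent
replicate scatter typical of the assay.

The simulator does **not** model phase-contrast optics, cell division or
apoptosis, front roughness/fingering, or drift; passing its tests shows the
measurement chain is correct and calibrated, not that it is robust to every
artefact of real microscopes.

## Geometry defaults

`image_margin_mm` defaults to 1.0: the rendered field (zone + 2 × margin =
7 mm at default) must keep the full zone inside the default 0.8 centred
crop (5.6 mm > 5 mm) with a visible monolayer ring. The insert model
defaults to the reference design (16 mm plus top × 3 mm, 9 mm body × 10 mm,
5 mm foot × 4 mm → 17 mm stack, 19.63 mm² zone); the plus-shaped cross
section itself is not modelled, only its span, as it affects no computation
here.

## Problem sizes in the test suite

Unit tests run on a scaled-down well (1.5 mm zone, 0.4 mm margin) where a
render is ~0.8 Mpx; at that zone radius the soft front ramp is a larger
relative fraction, so area tolerances in those tests scale with
ramp-width / zone-radius. Calibration and kinetics-fidelity tests run at
full scale (5 mm zone, 0.3525 px/µm, 33 frames; ~6 Mpx per frame). The
end-to-end plate test uses 5 treatments × 3 replicates × 9 frames on a
2.5 mm zone following the same percent trajectories. Threshold correctness
is checked against a brute-force oracle on 1000 random histograms; the
statistics against hand decompositions and scipy/statsmodels references at
1e−9.

## Known limitations

* The size filter and calibration assume a single global pixel scale; mixed
  magnifications within one batch are not supported (by design — one shared
  parameter set per batch protects comparability).
* Percent-area measurement error grows as the zone shrinks (perimeter
  effects); near closure the reported percent is noisier.
* The greedy linker has no gap closing or division handling; it is meant
  for sparse, well-separated cells.
* The two-way ANOVA is balanced-only; drop-outs must be handled upstream.
* Path-length velocity is jitter-biased upward (quantified above); prefer
  the net-displacement variant for heavily jittered data.
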