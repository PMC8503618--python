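# Methods

This note documents the models, parameter choices and numerical
decisions behind `afpathways`, and what the synthetic validation does
and does not demonstrate.

## Signal model and processing chain

A unipolar electrogram marks local activation by a steep negative
deflection; its rectified, band-limited derivative therefore peaks at
activation. The chain is: QRS template subtraction → first difference
→ zero-phase Butterworth band-pass (order 3, 40–250 Hz) → full-wave
rectification → zero-phase low-pass (order 3, 20 Hz) → per-channel
min–max normalization to [0, 1] over the analysis window. This is the
standard pre-processing used before dominant-frequency analysis; the
exact cutoffs are configurable (`AnalysisConfig.bandpass_hz`,
`lowpass_hz`) because published descriptions of the chain leave them
open. Filters are zero-phase (forward–backward) by design: causal
filtering would delay activation peaks and bias every downstream flow
direction estimate.

Consequences worth knowing:

- A pure low-frequency sinusoid (e.g. 5 Hz) has no in-band derivative
  content and is attenuated to the flat-channel guard
  (`flat_range_eps = 1e-9`); only signals with sharp deflections
  survive, which is the intent.
- Forward–backward filtering leaves edge transients; activation peaks
  are therefore only accepted 100 ms away from the window boundaries.
- The 20 Hz low-pass rings at roughly 40% of the activation peak, so
  peak detection requires height ≥ 0.5 (`peak_min_height`) on the
  normalized signal, plus 50 ms minimum separation — below the
  shortest plausible AF cycle length (~100 ms), above the pulse width.

QRS subtraction averages ±60 ms windows around the supplied QRS times
per channel and subtracts the template at each occurrence; with fewer
than two complete windows the recording passes through unchanged. An
optional detector picks QRS times from the cross-channel mean (the
far-field is common-mode); it is off by default because synthetic
scenes carry explicit artifact times.

## Grid, valve duplication, interpolation

Rows of the anatomical grid are splines ordered top (anterior mitral
valve) to bottom, columns are the eight electrodes along each spline;
for the left atrium, left = lateral / left PV, right = septal /
right PV. The valve-adjacent spline is duplicated on the opposite edge
(9×8) so propagation across the valve annulus is representable; this
requires the valve spline to be first in `spline_order`, which is
validated. Interpolation inserts two points per gap (9×8 → 25×22) by
bilinear weights that are exact unit vectors at original nodes, so node
values are preserved to machine precision. When electrodes are out of
contact, interpolation is linear over the Delaunay triangulation of the
remaining valid nodes and pixels outside their convex hull are marked
invalid — regions without support are excluded rather than inpainted.

## Optical flow

Classical Horn–Schunck: 4-point forward-cube derivative stencils
(edge-replicated), Jacobi iterations from zero initialization with the
standard 8-neighbour averaging kernel. Invalid pixels are excluded
from the neighbourhood averages by renormalizing the weights over the
valid in-bounds neighbours (the same no-flux treatment applies at grid
edges), and carry zero flow. Defaults `hs_alpha = 1.0`,
`hs_iters = 100` follow the original method's regime; both are
configuration, and the regularized magnitude under-estimates true
displacement (≈0.4–0.8 of a 1 px shift depending on iteration count),
which is immaterial here because the PV metric compares magnitudes to
the array mean, a scale-free rule.

Flow is computed between consecutive "lattice" frames at
t = k · 40 samples inside the window: a 10 s window at 2034.5 Hz gives
⌊10·2034.5/40⌋ = 508 analyzed frames and 507 flow fields.

## Wavefront averaging

Per analyzed frame the wavefront is the boundary pixel set of the
super-level region nd ≥ 0.9 (4-neighbour erosion; the grid border and
invalid regions do not generate boundaries), restricted to the
depolarizing side by the sign of the temporal derivative, and filtered
to 8-connected components of more than three pixels. Flow vectors at
wavefront pixels are vector-summed over the window and divided by the
number of analyzed frame pairs — not by the per-pixel contribution
count — so that rarely-activated or direction-cancelling pixels end up
with small averaged vectors. Only relative magnitudes matter
downstream (the tagging rule is invariant to a global scale), so the
choice of normalization affects presentation, not the metric.

## Streamlines

Seeds are the centroids of the Delaunay triangles over valid grid
nodes (2(n−1)(m−1) on a full n×m grid). Tracing is fixed-step Euler
(0.25 px) on the normalized field direction, forward then backward; a
branch stops on leaving the valid region, on field magnitude below
1e−6 of the field maximum, or when the turn between consecutive steps
exceeds 0.7 rad; length is capped at 4 grid diagonals. The displayed
set is built greedily by decreasing arc length (ties broken by seed
id, making selection deterministic and order-independent) subject to a
0.5 px minimum distance from all previously retained lines, checked
point-to-point at the ≤0.25 px sampling of the polylines. One caveat:
with 0.25 px steps a genuinely discontinuous 90° corner is smeared by
bilinear sampling over ~1 px, i.e. ~0.4 rad per step, below the
per-step-pair criterion; the angular stop is meaningful at the default
step for curvature concentrated within a step, and tests of the corner
behaviour use a 1 px step so the whole turn falls in one step pair.

## PV activation flow metric

Boxes default to the outermost 20% of columns on each side and the
middle 60% of rows of the interpolated grid (25×22 → cols 0–3 / 18–21,
rows 5–19); the inward direction points toward the grid centre along
the column axis. A box pixel is tagged when its averaged-flow
magnitude exceeds the mean magnitude over all valid pixels of the
whole array *and* its direction is within ±45° of inward. Each box
uses its own valid-pixel denominator (a pooled-denominator variant is
available behind `pooled_box_denominator`) because the headline metric
is the *maximum* of the two boxes, which is only meaningful per-box.

## Statistics

Group comparison uses the Wilcoxon rank-sum (Mann–Whitney U) test:
the responder and non-responder groups are independent samples of
unequal size, for which the signed-rank test is undefined. AUC is the
normalized U statistic (ties count half). The operating point for
sensitivity/specificity is the Youden-optimal threshold and is always
reported alongside, since no canonical threshold exists.

## Synthetic scenes: what they emulate, and what they do not

Scenes are kinematic: each driver prescribes a closed-form
activation-time map (planar: projection/speed; focal: radial distance/
speed; rotor: uniformly advancing angular phase plus radial delay —
an Archimedean spiral; multiwavelet: Poisson-seeded short-lived local
focal bursts, lifetime two periods), rendered as unit Gaussian pulses
(10 ms SD) in nd-space or as biphasic deflections (difference of 5 and
8 ms Gaussians, negative lobe dominant) in electrogram-space, with
additive Gaussian noise, optional common-mode QRS artifact, and
optional conduction heterogeneity: a frozen per-pixel delay field
(fibrosis stand-in) and beat-to-beat timing jitter (cycle-length
variability). Defaults: 8×8 grid, 2034.5 Hz, AF periods 160–200 ms,
conduction 0.10 px/ms ≈ 0.7 m/s at a 7 mm electrode pitch.

Two geometric facts shaped the conditions:

- *Spatial resolvability.* The rendered wavefront's spatial width is
  conduction speed × pulse width. Below ~0.08 px/ms the 0.9 isoline of
  an oblique front falls between electrodes, every leading-edge
  component is under four pixels, and the detector correctly reports
  nothing — an instrument-resolution limit, not an algorithm failure.
  Speeds are therefore kept in the physiological 0.08–0.12 px/ms range
  where the array resolves the front, as clinical baskets do.
- *PV drivers live behind the grid edge.* An Archimedean spiral is
  radially propagating only beyond v·T/2π ≈ 3 px of its core; a point
  rotor centred inside a PV box floods it with tangential flow. The
  clinical picture — re-entry *around* a vein whose centre lies beyond
  the mapped patch — is modelled by placing responder driver origins
  2–3.5 px behind the grid edge (the generator accepts a 4 px
  off-patch margin). PV triggers (paced vein) use the same entry
  geometry.

The synthetic cohort (`make_cohort`) pairs 20 PV-driven scenes
(alternating focal triggers and vein re-entry, left/right side, jittered
period/origin/chirality, with 4 ms delay noise and 8 ms cycle jitter)
against 20 non-PV scenes (central rotors and multiwavelet). Under
these conditions PV-driven scenes score ~20–60% on the metric and
non-PV scenes ~0%, a cleaner separation than clinical data shows —
the generator has no wavebreak, no anisotropy, no 3D-to-2D projection
distortion, and no electrode motion. Passing the cohort tests
demonstrates that the *pipeline* orders driver geometries correctly
and degrades as expected under dropout; it does not certify clinical
effect sizes, thresholds, or performance on real recordings.

## Numerical and degenerate-input choices

- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); every stage is bit-reproducible.
- Flat channels (range < 1e−9) get nd ≡ 0 and no peaks; all-invalid
  grids, empty groups, windows shorter than the filter warm-up (1 s),
  and increments spanning the whole movie raise errors rather than
  guessing.
- A zero averaged field yields a 0% metric (nothing exceeds the mean);
  a box with no valid pixels yields NaN for that box and the metric
  falls back to the other; both boxes empty is an error.
- Problem sizes in the test and acceptance runs (10 s windows, 20+20
  cohorts, 10-window sweeps, 3 dropout seed batches) were chosen as
  the smallest sizes at which the statistical assertions are stable.

## Known limitations

- Kinematic waves cannot exhibit conduction block, wavefront collision
  dynamics, or restitution; heterogeneity is purely a timing
  perturbation.
- The 9×8 valve duplication assumes spline adjacency across the valve;
  for a flat synthetic patch the duplicated row introduces a seam that
  mildly inflates the array-mean magnitude threshold (it affects both
  grids of the 9×8-vs-8×8 comparison and both cohort groups equally).
- Streamline spacing at 0.5 px yields dense sets on smooth fields;
  the "desired spacing" of the visualisation is exposed as
  `min_streamline_spacing_px` rather than fixed.
- The Horn–Schunck α and iteration count are not identifiable from the
  method description this package follows; sensitivity to them is best
  explored through `AnalysisConfig` rather than trusted as canonical.
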