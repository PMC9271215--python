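# Methods

This note records the models, numerical choices, and open design
decisions behind each module, and what the synthetic-data validation
does and does not demonstrate about real imaging data.

## Image model and preprocessing

Input volumes are two-channel fluorescence stacks: a signal channel in
which dye-filled vessels are bright tubes, and a background channel that
carries the same autofluorescent tissue structure without vessels.
Channel subtraction (clamped at zero — negative fluorescence is
non-physical) removes the shared background; the result is resampled to
isotropic 1 μm voxels by cubic spline interpolation before any
morphological step, since 3D thinning assumes isotropic connectivity.

Binarization marks a voxel as vessel when either

* (a) its intensity ≥ 6 × m, or
* (b) its intensity minus a circular 35th-percentile ranking filter
  ≥ 2.4 × m,

where m is the *non-empty-space mean*.  "Non-empty" is defined here as
voxels above 1 % of the volume's 99.9th-percentile intensity — a cheap
tissue mask that excludes the empty imaging space around the sample and
makes m deterministic and configurable (`floor_fraction`).  The ranking
filter runs per 2D plane orthogonal to the sectioning axis ("circular"
implies an in-plane footprint) with a default 20 μm radius; both the
radius and a 3D variant of the interpretation are configuration, since
the footprint geometry is not otherwise constrained.  The rule is
monotone in a voxel's own intensity, and condition (a) suffices
regardless of the filter output.

## Vessel tracing

* **Skeletonization** is 3D topology-preserving parallel thinning
  (Lee's method, via scikit-image), which preserves connected
  components and loops under the 26-neighbour foreground rule.
* **Radii** are Euclidean distance-transform values at skeleton voxels,
  in μm, with anisotropy-aware sampling.  On a 1 μm grid this
  quantizes radius at roughly the half-voxel level; capillary-scale
  radii (2 μm) therefore carry ~10 % systematic uncertainty, which is
  why the recovery benchmark budgets 15 % for radius but 5 % for
  length.
* **Graph building** clusters skeleton voxels with ≠ 2 neighbours into
  nodes (touching node voxels become one node at their centroid — the
  thinning of a thick junction rarely yields a single junction voxel),
  and collapses degree-2 chains into polyline segments.  Chain
  polylines are smoothed with a 7-point moving average (endpoints
  pinned): raw voxel chains zig-zag on the grid and inflate Euclidean
  length by up to ~12 %; smoothing brings length error to ~2 % on
  straight-tube tests.  The window is short enough (≈7 μm of arc) not
  to round off real capillary tortuosity at the scales generated here.
* **Short inter-node segments** (length < max(2 × mean radius, 10 μm))
  are contracted, shortest first: the two nodes merge at the segment
  midpoint and incident segments re-anchor there.  This interprets the
  shortest-graph-path cleanup as node contraction; the alternative
  (deleting the segment and re-routing) disconnects junctions that are
  physically one bifurcation and was rejected.
* **Reconnection** joins endpoint pairs within 10 μm, greedy globally
  nearest first, each endpoint used at most once, never the two ends of
  one segment, ties broken by lowest node id.  Reconnection can only
  merge components, never split them.
* **Spur pruning** removes terminal segments under 50 μm, shortest
  first, collapsing branch nodes that drop to degree 2 between
  removals, iterating to a fixed point; cycles and through-segments are
  untouched.  Isolated segments under the threshold are removed too
  (`keep_isolated=False` by default) — a free-floating stub shorter
  than a spur is equally likely an artifact.
* **QC** computes total length / total node count (branch + endpoint);
  ratios under 250 μm/node mark fragmented tracing.  Counting only
  branch nodes is exposed as an option; all-node counting is the
  default because endpoint-riddled fragmentation is exactly the failure
  mode being screened.

## Regional metrics

Segment length is apportioned to regions by densified polyline steps
(≤ half a voxel) assigned to the region at each step midpoint — a
segment straddling a border credits each side with exactly the arc
length inside it, which whole-segment assignment would not.  Branch
nodes go to the containing region.  Region volume is voxel count ×
voxel volume.  Regional mean radius is length-weighted (an unweighted
per-segment variant is exposed; the regional average is otherwise
dominated by short capillary fragments).  Density volumes bin length
into 20 μm voxels and smooth with σ = 2 bins; Gaussian smoothing
conserves total length away from the border.  Length density is
reported in m/mm³; the large-vessel length fraction uses a 5 μm radius
cutoff for display-style splits and 3 μm for large-vasculature
analysis, both parameters.

## Flow tensors

Within a 400³ μm control volume, segments are clipped at the faces
(Liang–Barsky), cut points becoming boundary nodes; a segment that
exits and re-enters contributes independent pieces.  For each Cartesian
unit gradient, boundary nodes take Dirichlet pressures from the linear
profile and interior nodes solve flux conservation (sparse SPD system,
direct solve).  Components with no boundary node are excluded — they
can carry no flow and would make the system singular.  Segment
conductance defaults to integrated per-point series resistance
Σ 8μ dl/(π r⁴), the correct composition for varying radii; a
length-weighted mean-radius variant (π r̄⁴ / 8 μ L) is selectable.
Signed flux through the three centre planes assembles the tensor
column-by-column; the sign convention orients positive flow down the
pressure drop so diagonals are positive.  The tensor is not symmetrized
by default (a `(k + kᵀ)/2` option exists for display).  Scalar
conductance integrates |k·n| over a deterministic 2,000-point
golden-angle Fibonacci sphere; for k = diag(a,0,0) the exact value is
a/2, matched to 0.5 % at that point count.

## Cortical flatmap

The depth potential solves the Laplace equation over cortex voxels with
Dirichlet 1 on layer-1 voxels 6-adjacent to non-cortex, Dirichlet 0 on
layer-6b voxels 6-adjacent to non-cortex, and natural (zero-flux)
conditions elsewhere (links leaving the cortex are simply omitted from
the finite-difference Laplacian).  The system is solved with
Jacobi-preconditioned conjugate gradients to a 1e-10 residual —
faster and tighter than fixed-sweep successive over-relaxation at the
sizes used here, and deterministic.

Streamlines take 0.5-voxel steps along the trilinearly interpolated
unit gradient.  The gradient field is computed from the potential after
filling non-cortex values with their nearest cortex value and a light
σ = 0.7-voxel smoothing: staircased Dirichlet corners can otherwise
have an exactly zero discrete gradient and stall the trace.  A
streamline terminates inside a pial Dirichlet voxel, at interpolated
potential ≥ 0.999, or on exiting the cortex on the high-potential side
(the staircased surface has columns with no 6-adjacent Dirichlet voxel
to land in); voxels exceeding the step budget (10× the depth extent)
are flagged unresolved and counted.

Azimuth: in each coronal plane, pial surface voxels are ordered by
angle around the plane's cortex centroid with the angular branch cut
placed along the ray pointing away from the surface's mean (so the cut
never falls on the contour), positions are smoothed by a 5-point moving
average to suppress voxel staircase, and cumulative arc length is
measured from the dorsal-ridge reference — the maximum-DV surface
point, ties resolved to the ML-median of the maximal set, +ML side
positive.  Hit points get sub-voxel arcs by projection onto the
flanking contour segments.  The 10 μm lookup is authoritative; 20 μm
is produced by striding.

Validation phantoms: a slab (closed-form linear potential, reproduced
to < 1e-9) and a half-cylinder shell (closed-form ln(ρ/r)/ln(R/r)).
The annular comparison uses effective radii measured from the Dirichlet
voxel sets and excludes the one-voxel collar at those sets plus a wedge
within 10° of the cut faces, where the phantom's artificial
termination adds Dirichlet staircase that the closed form does not
model; in that interior the discrete solution agrees to better than
2 %.  The azimuth check flat_x = Rθ holds to 2 % with a 1.5-voxel
absolute floor — the arc cannot be expressed more finely than the grid.

## Cell detection and densities

Candidates are strict local maxima within an 8 μm radius (plateaus
resolve to the lexicographically smallest coordinate; an intensity
floor defaulting to the preprocess non-empty mean suppresses noise
peaks).  Patches are a 101×101 μm window at 1 μm/px and a 501×501 μm
window resampled to 201×201 px by linear interpolation (≈2.49 μm/px),
each stacked with a marker plane that is 1 at the candidate pixel;
optionally a 201×201 px full-frame context.  The classifier seam takes
any callable over candidates; the bundled baseline thresholds peak
contrast over the patch-border median plus a half-max blob-size gate —
it is a reference implementation of the seam, sufficient for the
synthetic benchmark (F1 ≥ 0.95 at generator contrast), not a trained
cell detector.

2D counts convert to 3D with empirical factors 1.4 (cytoplasmic), 1.5
(nuclear), 2.1 (pericyte).  `estimate_conversion_factor` reports both
the pooled ratio (rounded to one decimal: 1,769/840 → 2.1) and, given
per-ROI pairs, the per-ROI mean ± SD — the two summaries coincide at
one decimal for the pericyte counts, and both are surfaced rather than
choosing.  Densities are (2D count × factor)/region volume.  Detection
scoring uses greedy one-to-one nearest matching within the radius;
against the optimal assignment the greedy F1 differs by < 0.02 on
random fixtures.

## Correlation statistics

Each ROI is one data point; animal tables are averaged per region, and
regions failing the vessel QC are excluded and listed.  Pearson R with
a two-sided t-test (n − 2 df); Bonferroni multiplier m = number of
pairs in the requested matrix, recorded in the output since no single
convention for m is universal.  Zero-variance inputs yield a missing
(NaN) result, not 0.  A volume-weighted aggregation variant exists but
is not default.

## Synthetic data: what it covers and what it does not

The generator's defaults mirror the imaging regime being modelled:
1×1×5 μm anisotropic voxels, capillary-scale radii (2–4 μm), a
signal-to-background ratio of 10:1, additive Gaussian noise at 20 % of
background, a 1 μm PSF, and a low-frequency background (smoothed noise
at ±30 % of the background level) shared between channels so the
subtraction step is non-trivially exercised.  Vessel growth is a seeded
random walk with Bernoulli branching — deliberately simple; ground
truth must be exact, and morphogenetic realism is a non-goal.  Radii
are constant per segment so the radius oracle is exact.  The
recovery-benchmark networks are straight-segment trees with ≥ 60 μm
segments, ≥ 2 μm radii, wide branch angles, and > 12 μm clearance
between non-adjacent segments.

Consequently, passing tests demonstrate correctness of the measurement
chain — thresholds, topology, lengths, radii, tensors, projections,
statistics — under known geometry.  They do not demonstrate robustness
to stitching seams, vignetting, non-Gaussian noise, unfilled vessel
gaps at real-data rates, touching parallel capillaries, or imaging-axis
anisotropy in the PSF; nor do they reproduce published brain-wide
correlation magnitudes, which require the original mouse datasets.

## Problem sizes

Benchmarks run at sizes chosen to exercise every code path at full
resolution while remaining desk-scale: recovery networks in 200³ μm
volumes at 1 μm voxels (ten seeds), flatmap phantoms at 10 μm voxels
(slab 400×500×200 μm; half-cylinder 1000×600×200 μm, outer radius
425 μm), control volumes at the native 400³ μm, and 100-seed batches
for the stochastic statistics checks.
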