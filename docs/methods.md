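# Methods

This note documents the models, defaults and design choices behind sdapkit:
what the synthetic-data generator emulates, how each estimator works, and
what the recovery tests do and do not demonstrate about real data.

## Coordinate and unit conventions

All coordinates are continuous nanometres with an arbitrary origin (+x
right, +y up); frames are 0-based integers; pixels appear only in rendering
(default 10 nm).  Longitudinal positions along the centriole are signed with
the SCLT1 distal-appendage layer at zero, distal positive and proximal
negative; the literature usually quotes the magnitudes ("proximal to
SCLT1"), we store the sign.

## The generative model

A simulated centriole is a set of protein layers, each a ring of radius *r*
at longitudinal position *z*, with Gaussian radial (`radial_sd`) and axial
(`axial_sd`) thickness.  Emitter angles are either uniform (continuous
rings) or drawn around nine-fold blade centers with angular jitter
`cluster_angular_sd`; all nine-fold layers of one centriole share a single
blade phase, because one set of appendages defines the blade angles for
every protein bound to it.  Partial occupancy removes contiguous random arcs
whose total angular measure is (1 − occupancy)·2π; the default is a single
arc, which matches the contiguous missing sectors seen in incomplete rings
and minimizes bin-quantization bias in the completeness estimate (the arc
count is configurable, 1–3).

Projection: the axial view maps an emitter to (r cosθ, r sinθ); the lateral
view is an orthographic side projection, (r cosθ, z), which produces the
characteristic two-chord "rod" for a ring seen side-on.  No astigmatic z is
modelled — the analyses are strictly 2D.  In the axial view, layers more
than `focal_depth` (default 400 nm) proximal to the distal-most layer are
omitted: a 2D dSTORM acquisition focused on the appendage region does not
detect the centriole proximal-end populations of ninein/CEP170, which would
otherwise project concentrically into the appendage rings.

Imaging: each labelled emitter (Bernoulli `labeling_efficiency`, default
0.8) produces a geometric number of localizations (mean
`mean_locs_per_emitter` = 5) — a one-parameter stand-in for fluorophore
blinking statistics, which are not otherwise constrained.  Localizations are
jittered by an isotropic Gaussian of sd `localization_sd` = 8.5 nm, the
precision implied by treating a 20 nm image resolution as a FWHM
(20/2.355).  Frames are uniform over `n_frames` (default 15 000); uniform
background is added per channel (1 µm⁻² by default); fiducial beads emit one
localization in every frame.  Per-layer emitter counts in the packaged
presets are set so that one protein channel carries roughly 700–2000
localizations per centriole, i.e. tens to low hundreds per blade punctum,
the density at which appendage rings are typically resolved; they are
exposed placeholders, since labelling stoichiometry is otherwise unknown.

Distortions: stage drift is per-frame (none / linear / random-walk);
chromatic aberration is a full second-order 2D polynomial applied to the
short-wavelength channel, with coefficient order (1, x, y, x², xy, y²).
Optics precede stage motion: positions are distorted first, then drift is
added.

Determinism: every stochastic entry point requires an explicit seed, and
each model component draws from its own seed-sequence stream, so simulating
a channel subset reproduces exactly the corresponding rows of a full run.

## Geometry presets

The packaged presets encode the measured wild-type architecture — ODF2 ring
diameter 200 nm at the centriole wall with two layers at −100/−200 nm,
CEP128 a compact layer (d = 250 nm) at −160 nm, centriolin at d = 300 nm
between them, CEP89 dual layers at −20/−120 nm, ninein/CEP170 at d = 600 nm
with populations at −150 and −500 nm (separation 350 nm), SCLT1 at
d = 400 nm defining zero, CP110 capping the distal end, and a γ-tubulin
cylinder of diameter 400 nm confined between the proximal end and the sDAP
level.  Positions and diameters not individually published (centriolin,
CEP89, SCLT1, the ninein proximal population, CP110) are placed consistently
with the qualitative ordering of the architecture.  Knockout presets edit
this geometry: sDAP loss (CEP128 knockout) collapses ODF2 to a single
thinned, proximally shifted layer, removes the proximal CEP89 layer and the
downstream sDAP proteins, and lets the γ-tubulin cylinder spread distally;
DAP loss (CEP83 knockout) removes the DAP layers, collapses ODF2 to its
proximal layer and broadens ninein toward the distal end.  Serum-state
presets set the CEP128 missing arc to 25% (starved) or 50% (fed) and double
the CEP170 radial spread when fed.  Fiber presets anchor nine α-tubulin
fibers at the sDAP tip radius/height plus six at the DAP region; the
knockout variant keeps only the DAP-anchored set.

## Estimators

**Puncta.** A punctum is a DBSCAN cluster of localizations; its centroid is
the punctum position.  Defaults are a 12 nm grouping radius with 8
localizations minimum: at the ODF2 ring scale adjacent nine-fold blades are
only 68 nm apart with ~12 nm per-axis spread, and larger grouping radii
(e.g. 20 nm) merge them, while 12 nm separates all packaged ring scales.
Two true clusters closer than the grouping radius merge — an inherent
property of density grouping, covered by a test.

**Ring center and diameter.**  Kåsa's algebraic circle fit, iterated with
MAD-based radius-outlier trimming (background localizations otherwise have
enormous leverage on the algebraic solution), then refined by Gauss–Newton
on (cx, cy, r).  The fit is arc-agnostic: a noiseless half-ring yields the
exact center.  Mean diameter is twice the mean punctum (or localization)
radius about the center, with no noise-bias correction — the plain
punctum-distance definition; the outward bias is ≤ σ²/r ≈ 0.7 nm at σ = 8.5,
r = 100.

**Angular occupancy.**  Localizations gated to median radius ± 3 robust sds,
binned at 10°; a bin is occupied when its count reaches max(3, 10% of the
median nonzero-bin count).  Completeness is the occupied fraction; for a
punctate nine-fold ring the inter-blade bins are legitimately empty, so the
statistic is meant for continuous rings (as in the serum-state analyses).
Edge bins partially covered by a gap bias the missing fraction slightly
downward (≲ 3 points at the default density); the recovery tests bound the
total error at ±5 points.

**Symmetry.**  Mode-9 power ratio of punctum angles; expectation 1/n under
uniform angles (tested by Monte Carlo), 1 for perfect nine-fold placement.

**View and axis.**  Principal-component analysis with outlier trimming
classifies the reference cloud (eigenvalue ratio < 1.8 ring/axial, ≥ 3
rod/lateral, else ambiguous).  For a rod reference the centriole axis is the
perpendicular through the rod centroid; for a compact distal reference
(CP110) the axis direction comes from the elongated target cloud.  The sign
is fixed by a distal marker, an explicit hint vector, or the
reference-is-distal convention; without any of these the orientation is
unidentifiable and an error is raised.

**Profiles and layers.**  Longitudinal histograms (10 nm bins) conserve
mass (Σ density·binwidth = n).  Layers are peaks of the Gaussian-smoothed
profile (kernel sd = localization precision), with minimum separation 50 nm
and prominence ≥ 0.2 × max; the layer position is the density centroid of
the ±FWHM window rather than the argmax, which is robust to binning.  The
detector agrees with a brute-force mode search on the kernel-inflated
two-Gaussian mixture across a parameter sweep (knife-edge separations within
~12 nm of the bimodality threshold are excluded as genuinely unstable).

**Composites.**  Each centriole is translated so the reference centroid is
the origin and rotated so the axis points to +y; histograms (10 nm pixels)
are summed.  The transverse sign is canonicalized from the reference
skewness only when the asymmetry exceeds floating-point noise; no mirror
matching is applied by default.  Composites of identical centrioles at
different poses are exactly n× the single histogram.

**Distal boundary.**  The signed 0.95-quantile of the projected positions
(piecewise-linear CDF when only a binned profile is available).  The
quantile makes the qualitative "spreads toward the distal end" comparisons
testable.

**Fibers.**  Localizations are grouped with a 50 nm bridging radius; a
connected component qualifies as a fiber when its principal-axis elongation
is ≥ 4:1, span ≥ 300 nm and support ≥ 30 localizations.  Components formed
by crossing fibers fail the straightness test and are decomposed by a
deterministic Hough vote (2° angle and 25 nm offset quantization, one PCA
refinement per extracted line).  Counting assigns each fiber by its
centriole-proximal anchor endpoint — to the annulus for per-radian rates, to
the longitudinal bin of its axis-nearest endpoint for lateral censuses.
Crossing-dense fields still undercount (merged near-parallel fibers count
once), so absolute rates are conservative; group contrasts are unaffected.

**Statistics.**  Two-sided Mann–Whitney U (exact for small tie-free samples,
tie-corrected normal approximation otherwise) with rank-biserial effect
size; a Welch t-test is available behind a flag.  No multiple-testing
correction — comparisons are single per-figure contrasts.  The
implementation matches full permutation enumeration for n ≤ 8 per group.

**Corrections.**  Drift: fiducial tracks are DBSCAN clusters persistent in
≥ 50% of frames whose per-frame positions wander smoothly (temporal scatter
about a rolling median ≤ 50 nm — this second criterion rejects dense
structural clusters that span many frames); the trajectory is the
track-mean displacement, linearly interpolated and smoothed by a 100-frame
centered moving average, re-anchored to zero at frame 0, and subtracted per
localization.  Correcting at the localization level is equivalent to
correcting rendered images in the noiseless limit and strictly sharper with
noise.  Chromatic: linear least squares on (1, x, y, x², xy, y²) per axis
from bead pairs (≥ 6 required for identifiability; degenerate layouts are
rejected by a rank check), with in-sample RMS and, for ≥ 10 beads,
leave-one-out held-out RMS.  Fit residual is non-increasing in polynomial
order (nested least squares).

## Problem sizes in the recovery suite

Recovery runs use 10 simulated centrioles per condition (matching typical
per-figure sample sizes in this literature), 100 paired simulations for
boundary-shift directions, and 40 replicate 5-vs-5 experiments for the
fiber-rate power check; the drift-correction chain is exercised at 3000
frames with three fiducials.  These sizes give Monte-Carlo error comfortably
inside the stated tolerances while keeping the whole suite under a minute
of simulation time.

## What passing tests do and do not show

The generator reproduces the geometry, blinking, noise, drift, chromatic
distortion, background and fiber anchoring that the estimators are designed
for — so parameter recovery demonstrates correctness of the analysis chain,
not of any biological claim.  Real data additionally contain tilted and
partially overlapping centrioles, antibody linkage error (~10 nm offsets
that inflate diameters systematically), non-geometric blinking with
position-correlated repeats, structured (non-uniform) background, and
curved or out-of-plane microtubules; none of these are emulated.  Epitope
position matters in reality (N- vs C-terminal antibodies give different
radii); a preset encodes one epitope geometry.

## Known limitations

- Strictly 2D: no astigmatic z, no tilted-ring ellipse fitting.
- The punctum definition (and hence puncta counts) depends on the grouping
  scale; defaults are tuned to the packaged ring geometries and are
  config-exposed.
- Angular completeness is a binarized-bin statistic; it saturates for
  punctate rings and carries a small gap-edge bias.
- Fiber counting is conservative in crossing-dense fields.
- The composite average assumes translation+rotation alignment only; no
  per-centriole scaling or mirroring.
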