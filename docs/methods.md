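# Methods

## Coordinate conventions

Positions along the antero-posterior axis are percent egg length (% EL),
0 = anterior pole; dorso-ventral positions are percent embryo height.
Intensities are arbitrary units (a.u.).  Cleavage cycles C10–C13 precede
C14A, the pre-gastrulation part of cycle 14, which is subdivided into
eight time classes T1–T8.

## Synthetic cohorts

The generator is the package's ground-truth source; its defaults define
the study conditions used throughout the tests and the acceptance script.

**Pattern model.**  A gene's expression at a time class is a sum of
Gaussian stripes, `A·exp(−(x−c)²/2σ²)`, and broad domains,
`A·expit((x−a)/w)·expit((p−x)/w)`, optionally attenuated toward the
anterior by a plateau factor (0.9 for the midge Hb domain).  These forms
make truth analytic: an isolated stripe peaks at `c`; an isolated domain
edge crosses half-maximum at `a` or `p`.

**Species presets.**  The `clogmia` preset (moth midge): Eve resolves
six stripes before gastrulation, budding off an initially broad domain —
stripe 1 at T2, stripe 2 at T3, stripe 3 at T5, stripes 4/5 clearing at
T6, stripe 6 forming de novo at T5 near the posterior pole.  T8 peak
positions are 32/42/52/62/72/82% EL; per-stripe total anterior shifts
(appearance → T8) default to 5.72, 6.99, 6.0, 5.5, 5.0 and 2.7% EL, with
peak trajectories linear in time-class index.  The anterior Hb domain
spans 25–52% EL at T8; its posterior boundary drifts 2.15% EL between T3
and T8; expression peaks at T3.  The residual (not-yet-resolved) Eve
domain weakens by 5 a.u. per class as stripes bud off, which is what
makes consecutive classes with equal stripe counts distinguishable —
the premise of expression-based staging.  The `drosophila` preset: seven
stripes all resolved by T4 (T8 positions 35–71% EL, 6% EL period, sharper
stripes σ 1.5–1.8), smaller shifts that increase posteriorly (1.4–4.1%
EL), and a stationary Hb boundary.  Stripe amplitudes grow from 70 (55
for the late-forming midge stripe 6) to 100 a.u. between appearance and
T8, and widths sharpen from σ ≈ 2.6 to 2.0% EL; both trends feed the
stripe-1/6 staging signature.

**Sampling.**  Nuclei sit on a jittered grid covering the embryo
(100 × 30 at C14A, i.e. ~1% EL internuclear spacing along A-P; counts
halve per earlier cleavage cycle).  Placement jitter is 10% of the grid
pitch.  Per embryo, an affine perturbation x → a·x+b (scale s.d. 0.02,
offset s.d. 2% EL) displaces the expression pattern — the variation
registration must remove.  Intensity = pattern(a·x+b) + paraboloid
background `20 + 10·((x−50)/50)² + 5·((y−50)/50)²` + Gaussian noise
(σ = 5 a.u., ~5% of a mature stripe), clipped at zero.  Default cohorts
use 20 embryos per class (the acceptance script uses 30, i.e. 240 per
species — the scale of the real studies this emulates).  All randomness
derives from one seed; identical configurations are bit-identical.

**What the generator does not emulate:** 3D embryo geometry and optical
sectioning, point-spread blur, mitotic figures, embryo-shape variability
beyond the affine jitter, D-V expression asymmetries, extraembryonic
staining beyond what the lateral strip excludes, and spatially
correlated (non-white) noise.  Passing recovery tests therefore shows
the chain is correct and well-conditioned under these statistics, not
that it would digest raw microscope data unchanged.

## Stage-by-stage numerical choices

**Segmentation.**  Otsu threshold (bright nuclei; polarity flag for
inverted contrast), watershed seeded at local maxima of the Euclidean
distance transform with minimum separation of one expected nucleus
radius.  On non-touching disks this reduces to connected-component
labelling.  Pixel → embryo coordinates use the foreground bounding box.
Single-plane images are assumed.

**Lateral strip.**  |y − 50| ≤ 5 at the default fraction 0.10.

**Background removal.**  The strip is narrow, so the paraboloid staining
field reduces to a quadratic in x.  Candidate floor levels are the means
of the lowest-quartile intensities in 12 windows along x; the quadratic
is fitted to the lowest third of the levels and the floor set evolves by
region growing (windows adjacent along x join when within 2.5 robust
s.d., but at least 2% of the level range, of the fit; inconsistent
members are trimmed).  Growth is restricted to adjacent windows and the
fit is held constant beyond its outermost supporting windows, because a
quadratic extrapolated into unobserved territory can pass through
windows that sit inside an expression domain and never see the floor.
The estimate is deliberately conservative: the lowest-quartile level
undershoots the true floor by about one noise s.d., so corrected
intensities keep a small positive offset rather than losing signal.
The baseline is clipped at zero and never increases any intensity;
profiles with fewer than 10 nuclei are returned unchanged with a flag.

**Orientation.**  Flip x → 100 − x iff mean Hb intensity in the anterior
half is below the posterior half; ties keep the orientation (flagged).
Dorso-ventral orientation is metadata, not computed.

**Staging.**  Cycle = C14A − round(log₂(calibration/strip count)),
clamped to [C10, C14A]; calibration is the configured C14A strip count
(300 nuclei by default).  The pairwise distance fits a quadratic spline
(40 interior knots) to embryo 1 and evaluates embryo 2 against it after
a nuisance alignment — free affine x-transform (coarse offset scan
−8…8% EL then Nelder–Mead; the objective oscillates with the stripe
period, so a pure local search can fall into the wrong valley) and
closed-form linear intensity rescale.  The variance per nucleus is the
embryo's local residual variance (rolling window of 31) plus the model
spline's estimation variance, multiplied by (n/(n−k))² so that the null
expectation of χ² equals ν = n − k (k = spline coefficient count);
without this calibration every same-class probability saturates in the
tail and the distance collapses to 1.  distance = 1 − (p(1→2)+p(2→1))/2.
Clustering is agglomerative with the mean-of-the-merged-pair update
(WPGMA); ties break on the lowest embryo id, making the result
independent of input order.  With signatures the procedure is two-stage:
the χ² distance merges for as long as it is informative (until every
remaining pair probability has underflowed to distance exactly 1.0), and
the remaining merges are ordered by α + (1−α)·|Δ cluster-mean pca score|
(α = 0.5), so the signature decides only among clusters the χ² fit
cannot tell apart.  Signature ratios use spline peak intensities and
curvature-based widths (σ² = −I/I″ from a local parabola fit to the
nuclei, which is insensitive to neighbouring trough depths); stripe 6
must be detectable (≥ 4 stripe-like peaks) or the embryo is excluded
from the refinement only.  Full-cohort T1–T8 assignment first groups
embryos by nearest preset stripe count (counted at a stricter prominence
of 15% of range and width ≤ 7% EL), then splits count-ambiguous groups
with the χ² clustering, ordered by mean stripe brightness; if
mean-linkage collapses into strongly unbalanced clusters the split falls
back to ranking by brightness.

**Registration.**  Per-embryo least-squares quadratic splines on 60
uniform interior knots (coarser grids leave percent-level lack of fit on
mature stripes); extrema are found exactly as roots of the
piecewise-linear spline derivative, and only registration-grade
landmarks are kept: extrema with prominence ≥ 15% of the profile range
whose peaks are narrower than 7.5% EL at half local prominence.  Flat
residual-domain tops and noise wiggles are excluded — their positions
wander by several % EL and, worse, they make the landmark structure
differ from embryo to embryo.  Peak positions are refined by a local
parabola fit to the raw nuclei (removes the knot-grid bias of the
spline extremum).  The reference is the slot-wise mean over embryos
with the modal (peak count, trough count) structure; modal embryos pair
to it by A-P order (immune to stripe-period slips on periodic
patterns), others by nearest position after a coarse shift scan.  The
per-embryo map is a trimmed least-squares line through the matched
pairs; maps with implausible parameters (|a−1| > 0.12, |b| > 12% EL)
fall back to the identity.  The reference is recomputed once after
transforming (two-pass) and the cohort-mean map is constrained to the
identity (gauge fixing).  Classes with fewer than two stripe-grade
peaks (median over embryos) are left unregistered: a single stripe plus
a domain edge cannot anchor an affine fit.  Eve GCPs drive the
transform; all channels receive the identical map.

The gauge freedom is the method's irreducible uncertainty: each class's
atlas is defined only up to the cohort-mean of that class's true jitter,
an offset of s.d. ≈ 2/√n % EL.  Quantities that difference two classes
(per-stripe shifts, boundary drift) inherit √2 times that noise, which
dominates their error at realistic cohort sizes and is why the fly
preset's small shifts are recovered with larger relative scatter than
the midge's.

**Integration.**  Bin j covers [j, j+1)% EL (last bin closed); empty
bins are filled by linear interpolation and flagged.  Smoothing is a
Gaussian of σ = 3 × mean internuclear spacing (interpreted as σ, not
FWHM), reflective boundaries; spacing is the median nearest-neighbour
distance with y converted to EL units by the height-to-length ratio
(0.4).  Scaling multiplies to max = 255 jointly per gene across time
classes so temporal amplitude dynamics survive.

**Features.**  Peaks come from a quadratic-spline refit (40 knots) of
the *unsmoothed* binned atlas — the refit does the regularization, and
the three-nuclei display kernel would inflate stripe widths past the
stripe/domain cutoff.  Prominence is computed inside a ~12% EL window
(one stripe period): with unequal adjacent peaks a global prominence
contour hands the taller peak a base far below their shared trough and
grossly overstates its half-height width.  Peaks wider than 7.5% EL at
half prominence are classified as residual domains, not stripes (mature
stripes measure 4–6% EL).  Stripe identity is anchored at the most
mature class (labels 1..n anterior → posterior) and propagated backwards
by closest-first matching with a 5% EL per-class jump limit; a stripe's
appearance class is the earliest class its label reaches.  Boundaries:
single-level Haar shrinkage (universal soft threshold), plateau maximum,
then the requested-side half-maximum crossing with linear interpolation
between bins.  Widths reported for the species comparison are
peak-to-peak distances (stripe 1→6 or 1→7); stripe half-height widths in
the stripe table are at half local prominence.  The Welch test is the
closed-form statistic with Welch–Satterthwaite degrees of freedom;
ranked mode replaces pooled values by mid-ranks first.

## Problem sizes

Unit tests run cohorts of 1–10 embryos; recovery tests use the study
conditions: 20 rendered embryos (segmentation), 30 embryos at zero noise
(registration), 15 per class for T5–T8 (staging), and 20–30 per class
for the full-pipeline feature recovery.  The acceptance script uses 30
embryos per class per species (240 + 240).  The degenerate-cohort
fidelity check switches off noise, jitter, placement jitter and the
background field together: a background under a domain that reaches the
posterior pole is unidentifiable from a single profile, so a nonzero
background would measure the floor estimator's conservatism rather than
pipeline numerics.

## Known limitations

* Registration gauge freedom (above) bounds shift accuracy at ~0.5% EL
  per class pair for 30-embryo classes.
* Classes with fewer than two resolved stripes are not registered;
  their atlases carry the full embryo-to-embryo jitter as smear.
* Consecutive time classes that differ only in stripe brightness
  (T3 vs T4 early in stripe formation) are separated by a brightness
  ranking when the χ² distance cannot split them; accuracy there is
  limited by the amplitude overlap between classes.
* The χ² probability saturates for clearly different embryos (p
  underflows), so the distance matrix is informative near 0 and ordinal
  at 1; the clustering design accounts for this explicitly.
* Background estimation never extrapolates beyond observed floor
  windows; under broad domains the subtraction is conservative rather
  than exact.
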