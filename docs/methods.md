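# Methods

## The problem

Partial fecundity (PF) — the number of mature oocytes a ripe female can
shed in one spawning event — is the quantity that links individual
clam biology to the choice of a minimum landing size.  In venerid clams
the gonad is diffuse in the visceral mass, so PF cannot be weighed or
counted directly; it has to be reconstructed stereologically from
serial histological sections.  This package implements that
reconstruction and, because the underlying tissue data cannot be
redistributed, pairs it with a generative 3-D gonad model so that the
whole chain is testable against known ground truth.

## Gonad model (germ-grain / Boolean)

A female gonad of a clam with shell length TL (mm) is a prolate
spheroid with semi-axes (a, a, 2a), its long axis along the sectioning
axis z, scaled so that its volume matches

    G_v = 17.2 · TL − 304.5   [mm³],

optionally multiplied by lognormal noise with unit mean and CV
`gv_noise_cv` (default 0.08, back-computed from the reported adj. R² of
0.97 over TL 19–33 mm).  The 2:1:1 shape is a modelling choice; none of
the estimators depends on it beyond having smooth, analytically known
cross-sections.

Oocytes are oblate spheroids: equatorial (maximum) diameter d_max, polar
(minimum) diameter d_min = q·d_max with aspect ratio
q ~ Uniform(0.65, 0.95), geometric volume π/6·d_min·d_max², random
symmetry-axis orientation, centre uniform in the region.  Overlap is
permitted (Boolean model): the estimators observe section profiles, not
packing, and ignoring exclusion keeps generation linear in oocyte
count.  Each oocyte carries a concentric spherical nucleus (germinal
vesicle) of diameter `nucleus_fraction`·d_max (default 0.35).

d_max follows a truncated normal per maturity stage and development
class.  Means 70.3/41.5 μm (stage 4A mature/immature) and 70.1/38.6 μm
(stage 4B), stage ranges [5.85, 154.89] μm (4A) and [9.54, 139.21] μm
(4B); the mature/immature split is pinned at 60 μm (the vitellogenesis
threshold used for maturity classification), so mature oocytes sample
from (60, upper] and immature from [lower, 60].  The standard
deviations (25 μm mature, 15 μm immature) are free parameters chosen to
respect the reported ranges; only means, extremes and the threshold are
constrained by data.  Oogonia are not modelled separately; anything
below the threshold counts as immature.

Two calibration modes fix the oocyte content:

- **occupancy** (default): oocytes of each class are added until their
  summed geometric volume first reaches the configured percentage of
  the region volume — 19.1% mature + 20.5% immature in ripe (4A)
  females, 7.8% + 14.0% in partially spawned (4B) females.  Realized
  occupancy overshoots the target by at most one oocyte volume
  (≪ 0.1 percentage points at realistic sizes).
- **count**: the mature-oocyte number is drawn from
  PF = 3.01·10⁴·TL − 5.21·10⁵ with lognormal noise (CV 0.2,
  back-computed from the reported adj. R² of 0.85); the immature class
  remains occupancy-calibrated and mature occupancy is emergent.

Both modes exist because the published occupancy fractions, diameter
means, G_v regression and PF regression are not jointly consistent with
a single simple model: occupancy-calibrated gonads at these diameters
imply a PF~TL slope of ≈1.2·10⁴, well below the reported 3.01·10⁴.
Each recovery test states its mode.

Maturity at the population level is Bernoulli with logistic probability
p(TL) = 1/(1+exp(−(a+b·TL))).  Defaults a = −16.8, b = 1.5 give
TL₅₀ = −a/b = 11.2 mm and p(15 mm) ≈ 0.997, matching the observations
that the smallest mature individuals appear near 9.6–9.9 mm and that
everything above 15 mm is mature.

## Observation model

Sections are half-open slabs [k·s, k·s + T), k = 0, 1, …, tiling the
region's axial extent (defaults T = 6 μm, s = 100 μm).  Per section the
gonad area G_a is the analytic cross-section at the slab mid-plane.
Per oocyte and slab, the recorded profile is the largest in-plane
ellipse over planes inside the slab.  For an oblate spheroid with
equatorial semi-axis ae, polar semi-axis ap and axis tilt cosine t
against the slab normal, the axial half-extent is
w = sqrt(ae² + (ap²−ae²)t²) and a plane at offset h (|h| < w) cuts an
ellipse with semi-axes ae·s(h) and ae·ap·s(h)/w, s(h) = sqrt(1−h²/w²);
the best plane is the admissible one closest to the centre.  Thin
sections are treated as planes (no projection through the slab).

A profile is flagged `nucleus_hit` when the slab geometrically
intersects the nucleus sphere (rule "intersect", the default — what an
observer calling a cell "sectioned through the nucleus" sees) or when
the slab contains the nucleus centre (rule "center", an unbiased
counting rule kept as an internal oracle).

Camera fields (default six per gonad, 870 × 660 μm, a 10× camera field
— the true field size at 10× is not documented, so this default is
declared, not inferred) are placed on sections drawn uniformly at
random among those whose cross-section can host the rectangle; the
rectangle position is uniform among positions fully inside the
cross-section circle, and only profiles whose centres fall inside a
field are retained.  A field large enough to cover the whole
cross-section degenerates to whole-section counting with the
cross-section itself as effective area; a field that can neither fit
inside nor cover the section is an error.  Lost or folded sections are
not simulated.

## Estimators

**Volume.**  Cavalieri: Ĝ_v = Σ G_a·s.  Exact for constant
cross-sections, unbiased for systematic sections; with sections pinned
at z = 0 instead of a random start the quadrature error telescopes to
second order and is ≪ 1% for spheroidal regions.

**Counts.**  Only nucleus-hit profiles are counted.  Under the
intersect rule a nucleus of diameter d_n is hit by slabs over an axial
window of length d_n + T, so raw counts are corrected by the
Abercrombie factor T/(T + d̄_n); the class-mean nucleus diameter
d̄_n defaults to `nucleus_fraction` × the analytic mean of the class
d_max distribution (for real data it is a user input).  Because the
expected raw count is linear in d_n, correcting with the class mean is
exactly unbiased.  Number density per class is
(corrected count)/(total field area × T), scaled to the gonad by Ĝ_v.
Under the center rule counts need no correction.

**Mean oocyte volume.**  Profiles cut through the nucleus are a
size-biased sample (hit probability ∝ d_n + T), so the class mean
volume weights each profile by 1/(T + f·p_max), its own Abercrombie
factor with the per-profile nucleus diameter read as
f·p_max (f = `nucleus_fraction`, p_max the measured profile d_max);
this cancels the size bias exactly in expectation.  A second,
independent bias comes from the best-plane measurement convention: the
implied profile volume π/6·p_min·p_max² equals the true volume times
s³/W̃ (W̃ = w/ae), which averages slightly above 1 under isotropic
orientation.  Each profile volume is divided by the analytic shape
factor

    κ(d) = P₀·A + (1 − P₀)·B,    P₀ = T/(f·d + T),

where A = E[q/W̃]/E[q] and B the corresponding cap-integral average
over the offset distribution given a hit — closed-form constants
computed by Gauss–Legendre quadrature from the configured aspect-ratio
range.  At the defaults κ ≈ 1.008 (mature) to 1.018 (immature).  With
these two corrections the measured class mean-volume ratio against
ground truth is 0.99–1.00.

**Occupancy and PF.**  Percent occupancy per class is
100·N̂·ŌV/Ĝ_v; a Delesse areal-fraction estimator
(Σ profile ellipse areas / field area, all profiles) is available as a
sensitivity flag — note it inherits the best-plane inflation
(≈ +15%) undiluted and is reported uncorrected.  PF is N̂(mature),
defined only for ripe (4A) females.  The spheroid volume is
π/6·d_min·d_max² by default ("corrected"); the literal variant
4/3·π·d_min·d_max², which treats full diameters as semi-axes and
therefore overstates a sphere eight-fold, is kept behind
`mode="paper"` purely for comparison with reports using that formula —
generator truth and estimator must use the same mode in any recovery
comparison, and outputs are labelled with their mode.

Residual end-to-end accuracy: cohort mean total occupancies over 30
gonads land within ±2% relative of the configured 39.6% (4A) and 21.8%
(4B); remaining wobble is field-sampling noise, not bias.

## Maturity ogive

Females are mature when any oocyte exceeds 60 μm d_max (an empty smear
reads as immature — the "only immature oocytes seen" criterion is
vacuously true); males when elongated-tail spermatozoa are present;
indeterminate individuals are excluded.  The ogive is a binomial GLM of
per-size-class mature counts on class midpoints (1-mm classes by
default, classes weighted by their n), with TL₅₀ = −a/b and a
delta-method SE; complete separation falls back to a lightly
ridge-penalized fit and is reported via a warnings field, never
silently.  A percentile bootstrap CI is available behind a flag.

Estimator property worth knowing: TL₅₀ is a nonlinear transform of the
coefficients and carries an O(1/n) bias (≈ +0.08 mm at n = 500 with
the default steep ogive, identical for unbinned ML and bias-reduced
coefficient fits); it is far below the delta-method SE of a single fit
(≈ 0.2 mm) but visible when averaging many replicates.

## Cohort statistics

OLS with slope F-test and adjusted R² for G_v~TL and PF~TL; CIs for a
prediction at a new length are mean-response t-intervals by default
(the published "95% CI" does not state mean vs individual; a
prediction-interval variant sits behind a flag).  The MCRS scenario
reports predicted PF at the new (22 mm) and old (25 mm) sizes, the raw
percent change in both directions, and the headline value rounded to
the nearest 10%: with the published coefficients, 1.412·10⁵ vs
2.315·10⁵ eggs — a 39.0% reduction (≈40%), equivalently 64% more eggs
at 25 mm.

Occupancy ANOVA is two-way fixed-effects (maturity stage × oocyte
stage) with type-II sums of squares — the reference design is
unbalanced (20 vs 6 females) — plus a one-way ANOVA on per-female
totals and Tukey HSD (Tukey–Kramer for unequal n) on cells and both
marginals.  The ANCOVA works on log counts with log TL as covariate,
reports the homogeneity-of-slopes check first, then type-II tests and
simple main effects per oocyte class.  The originally reported F table
cannot be reproduced without the raw per-female data; instead the
package's tests verify the reproducible structure: the partially
spawned minus ripe occupancy contrast is negative and the stage effect
significant in ≥95% of 200 simulated cohorts at the reference design,
and the ANOVA/ANCOVA implementations match closed-form oracles on
balanced toy designs to machine tolerance.

## Phenology

Descriptive only: monthly mean ± sample SD (n−1) of bottom seawater
temperature and chlorophyll-a from timestamped series (10-minute to
daily cadences), and monthly maturity-stage composition percentages
with F1/M1/indeterminate merged into the inactive code — sexes are
indistinguishable in inactive gonads.  No environmental-trigger model
is fitted: the temperature/food link to spawning is narrative in the
underlying study, and any regression here would be invention.

## Pipeline, seeds, units

`RunConfig` (YAML/JSON, unknown keys rejected, range checks catch unit
slips such as spacing given in mm) drives simulate → section →
estimate → stats.  Per-stage seeds derive from the master seed by
hashing (blake2b of "seed:stage", reduced below 2³¹) so stages can be
rerun independently; gonads are streamed one at a time because a
full-size gonad holds ~10⁶ oocytes.  Internally all geometry is in μm
and μm³; mm/mm³ appear only at I/O boundaries.  The manifest records
config, seeds, package version and SHA-256 hashes of outputs, and is
byte-identical across reruns of the same configuration.

## Simulation scale in the test suite

Full-size gonads (G_v 22–263 mm³, ~0.3–1.5 million oocytes) are used
for the headline recovery checks: 30 gonads per stage for occupancy,
26 for the G_v slope, 20 count-calibrated for the PF slope.
Many-replicate properties (the 200-seed ANOVA sign test, the
200-replicate count-bias bound) run on gonads scaled down ~70-fold in
volume (G_v = 0.25·TL − 3.5) with 300 × 225 μm fields; occupancy
targets, diameter distributions and estimator settings are identical,
so the contracts under test are unchanged while a full 200-seed sweep
stays around a minute.

## What the synthetic data does and does not show

The generator reproduces the statistical summaries of a real cohort
(volume–length scaling, occupancy fractions, diameter distributions,
maturity saturation) but not tissue reality: no follicle architecture,
no intra-gonad gradients or intraindividual asynchrony, no stain or
segmentation error, no lost/folded sections, spherical concentric
nuclei with a fixed nucleus:cell ratio, and independent uniform oocyte
placement.  Passing recovery tests therefore demonstrates that the
estimators are correct for the stated observation model — they do not
validate histological practice on real slides, where measurement error
and the nucleus-visibility criterion add biases of their own.  The
nucleus-hit counting criterion also means absolute oocyte numbers in
real material are likely conservative, a caveat the estimators here
share by construction.
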