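# Methods

## The model

`zoicomp` quantifies neighborhood competition among mapped forest trees.
For a focal tree alive at the start of a census period, the predictors are
sums of the basal area (ba, cm², `ba = gbh²/4π` with gbh the stem girth at
breast height in cm) of all *larger* neighbors that survived the period,
split into conspecific (CON) and heterospecific (HET) components, restricted
to a circle of radius r around the focal position and weighted per point by
a distance decay (1, 1/d or 1/d²; 1/d is the default). Because zero
neighborhoods must survive the log transform, 1 cm² is added inside the
log: every model term is `ln(1 + Σ)`.

Growth is the absolute basal-area growth rate `agr = (ba_t2 − ba_t1)/Δt`
(cm²·y⁻¹), modelled by OLS on the log scale with the focal's own size as a
covariate; survival is the 0/1 outcome over the period, modelled by
logistic regression with the same structure. Growth effect sizes are
squared partial correlations `t²/(t² + df_resid)`; survival effects are the
raw logistic coefficients β, convertible to odds changes via
`(exp(β) − 1)·100`. Model fit for survival is summarized by the likelihood
pseudo-R², `R_L² = (L₀ − L_p)/L₀ · 100`, with a degrees-of-freedom
adjustment of the same form as in linear regression (the adjustment formula
is not uniquely standard; the linear-regression form is a documented
choice). Growth fits additionally report a PRESS-based predicted R²
computed from the hat matrix.

### Spatial extension

In the nonspatial variant each neighbor's whole basal area sits at its stem.
In the spatially extended variant each crown is a disc of radius
`cr = a + b·√gbh` (pooled allometry; default coefficients −1.003 and 0.523,
with −0.959/0.516 and the rounded −1.0/0.52 as alternatives) filled with
uniform random points:

* **equal** — 10 points per m² of crown area;
* **larsm** — as many points as the tree's basal area in cm², so larger
  trees get disproportionally denser crowns, encoding asymmetric
  competition for light.

Point weights are `ba/N` within a tree, making the summed weight equal the
basal area exactly in both modes (for `larsm` the weight is within rounding
of 1 cm²; exact conservation was preferred over exactly-unit weights).
Point counts round half-away-from-zero with a floor of one point. A crown
of zero radius degenerates to a single stem point carrying the whole basal
area, which makes the nonspatial model a strict special case: forcing
`cr = 0` for every tree reproduces the nonspatial predictor tables and fits
bit for bit (this is asserted in the test suite).

### Crown plasticity

A point of tree S is *shaded* when a point of a strictly larger tree lies
within a tolerance Δd of it; Δd takes values 0–1.2 m in 0.2-m steps,
separately for conspecific and heterospecific larger trees (49
combinations). Δd = 0 flags nothing — with continuous coordinates two
points never coincide. Shaded points are then

* **removed** — deleted, shrinking the tree's effective basal area; or
* **relocated** — moved into the unshaded part of the crown.

Processing is hierarchical from the largest tree down ([A → B] → C): each
tree is flagged against the *already adjusted* clouds of its larger
neighbors, so the adjusted canopy contains no residual shading at tolerance
Δd. Trees of equal girth do not shade each other (girth stands in for
height; ties are broken only for processing order). A tree whose points are
all shaded vanishes as a neighbor.

The unshaded crown outline for relocation is estimated by a Gaussian
product-kernel density on a 25 × 25 grid spanning the unshaded points
padded by one bandwidth per axis (normal-reference bandwidths,
`1.06·min(sd, IQR/1.34)·n^(−1/5)`). The target region is the filled contour
at the lowest "pretty" level strictly between the grid's minimum and
maximum density — the outermost contour line a default density plot would
draw. (A rule of "minimum positive grid density" would select the whole
padded grid, since a Gaussian kernel is positive everywhere, and would make
the density estimate vacuous; the outermost-plotted-contour reading keeps
the region hugging the point cloud while still allowing it to extend beyond
the original disc, i.e. plastic crowns.) Relocated points are rejection-
sampled uniformly inside this region, with the additional constraint that a
candidate position must not itself lie within Δd of a larger tree's point —
this is what guarantees the no-residual-shading invariant for relocation.
Degenerate unshaded sets (fewer than three points, or zero variance on an
axis) fall back to jittered copies of unshaded points, and ultimately to
exact copies, which are unshaded by definition.

Neighbor queries use cKDTrees per accumulated species chunk; results are
contractually identical to the brute-force all-pairs distance check, which
the tests assert on small canopies.

### Focal position

Focal trees are represented as points (no crown) when their neighborhood is
evaluated. Their location is either the stem coordinates or the centroid of
the unshaded part of their own crown — the latter as a proxy for where the
crown actually receives light. For the largest trees the two coincide up to
sampling noise.

### The model grid and averaging

Radii run from 1 to 20 m in 1-m steps, independently for the CON and HET
terms; with the 7 × 7 Δd combinations the spatial two-term scan has exactly
7·7·20·20 = 19,600 cells (nonspatial: 400). Grid cells are compared by
AICc, where k counts the mean parameters plus, for growth, the residual
variance. The final CON and HET effects are unweighted means of the raw
coefficients over all retained cells within 2 AICc units of the minimum (no
Akaike weights — the models share a common structure and differ only in
radius and tolerance). Summaries also report the mean and range of radii
and tolerances in the band, the least-squares slope of coefficient on
radius, and an automated bimodality diagnostic of the coefficient
distribution (two histogram modes on either side of zero, or separated by
at least twice the absolute mean) — reported, never acted on.

Growth cells are excluded when fewer than five focal trees have any CON
neighbor or fewer than five have no HET neighbor at all (such fits ride on
extreme radii); survival cells are never excluded this way, but estimates
with SE > 100 are dropped from the averaging. Before fitting, growth
observations with residuals below −3 SD in the per-species size regression
(`ln agr ~ ln ba`, no neighbor terms) are excluded iteratively.
Non-positive growth rates are floored at ε = 0.01 cm²·y⁻¹ before the log
(dropping them is a config option); agr is defined on basal area — the
natural scale given that the model regresses on and sums basal areas — with
a girth-based variant available.

A reference-model comparison labels a scan "much better"/"much worse" than
the nonspatial size-plus-all-neighbors model when the AICc difference
reaches ±7, else indistinguishable.

### Community level and randomization

Species-level averaged effects are assembled into one row per species with
between-period differences, total plot basal area per species and an
over-understory index class (<20 understory, 20–55 intermediate, >55
overstory). Community regressions (OLS with PRESS-predicted R²) relate
effects to log₁₀ plot basal area; Pearson correlations (Spearman optional)
relate growth-effect changes between periods to survival effects; a
Procrustes rotation with a row-permutation test (√(1 − m²) correlation,
protest-style p) compares two community ordinations.

The null model re-draws every tree's position uniformly in the plot under
minimum nearest-neighbor distances that differ within vs. between six gbh
size classes (bounds 10/30/60/120/240/480 cm; defaults 1 m within and 0.5 m
between classes — simple packing rules, fully configurable), placing large
trees first and relaxing with a warning after an attempt cap. Species
identities, girths and statuses are untouched, so each species' size
structure is preserved exactly. Re-running the pipeline on (by default 100)
randomized layouts yields per-species null distributions; the envelope is
the null mean ± 3 SE, where SE is the standard deviation of the effect
across runs — each run yields one effect estimate, so the across-run SD
estimates the effect's sampling SE under the null (SD/√n_runs would be the
SE of the null *mean*, which is not the comparison being made). Magnitude
bands for |observed − null mean| are 0.06/0.1 (growth) and 0.6/1.0
(survival) for moderate/large. Community-level slopes and t-values per run
give sign counts and an empirical two-tailed p as the rank of |t_obs| among
the null |t|.

## The synthetic-forest generator

The generator emulates the study design the package targets: 100 × 400 m
plots with a 20-m analysis border, two periods of 10.00 and 11.07 years,
multi-species stem maps, and right-skewed girths (truncated exponential on
[10, 200] cm, rate 0.05 cm⁻¹, mean ≈ 30 cm). Species abundances follow a
log-series-style rank-abundance law (explicit counts for tests); stem maps
are Thomas cluster processes (mean 40 offspring per parent, 6-m cluster
SD) or CSR. The clustering defaults produce the strong conspecific
aggregation and local dominance typical of the tropical forests this
methodology was built for; in particular they leave a handful of focal
trees without any larger heterospecific neighbor at mid radii, which is
what keeps the zero-HET exclusion rule from discarding mid-radius growth
cells (as in the field data, only the largest radii are excluded).

Dynamics are generated from the package's own regression equations at a
known true radius and tolerance (defaults r = 10 m, Δd = 0, linear decay,
larsm filling): survival is Bernoulli from the logistic equation (defaults:
intercept 5.0, size slope 0.2, CON −0.5, HET −0.25, giving ≈ 15% decadal
mortality, consistent with ~1.5–2%·y⁻¹ field rates), growth is lognormal
from the growth equation (defaults: intercept −1.3, size slope 0.5, CON
−0.2, HET −0.1, σ = 0.2), and the next census girth is back-computed from
`ba_t1 + agr·Δt` (growth is strictly positive on the log scale, so girths
never shrink). Dead trees carry their last measured girth. Survival is
drawn *before* growth using the full period-start neighborhood, because the
fitted models' "neighbors that survived the period" definition is circular
at generation time; growth then uses surviving neighbors only, exactly
matching the fitted growth model. Per-period coefficient overrides emulate
between-period regime shifts; no attempt is made to model climate forcing
mechanistically.

What the generator does **not** emulate: measurement error in girth and
coordinates, recruitment, multi-stemmed trees, species differences in
allometry or error variance, and vertical canopy structure. Passing
recovery tests therefore demonstrate the correctness and statistical
calibration of the pipeline under its own assumptions, not the realism of
those assumptions for any particular forest.

## Numerical choices

* Distances are floored at 0.1 m (the coordinate precision) before decay
  weighting, so 1/d and 1/d² stay bounded.
* Neighbor inclusion and the focal border test are closed (≤ r, ≥ border).
* Size-class membership is half-open: [10, 100) cm for the default focal
  class.
* ALL-neighbor sums are computed as CON + HET so that identity is exact in
  floating point.
* Per-tree random substreams are derived from (master seed, CRC32 of the
  tree id), making crown filling reproducible and independent of row order;
  the seeding contract is part of the public API.
* Canopy adjustment is computed once per (Δd_CON, Δd_HET) combination and
  reused for all focal trees; repeated stochastic refills are deliberately
  not averaged over.
* Logistic fits use Newton ML with a convergence check; separation,
  rank-deficiency and non-convergence mark the cell excluded
  (`unstable`/`collinear`) without aborting a scan.

## Problem sizes in the shipped tests

The validation suite runs on deliberately modest problem sizes chosen to
exercise every code path: the exact nonspatial-limit check uses a 1-ha CSR
stand; parameter recovery uses twenty 4-ha stands of five species (≈ 500
focal conspecifics each) scanned over five radii at Δd = 0; the
randomization-null check uses a 2-ha ten-species neutral stand with 20
randomization runs. Full 19,600-cell scans are enumerated and spot-checked
rather than fitted exhaustively in the tests; the pipeline itself places no
limit on grid size.

## Known limitations

* Crowns are circular at fill time and 2-D throughout; height enters only
  through the girth-implies-taller assumption, and equal-girth trees
  neither shade nor outrank each other.
* The relocation contour is a gridded KDE outline; its exact shape depends
  on the 25 × 25 grid and the pretty-level choice, although conservation
  and no-residual-shading hold regardless.
* Focal trees are points; a fully crown-integrated focal representation
  (with the attendant risk of focal trees vanishing under complete overlap)
  is out of scope.
* The crown allometry is taken as published constants and shared across
  species (a per-species override hook exists); refitting it requires crown
  measurement data the package does not ship.
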