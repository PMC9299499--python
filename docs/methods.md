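# Methods

## Dose–response model and error structure

Continuous micronucleus responses (MN-PCE %) are modelled with the
four-parameter exponential and Hill families for increasing effects:

```
exponential:  m(x) = a [ c − (c − 1) e^(−b x^d) ]
Hill:         m(x) = a [ 1 + (c − 1) x^d / (b^d + x^d) ]
```

Both satisfy `m(0) = a`, are non-decreasing for `c > 1`, and approach the
plateau `a·c`. `a` carries response units; `b` has units `dose^(−d)`
(exponential) or dose (Hill, where it is the dose of half-maximal increment);
`c` (maximum fold-change) and `d` (log-steepness) are dimensionless.

Errors are lognormal with constant per-level variance: `log y ~
Normal(log m(x), var)`. The log-likelihood is computed from per-(level,
dose) sufficient statistics of the log-responses, so individual-animal and
group-summary data share one code path. Published arithmetic summaries
(mean, SD, n) are mapped to log scale by the lognormal moment map
`logvar = ln(1 + CV²)`, `logmean = ln(mean) − logvar/2`, and the group's sum
of squared log-deviations is taken as `(n − 1)·logvar`. Responses must be
strictly positive (lognormal support); zero responses are rejected with a
row-addressed error rather than silently shifted.

## Covariate structure and selection

Subgroups (sexes, studies) are fitted jointly with `c` and `d` shared — a
hard constraint, never relaxed — while `a`, `b` and `var` may be
level-specific. Selection is forward stepwise from the all-shared model: at
each round the candidate among (a, b, var), in that fixed order for
deterministic tie-breaks, with the largest log-likelihood gain is accepted
when `2·ΔLL` exceeds the χ² critical value at α = 0.05 with `(L − 1)`
degrees of freedom for `L` levels (1.9207 log-likelihood units for two
levels). The candidate fit is warm-started from the current fit, which
guarantees nested-model dominance up to optimizer tolerance. Only the full
four-parameter curves are fitted; a nested sub-model ladder (dropping d, or
c, etc.) is left as a configuration stub (`submodel_ladder="full"`), since
the covariate analysis implemented here operates on the full models.

## Maximum-likelihood fitting

The variance parameters have closed-form ML solutions given the curve, so
the optimizer works only on the curve parameters, in transformed
coordinates: `log a`, `log(c − 1)`, `d`, and for potency either
`ln b + d·ln x_top` (exponential — the log exponent at the top dose, which
decouples the scale of `b` from `d`) or `ln b` (Hill). Box constraints:
`d ∈ [0.25, 4]` by default (standard continuous-BMD regularization against
infinite-slope and flat-shape degeneracy; configurable), `c ≤ 10⁴ `, and
data-driven bounds on `a` (±50-fold around the observed per-level geometric
means). Optimization is bounded L-BFGS-B from a fixed, seed-free lattice of
36 starting points over (d, c, potency); the 10 best lattice points are
polished (plus any warm start), with `ftol = 1e-12`. There is no randomness
anywhere in the fit path.

`converged` reports optimizer success; parameters ending on a bound are
listed in `diagnostics["at_bounds"]` rather than forcing `converged=False`,
because for steep short-series designs `c` and `d` routinely and
legitimately rest on their (deliberate) bounds. A `flat_model` flag is set
when the fit beats the nested dose-independent (constant-mean) model by less
than χ²₀.₉₅(2)/2 or `c` collapses to its lower bound; a 50% effect size is
then typically unreachable and the BMD is reported as +∞.

Identifiability gate: fitting requires ≥ 3 distinct doses including the
control, and at least as many (level, dose) cells as free curve parameters.
(Counting cells rather than distinct doses lets a 3-dose two-level dataset
identify the 4 shared curve parameters, which a literal distinct-dose rule
would wrongly reject.)

## BMD, profile CIs, combination

`BMD` solves `m(BMD) = a(1 + CES)` in closed form per family; it is +∞ when
`CES ≥ c − 1`. The default CES is 0.50, the recommendation for in vivo
micronucleus data; 0.10 is the usual general default and is available in
configuration.

Confidence bounds reparameterize the focal level's potency as an explicit
BMD parameter (`b` recovered from BMD, c, d at the given CES) and profile
out every nuisance parameter. The two-sided 90% bounds are where the
profile log-likelihood falls by χ²₀.₉₀(1)/2 ≈ 1.3528 below the maximum; the
BMDL is therefore a one-sided 95% lower bound. The search steps outward
from the MLE in 0.35 log-dose increments to bracket the crossing, then
bisects to 1e-4 in log-dose; inner maximizations are warm-started from the
MLE mapping and the previous profile point (bisection rather than a
root-finder makes the search robust to the small warm-start noise of the
inner maximizations). The bracket spans three decades either side of the
MLE; an upper crossing not found inside it is reported as BMDU = +∞, and a
lower bound pinned at the bracket edge is flagged in diagnostics.

Across families, the per-level point of departure interval is the lowest
BMDL and highest BMDU (infinite BMDU dominates); covariate-structure
selection runs per family independently. The PoD carried into
human-equivalent conversion is the minimum combined BMDL across levels
(configurable rule). The CI ratio BMDU/BMDL is reported per family, level
and combination as the study-precision metric.

## HED and MOE

Rat mg/kg → human mg/kg divides by 6.2 (equivalently ×0.16), and ×37 (human
Km) converts to mg/m², per the FDA starting-dose body-surface-area table
(only the rat divisor is bundled; other species can be passed explicitly).
Two chains are reported side by side: the exact multiplicative chain, and
the conventional reporting chain that rounds mg/kg to 2 decimals before
applying Km and gives mg/m² to 3 significant figures (2.89 → 0.47 → 17.4).
The pipeline's headline mg/m² PoD and downstream MOE follow the reporting
chain, matching how such numbers are carried in assessments. MOE =
PoD(HED)/exposure; zones are green at MOE ≥ 10, yellow at 3 ≤ MOE < 10, red
below 3, boundaries assigned to the more favorable zone. For an exposure
range the summary verdict is the zone at maximum exposure (smallest margin).
No dosing-schedule (intermittency) adjustment is applied.

## Synthetic data: what it emulates and what it does not

The generator draws `y = m(x)·exp(ε)`, `ε ~ N(0, var)`, per animal, with a
single seeded generator and fixed draw order (bitwise reproducible;
replicate r of a simulation study uses seed + r). Two bundled designs
emulate the source studies of the etoposide case:

* **Garriott-like** (14-day F344 rat study): doses 0, 1.14, 11.36, 57
  mg/kg/day, male and female, n = 5/group (the conventional micronucleus
  cohort; the published report does not state n). The true curve is an
  exponential family calibrated analytically to the study's reported spans:
  control means 0.10 % (male) / 0.14 % (female) and top-dose means 8.7 % /
  1.86 %. The shared fold-change is c = 95, just above the 87-fold male
  span that lower-bounds it; `d` is solved so the male true BMD50 is 4.631
  mg/kg, the geometric centre of the interval reported for this study; the
  level-specific `b` follow from the top-dose anchors. Under the
  shared-shape constraint these span anchors force the female true BMD50 to
  ≈ 14.97 mg/kg (≈ 3.2× the male) — matching the reported female spans and
  the reported female BMDL simultaneously is not algebraically possible in
  a shared-c,d model, and the spans were given priority.
  (The low dose is 1.14 mg/kg per the study table; a 1.4 mg/kg figure
  appearing in some secondary text is treated as a typographical variant.)
* **Fiedler-like** (2-day Sprague-Dawley rat study): doses 0, 14.3, 28.5,
  57, 114 mg/kg/day, males, calibrated to the reported medium-only span —
  2.3 % at 14.3 mg/kg to 4.9 % at 114 mg/kg — with background 1.6 % and
  c = 3.5 (a shallow curve that approaches neither background nor plateau
  within the dosed range; true BMD50 ≈ 16.4 mg/kg).

The within-group log-variance defaults to 0.1 for both designs (log-SD
0.32, CV ≈ 33 %). This is a homoscedastic idealization: real micronucleus
counts at ~0.1 % frequency (a few micronucleated cells per 2000 scored)
carry much larger relative counting error than at 8 %, so the stand-in is
*more* informative at low doses than real data — its confidence intervals
are correspondingly tighter than those published for the original study
(ratio ≈ 1.5 here vs ≈ 2.6 there). Passing tests on this stand-in
demonstrate the correctness and calibration of the machinery, not agreement
with the unpublished animal tables. Counting error (binomial/Poisson in
cells scored) is deliberately not simulated, since the analysis path is
continuous-lognormal.

The design-comparison harness contrasts the two studies as they were run
(each design with its own calibrated curve): the medium-only study's weak
log-scale signal (≈ 2-fold total rise against the same noise) is what
produces its wider BMD confidence intervals. A shared-curve mode that puts
one curve under both dose layouts is also available; note that on a shared
curve the higher-dosed five-group layout spans more of the response range
and is, if anything, the more informative design — the imprecision of the
medium-only study is a property of its response span, not of its dose grid.

## Problem sizes used in the checks

The simulation-based checks use 200 replicates for profile-CI coverage and
for likelihood-ratio null calibration (null design: two identical levels,
n = 50/group, var = 0.05, doses 0/1/4/16), 100 replicates per arm for the
design comparison in the test suite (40 in the acceptance script), and
reduced replicate counts (10–20) for smoke-level recovery trends.

## Known limitations

* Only the full four-parameter models are fitted; PROAST-style nested
  sub-model selection within a family is stubbed out.
* Decreasing dose–responses are out of scope (`c > 1` enforced); the
  endpoint modelled is induction only.
* Profile coverage is asymptotic (χ² calibration); at n = 5/group it is
  accurate to within a few points but not exact.
* One categorical covariate at a time; no model averaging or bootstrap CIs.
* The bundled species table carries only rat and the human identity row.
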