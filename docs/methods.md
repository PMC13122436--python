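# Methods

`otolife` reconstructs juvenile life histories of fall-run Chinook salmon
from archival-structure chemistry and quantifies size-selective mortality
between sequential sampling points along the migratory corridor. This note
documents the models, the parameter choices that matter, and what the
synthetic data generator does and does not emulate.

## Threshold reconstruction of habitat transitions

A laser transect along the otolith's dorsal axis yields an ordered series of
(radius, ⁸⁷Sr/⁸⁶Sr, SrV) measurements, chronological from the core. Because
the natal river (American River, AME) sits isotopically above every other
salmon river in the basin, two water reference values convert the series
into habitat transitions:

* **Natal exit** = first *downward* crossing of the AME minimum water value
  (0.7085), located by linear interpolation between neighbouring
  measurements.
* **Freshwater exit** = first *upward* crossing, after natal exit, of the
  estuary-boundary mean (0.70785); the profile then rises to the marine
  value (0.70918).

Fallbacks, in order of the information available:

| situation | rule |
|---|---|
| juvenile caught upstream of the estuary boundary, no downward crossing | total otolith radius is the natal-exit size |
| adult or Bay-caught fish, no downward crossing (rapid migrant) | freshwater-exit radius doubles as natal exit (zero Delta growth) |
| ratio never crosses the estuary boundary | upward crossing of 52% of the within-fish min-max-normalised SrV range (ocean water is Sr-rich) |
| fish sampled at the estuary boundary | measured fork length is the freshwater-exit size |
| fish measured in the natal-river trap | measured fork length is the natal-exit size |

Numerical conventions: a measurement exactly at a threshold counts as a
crossing at its own radius (keeps the crossing radius continuous in the
data); only the first qualifying crossing is used, with an optional
minimum-run filter (k consecutive points beyond the threshold, default
k = 1, off) to discount transient noise; analytical 2SE values are carried
through but not used in detection. SrV is normalised over the whole
measured transect by default; a freshwater-only window is available as an
option since the convention is not uniquely determined. Reconstruction is
invariant to measurements added beyond the ocean plateau (adult transects
are truncated near 1000 μm).

## Back-calculation of size and mass

Fork length (mm) from otolith radius OR (μm) uses the published broken-stick
regression

    FL = 0.021259·OR + 31.08748   (OR < 256)
    FL = 0.165660·OR − 5.8799     (OR ≥ 256)

whose branches agree to < 0.001 mm at the joint (≈ 36.53 mm). The inverse
map is the exact piecewise-linear inverse. Mass is a configurable strictly
increasing allometric curve m = a·FL(OR)^b (defaults a = 10⁻⁵ g/mm³,
b = 3); the radius→mass curve used originally is published only as a
figure, so the functional form is a package choice — but every quantity
interpreted downstream is a mass *fraction*, which is invariant to a and
robust to b. Freshwater growth is split at the natal-exit radius: mass
gained from the emergence radius (215 μm) to natal exit is natal, from
natal exit to freshwater exit non-natal, then normalised to their sum. The
emergence baseline is evaluated through the same mass model at the
emergence radius, so a fish leaving at emergence has exactly zero natal
gain; the conventional 215 μm ↔ 30 mm emergence pairing is retained as
documentation (the FL regression itself evaluates 215 μm to 35.7 mm, an
inconsistency in the published pairing that fractions are insensitive to).

## Migratory phenotype model

Natal-exit sizes pool across all sampling points (a single global cutoff;
per-year cutoffs are deliberately unsupported). The workflow:

1. **Hartigan's dip test** for unimodality. The dip statistic — the sup-norm
   distance between the ECDF and the closest unimodal CDF — is computed
   with the greatest-convex-minorant / least-concave-majorant modal-interval
   algorithm, implemented from scratch and verified in the test suite
   against an independent linear-programming oracle that solves the
   defining minimisation directly. P-values come from bootstrap resamples
   of the uniform null (the asymptotically least-favourable unimodal
   distribution). Consequence worth knowing: calibration is exact for
   uniform data and *conservative* for any other unimodal shape (measured
   0/200 rejections at nominal 0.05 for normal samples of n = 200), so a
   rejection is trustworthy.
2. **Two-component normal mixture by EM**, hand-written for the 1-D case:
   five starts (one quantile-based, four random), convergence when the
   log-likelihood changes by < 10⁻⁸ (max 1000 iterations), degenerate
   (σ → 0) starts discarded. The fit is cross-checked against an
   independent EM implementation (scikit-learn) in the tests.
3. **Density crossing**: the cutoff is the root of w₁φ₁(x) = w₂φ₂(x)
   between the component means, found by bracketed root finding on the
   log-density difference (a quadratic, so the bracketed root is unique)
   to 10⁻⁶ mm. Heavily overlapping components (no sign change) raise.
4. **Classification**: early ⇔ natal-exit FL ≤ cutoff (boundary inclusive).
   A legacy 55 mm cutoff (≈ 398 μm) is reported alongside for cross-study
   comparison.

## Selection differentials

For initial sample z and survivor sample z*, the standardized differential
is i = (z̄* − z̄)/s with s the initial sample's standard deviation
(n − 1 denominator). The defining equation is sometimes written with the
variance in the denominator, but the published per-segment values are only
reproduced under SD standardisation (the classical choice), so SD is the
default and `standardize_by="variance"` is an explicit option. Positive i
means smaller outmigrants survived worse. Segments per cohort year: Delta
(entering vs. leaving the Delta), Ocean (leaving the Delta vs.
cohort-matched adults), All (entering vs. adults); adults map to
outmigration year as escapement year − age + 1. Differentials are regressed
(OLS, linear and quadratic) on log₁₀ mean Jan–June natal-river flow, mean
Delta-entry size, and log escapement the previous fall.

The catch-expansion sensitivity tool resamples otolith-sampled fish, within
1-, 3- or 4-month bins, with replacement proportionally to the observed
catch per bin; bins with catch but no samples merge into the subsequent bin.

## Cohort demography

Carcass surveys skip fin-clipped fish, so hatchery-assigned sample counts
are expanded by the exact reciprocal 1/(1 − marking rate) (1.333… at the
25% default; the conventional factor 1.33 is display rounding only).
Natural escapement = total escapement × natural fraction. The cohort
replacement rate of brood year B sums age-weighted natural returns in
B+2..B+4 over natural spawners in B; missing age fractions are imputed with
the cross-year mean, and an age-3-only variant avoids the age assumptions
entirely. Return ages use scale reads when present, otherwise age 3 with
fork-length overrides (< 57 cm → 2, > 100 cm → 4).

## Provenance rules

Class probabilities over candidate natal sources are an *input* (produced
upstream by a trained classifier in real use). The deterministic layer on
top: eye-lens natal δ³⁴S prescreen (≤ 10.5‰ candidate wild; > 16‰ analysed
anyway to rule out brackish-water rearing of displaced fry); juvenile
constraints (fry < 55 mm are natural origin; sampling before a hatchery's
first release excludes that hatchery; southern-tributary sources excluded
at the upstream trawl) applied by zeroing the violated source's probability
and renormalising; then the exogenous-check rule moving weakly
hatchery-assigned fish (p < 0.8) with sharp feeding checks (> 1.5) to the
wild natal source — never the reverse, which measurably misclassifies wild
fish. Constraints run before the exogenous step; every fired rule is
recorded per fish.

For synthetic data a stand-in classifier supplies the probabilities:
softmax over sources of minus the distance between each source's reference
water value and the mean early-transect ratio, windowed to 100–250 μm. The
window's upper bound sits below the smallest back-calculable natal-exit
radius (256 μm), so it reflects natal water even for the earliest migrants
— without this the earliest migrants are systematically misassigned to the
on-river hatchery, which biases the analysis set and manufactures spurious
selection (the same failure mode the original workflow addressed by
training on simulated early-migrant profiles).

## Synthetic cohort generator

The generator is the exact inverse of the reconstruction and defines the
study conditions for all statistical tests:

* Natal-exit FL: mixture of an early (fry) component N(40.5, 3.0) with
  weight 0.7 and a late (smolt) component N(70, 8), truncated at
  ≥ 36.6 mm. The truncation exists because the printed broken-stick maps
  fork lengths below its branch joint (36.53 mm) to radii far inside the
  pre-emergence core (33 mm → 90 μm < 215 μm), so smaller fry sizes are
  not representable under the regression's inverse.
* Freshwater-exit FL: N(80.1, 9.38) (the observed ocean-entry
  distribution), floored at natal exit + 5 mm for Delta-rearing fish. Half
  the late migrants (and all hatchery smolts) are rapid migrants with
  freshwater exit = natal exit.
* Profiles: natal-river baseline 0.7092 (hatchery 0.70875), Delta value
  0.7070, ocean 0.70918; piecewise-linear transitions of 30 μm positioned
  so the noiseless series crosses each threshold exactly at the true exit
  radius; 10 μm spot spacing; ratio noise SD 10⁻⁴ (7σ below any threshold
  margin); SrV ramps 1 → 3 through the 52% point exactly at freshwater
  exit. Spot spacing and noise are package choices; the source data report
  neither.
* Survival: logistic in natal-exit FL per segment,
  p = expit(logit(p₀) + β(FL − 47)), defaults p₀ = 0.3, β = 0.06 /mm
  (Delta) and p₀ = 0.03, β = 0.03 /mm (ocean). A survival model is not
  specified by the study; this is the minimal mechanism that produces
  segment-wise differentials of the observed order (Delta i ≈ 0.5–1.7 SD
  units) while keeping each sampling point a survivor subset.
* Observation: lethal catches of fixed size per point (100 entry, 60
  seine — early migrants 4× more catchable, matching the seine's bias
  toward margin-rearing fry — 60 exit, 400 carcass), juvenile monitoring
  and carcass surveys both restricted to unmarked fish; eye-lens δ³⁴S
  N(7, 1.5) wild vs. N(14, 1.5) hatchery around the 10.5‰ screen; 25%
  hatchery marking; return ages 2/3/4 with probabilities 0.1/0.7/0.2.

What the generator does **not** emulate: vateritic or otherwise unreadable
otoliths, estuarine (brackish) rearing signatures, flow-dependent phenotype
expression or survival, tag-based abundance, and inter-annual parameter
drift (cohorts are exchangeable unless configured otherwise). Passing tests
therefore demonstrate that the estimators recover known structure under
clean, correctly specified conditions — not that the thresholds or the
mixture model are robust to field messiness.

## Problem sizes and determinism

Default test/analysis sizes: cohorts of 2 000–20 000 fish, transects of
40–90 spots, 200–2 000 bootstrap resamples for the dip null, 20-seed
parameter-recovery sweeps. One `numpy` Generator seeded at the top drives
every stage; identical config + seed gives byte-identical outputs (tested).

## Known limitations

* The radius→mass curve's true coefficients are unavailable; only mass
  fractions should be interpreted.
* The stand-in classifier is far simpler than the trained assignment model
  it replaces and is only meant to exercise the rule layer.
* The dip test's bootstrap p-values are exact only against the uniform
  null; for other unimodal shapes the test under-rejects.
* Absolute selection differentials for segments anchored at the in-river
  trap can be overstated when the trap sits upstream of the isotopic
  breakpoint; the catch-expansion tool exists to probe exactly this.
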