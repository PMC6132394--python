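# Methods

## Data model

The unit of observation is one analyte concentration in one annual pool
sample: all specimens of one type collected at one site in one year,
homogenised into a single analytical sample. A record carries its unit
(mg/kg, µg/kg, ng/kg or pg/g, bridged by exact powers of ten; pg/g ≡ ng/kg),
its basis (wet, dry or lipid weight — carried as metadata and only ever
changed by an explicit conversion), a censoring flag (a censored value
stores the LOQ and means "at or below LOQ") and, for mussel soft-body
pools, the matrix fractions: tissue water content *w* and breathing-water
share *b* of the pooled wet weight. Series may have year gaps (biennial
sampling is common); nothing downstream imputes missing years.

## TEQ aggregation

TEQ = Σᵢ TEFᵢ·c̃ᵢ over a congener panel, where c̃ᵢ is the measured value for
quantified congeners and, for censored ones, LOQᵢ (upper bound), LOQᵢ/2
(middle) or 0 (lower). The upper bound is the regulatory default and the
package-wide convention; the three bounds are always ordered lower ≤ middle
≤ upper with equality exactly on censor-free panels. TEF values are the
WHO-2005 re-evaluation (29 congeners; reference congener 2,3,7,8-TCDD has
TEF 1), shipped as a JSON config with provenance recorded in outputs, so a
future TEF revision is a config change. Class tags (dioxin / furan /
dl-PCB) support the PCDD/F-only sub-sum that food regulation limits
separately from the full PCDD/F + dl-PCB TEQ. The same bound switch applies
to plain congener sums (e.g. Σ6 ndl-PCB) for consistency.

## Conversions

All conversions are linear in the concentration: breathing-water correction
multiplies by 1/(1−b) (b = 0.58 → 2.381; b = 0.67 → 3.030), wet→dry divides
by the dry-mass fraction 1−w, dry→wet multiplies by it, lipid normalisation
divides by the lipid fraction. Stored values are never rounded;
presentation rounding (factors to one decimal, thresholds to two) lives in
the report layer only. A dry-mass-based conversion (e.g. a 17.38 % dry-mass
content) is expressed through the same operation with w = 1 − dry-mass
fraction rather than a second formula.

## Threshold compliance

The registry holds one entry per (analyte, matrix class, kind, protection
goal): food maximum levels (kind ML, externally sourced from Reg. (EC)
No. 1881/2006 and its amendments — regulation values change, so they are
config, not code), WFD biota EQS values (9.1 µg/kg PFOS, 0.0085 µg/kg ΣPBDE,
167 µg/kg HBCDD for secondary poisoning alongside the 6100 µg/kg
human-health quality standard), the OSPAR EAC of 12 µg/kg dry weight for
TBT in bivalves, and the Norwegian 150 µg/kg ww TBT standard. Comparison
reconciles units exactly and bridges a wet/dry basis mismatch through the
site's mean water content — the dry-weight threshold is expressed on the
wet-weight scale of the data (12 µg/kg dw → 1.13 µg/kg ww at 90.6 % water).
Every conversion is logged in the flag's `basis_note`. Status is
"exceedance" only for ratio strictly > 1 (equality complies); a comparison
that cannot be reconciled (no water fraction, lipid basis) is
"not assessable", never silently guessed.

## Trend machinery

**Smoother.** LOESS with the window fixed in *years*: the fit at target
year t is a weighted least-squares line over observations with
|year − t| ≤ 3.5 (7-year width; the name of the tool class says width in
years, so the window is a time span, not a nearest-k-points rule), tricube
weights in the scaled distance. When a window holds fewer than three points
(sparse biennial series, edge years) it widens symmetrically to the third
nearest observation so every local fit stays solvable. Local degree 1 with
tricube weights are the classical LOESS defaults; a uniform-weight option
exists mainly because a full-span uniform window collapses the smoother to
the ordinary least-squares line, which the test suite uses as an exact
oracle. Each fitted value is a fixed linear combination of the
observations, so the smoother has an explicit hat matrix L with rows
summing to one (constants are reproduced exactly; adding a constant shifts
the fit by that constant).

**ANOVA decomposition.** Three nested fits — mean M0, straight line M1,
smoother M2 — give residual sums of squares RSS0 ≥ RSS1 ≥ RSS2. The
smoother's model degrees of freedom are tr(L) (first-order approximation,
standard in this style of assessment; the two-trace correction
2 tr(L) − tr(LLᵀ) is a known refinement not used here), leaving residual
df = n − tr(L) and residual variance s² = RSS2/df. Then

    F_linear    = (RSS0 − RSS1) / s²              ~ F(1, n − df₂)
    F_nonlinear = (RSS1 − RSS2) / (df₂ − 2) / s²  ~ F(df₂ − 2, n − df₂)

with df₂ = tr(L). The non-linear component is reported as not applicable
when the smoother is no rougher than a line (df₂ ≤ 2). A series needs ≥ 7
points for the ANOVA (≥ 5 for the bare smoother). "Significant" means
p ≤ α with α = 0.05 by default, configurable. With n = 15 annual values and
the 7-year window, tr(L) ≈ 4, leaving ~11 residual df; the Monte-Carlo
calibration below shows the linear test holds its nominal level to within
the band expected of the trace approximation.

**Contrast test.** The difference of smoothed values at two years a, b is
Δ = (l_b − l_a)·y with variance s²·‖l_b − l_a‖², referred to a t
distribution on the smoother's residual df. Spans shorter than seven years
are refused outright — over a short span the difference is dominated by
local noise and the assessment convention is not to interpret it.

**Linear trend line.** Ordinary least squares on the raw concentration
scale (not log: declining series can have trend lines crossing zero before
the final year, and that negative calculated endpoint is the signal
"not detected" — impossible on a log scale; a log option would forfeit that
semantics and is deliberately absent). Reported per series: slope, the
line's values in the first and last sampling year, the percent change
between them, and the ratio max/min between the calculated and measured
final-year values. A ratio ≥ 2 (configurable) flags series where the trend
line does not represent the last year, in which case compliance is assessed
on the measured value as well.

**Censoring in fits.** Censored points enter trend fits at their LOQ
(consistent with upper-bound aggregation); LOQ/2 is available as an option.

## Mann-Whitney site comparison

U = min(U1, U2) from midrank sums. For tie-free pooled samples of at most
16 values the two-sided p is exact: twice the enumerated one-tail
probability P(U1 ≤ u) over all C(n1+n2, n1) rank assignments, capped at 1
(the null distribution of U1 is symmetric, so either tail doubles to the
same value). Larger or tied samples use the normal approximation with
tie-corrected variance and continuity correction. Two-sided throughout:
between-site differences matter in either direction. Site comparisons pool
annual values unpaired over the overlapping year range only, so neither
site is advantaged by years the other did not sample. No multiple-testing
correction is applied across analytes; the per-analyte p-values are
reported as-is.

## Synthetic data generator

Series follow c(t) = c₀·e^(−kt) plus an optional symmetric hump
(zero at both ends, peaking mid-series) for non-linear-trend studies;
observations are c(t) times mean-one lognormal noise with coefficient of
variation `noise_cv` (multiplicative, scale-free, respecting positivity and
right skew of concentration data); values below the LOQ are emitted at the
LOQ with the censoring flag set. Congener panels draw lognormal
concentrations per TEF-table congener with independent censoring. Both
return generator-side ground truth (mean curve, censoring count,
term-by-term TEQ sums) computed independently of the library code they are
used to test. Everything is driven by a single integer seed;
identical seeds give bit-identical records.

The packaged demo campaign mirrors a three-site mussel + eelpout design:
sites NS1/NS2/BS with mussel water contents 90.6/92.6/94.7 % and
breathing-water shares 67/58/67 %, mussel soft-body series 1985–2017
(TBT 1988–2013), eelpout fillet metals 1994–2017 annually and organics
biennially 2003–2015 plus 2016–2017. Concentration scales are plausible for
coastal biota and sit below the food maximum levels, with two deliberate
exceptions wired into the design: PBDE above its (very low) biota EQS at
all sites in all years, and early PAH/TBT levels high enough that
breathing-water-corrected or EAC comparisons catch them. Noise CV defaults
to 0.2, a typical between-year variability for annual pools.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: between-analyte correlation within a pool, analytical
batch effects and changing LOQs over decades, autocorrelated environmental
forcing (years are independent given the mean curve), species/size/lipid
covariate structure, and any attempt to match a real programme's actual
concentration magnitudes beyond order of magnitude.

## Monte-Carlo calibration (computed by the acceptance script and tests)

Type-I error of the linear-component test: 2000 null series of 15 annual
values with lognormal CV 0.2 at α = 0.05 (the package's study conditions;
n = 15 is a typical monitoring series length, CV 0.2 as above). Power:
500 replicates of a 50 %-per-decade exponential decline (k = ln 2/10 per
year) under the same noise. Problem sizes were chosen so the full study,
suite and acceptance script, runs in seconds on one CPU while keeping
Monte-Carlo standard errors near half a percentage point.

## Numerical choices and degenerate inputs

* Tricube weight exactly at the window boundary is zero; the widened
  window multiplies the third-nearest distance by (1 + 1e-9) so the
  boundary point keeps positive weight and the 2×2 local system stays
  non-singular. If all usable weight falls on one abscissa the local fit
  degrades to the weighted mean.
* A constant series yields a constant fit with s² = 0; an exactly linear
  series yields RSS2 = 0, in which case the linear F is reported as
  infinite with p = 0 rather than 0/0.
* Duplicate (series, year) records with identical values collapse to one
  point; with conflicting values they are an error, never averaged.
* Units convert by exact decimal factors; mixed-unit series are converted
  to the first-seen unit at assembly.
* Exceedance at exactly ratio 1 is compliant (strict inequality).

## Known limitations

* The trace-based smoother df makes the ANOVA F reference approximate; the
  empirical level at the default settings sits near 5–7 % rather than
  exactly 5 %.
* Censored values substituted at the LOQ bias fitted trends upward late in
  a decline when censoring concentrates there; no likelihood-based
  censoring model is provided.
* Threshold matching is by (analyte, matrix class) tags; mapping species
  and tissues to regulatory product categories is configuration, and no
  legal interpretation of amendment applicability is attempted.
* The wet/dry bridge uses one mean water content per site; within-series
  variation in water content is not propagated.
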