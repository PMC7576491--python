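# Methods

## Exposure metric

Each PM2.5 filter sample carries concentrations (ng/m³) of 15 priority PAH
congeners (the 16 EPA congeners minus naphthalene, which is almost entirely
gas-phase; the exclusion is configurable). The carcinogenicity-weighted
exposure is the BaP-equivalent concentration BaPeq = Σ Cᵢ·TEFᵢ. Default
TEFs follow the Nisbet & LaGoy scheme with one deliberate deviation:
dibenz[a,h]anthracene is assigned TEF 1 rather than 5. At TEF 5 even trace
DahA dominates the BaPeq budget, which is inconsistent with
benzo[b]fluoranthene being the second-largest contributor in
coal-combustion profiles of this kind; TEF tables are fully overridable
through the config file, so users holding the opposite view lose nothing.

The weight dichotomy is binary: the six five- and six-ring congeners (BbF,
BkF, BaP, IcdP, DahA, BghiP) are classed HMW and everything else LMW. This
matches the convention of reporting "the six high-molecular-weight species"
as a block in particulate studies; chemists who class the 228 Da isomers
(BaA, Chr) as HMW should read LMW here as "four rings and below".

## Sample validity and nondetects

Personal pump samples are valid only with 22–26 h of pump operation
(inclusive); fixed-site samplers are never duration-filtered. Nondetects
("ND" or blank cells) are stored as 0 with a retrievable flag — zero
substitution is the convention the data's printed ranges imply — and an
LOD/2 substitution is available as an option. Sample standard deviations
use the n−1 denominator throughout; a single-sample season reports its sd
as NaN rather than 0.

## Dosimetry

IR (m³/day) = TV (L) × BF (min⁻¹) × 1.44, the exact unit conversion
1440 min/day ÷ 1000 L/m³. LADD = C·EF·ED·CF·IR/(BW·AT) in mg·kg⁻¹·day⁻¹
with CF = 10⁻⁶ mg/ng; doses are also reported in ng·kg⁻¹·day⁻¹ as a
presentation convenience. ILCR = SF·LADD with SF = 3.14 (mg kg⁻¹ day⁻¹)⁻¹,
the standard BaP inhalation slope factor; the exceedance flag is strict
(risk exactly at 10⁻⁶ does not exceed). The averaging-time invariant
AT ≥ EF·ED is enforced at construction.

Default scenario constants: EF 140 day/yr (heating) / 220 day/yr
(non-heating), ED 10 yr, AT 25500 day (70-yr carcinogenic averaging).

## Monte Carlo engine

Per season the uncertain parameters are:

| parameter | heating | non-heating | kind |
|---|---|---|---|
| BaPeq (ng/m³) | LN(2.7, 0.4) | LN(−2.4, 1) | lognormal, natural-log params |
| IR (m³/day) | N(35.1, 15.0) | N(42.1, 12.5) | normal, truncated at 0 |
| BW (kg) | N(29.9, 5.6) | N(29.9, 5.6) | normal, truncated at 0 |

Lognormal parameters are the mean and sd of natural-log-transformed data
(LN(2.7, 0.4) has arithmetic mean e^{2.7+0.08} ≈ 16.1 ng/m³, matching the
measured heating BaPeq level; a base-10 reading would give ~766 and is
untenable). The non-heating exposure entry is treated as lognormal with
log-mean −2.4 and log-sd 1 (arithmetic mean ≈ 0.15 ng/m³), consistent with
the measured non-heating BaPeq of ~0.2 ng/m³.

Each iteration draws C, IR, BW independently, in that fixed order, from one
`numpy` generator seeded by the scenario seed, so identical specs give
bit-identical draw vectors. Normal parameters are truncated at 0 by
resampling: IR with sd 15.0 on mean 35.1 would otherwise produce negative
inhalation ~1% of the time, and resampling perturbs the stated mean less
than clipping or folding. No correlation structure is imposed between C,
IR and BW. Default iteration count is 10,000.

Under these choices the heating-season exceedance of 10⁻⁶ computes to ~0.92
rather than any smaller figure a different truncation/rounding convention
might give; the package reports the computed value and additionally asserts
only the robust qualitative contract (heating exceedance > 0.5, non-heating
< 0.05).

Distribution selection for measured exposure values fits a normal to the
raw data and a normal to the natural logs (both maximum likelihood) and
selects the family with the larger one-sample Kolmogorov–Smirnov p-value
against the fitted distribution. The K-S p-values with estimated parameters
are optimistic (Lilliefors effect) but are used only for model selection,
where the bias applies to both candidates.

## Diagnostic-ratio classification

Ratios are A/(A+B) for the five conventional isomer pairs; a pair summing
to zero yields an undefined (NaN) ratio, which is a value, not an error.
Classification uses BaA/(BaA+Chr) (<0.2 petroleum, >0.35 coal/biomass) and
IcdP/(IcdP+BghiP) (<0.2 petroleum, >0.5 coal/biomass). The cited threshold
inequalities are strict, leaving the boundary points unassigned; boundary
values are placed in the closed middle ("mixed") interval. The combined
verdict is the agreement of the two labels, "mixed" on disagreement, and
defers to the defined one when a single label is indeterminate. I/O ratios
of exactly 1 are likewise indeterminate.

## Synthetic cohort generator

The generator emulates a two-season personal-monitoring campaign at a
coal-heated school: four season-by-sex participant groups (7/9 heating
boys/girls, 12/10 non-heating; heights, weights and spirometric IRs drawn
from the groups' normal distributions, with TV and BF chosen so TV·BF·1.44
reproduces the IR draw exactly), one personal sample per participant (38
total), and two indoor/outdoor fixed-site pairs per season.

Concentrations are built top-down: each sample's total PAH is drawn from a
lognormal moment-matched to the season target (heating mean 89.1, sd 47.3;
non-heating mean 1.75, sd 0.9 ng/m³ — the non-heating sd is a generator
choice at CV ≈ 0.5, mirroring the heating CV, since no seasonal sd is
available), then split across congeners by a season composition profile
with multiplicative noise, with isomer-pair masses re-split by ratios drawn
around the diagnostic targets. Drawing the total first and splitting it is
what guarantees the weight-class and diagnostic-ratio targets jointly;
independent per-congener draws would not.

The heating profile puts 56% of mass in the six HMW congeners, BaP at a
share giving a season mean near 10.3 ng/m³ (per-sample BaP drawn from
N(10.3, 4.79) truncated to [3.86, 21.86] and capped at 35% of the sample
total for coherence), and BbF large enough that it remains the second
BaPeq contributor after BaP. Heating diagnostic draws are
BaA/(BaA+Chr) ~ N(0.46, 0.03) on (0.41, 0.60) and IcdP/(IcdP+BghiP) ~
N(0.51, 0.02) truncated to (0.501, 0.557) — the lower bound keeps every
heating sample strictly in the coal/biomass class that the season's source
structure dictates while staying within the 0.51 ± 0.06 band. The
non-heating profile is LMW-dominated (Ant 23%, Phe 15%, Fla 14%), BaP is
uniform on [0, 0.01] ng/m³, and both classifying ratios are drawn in
petroleum territory (mostly < 0.2). Heating fixed-site pairs have
indoor/outdoor ratios in (1.2, 3.0) for every congener except Acy
(≤ 1); non-heating pairs sit in (0.4, 0.9) throughout. PM2.5 is drawn
around the season mean (230 / 168 ng/m³, in the units as printed) and
floored at 1.05× the sample's PAH total.

Shares beyond the printed ones are generator choices; `ground_truth.csv`
records every target with a `source` column (`study` vs `generator`), and
the recorded seed regenerates the bundle byte-for-byte.

What the generator does **not** emulate: within-child correlation between
seasons (each season gets an independent cohort), meteorology or
time–activity patterns, measurement error and recovery variation, or
between-congener correlation beyond the composition profile. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
not that field data satisfy those assumptions.

## Numerical choices and problem sizes

- Test simulations use 10,000 iterations (the analysis default); the
  moment-convergence checks use 100,000 draws against quadrature closed
  forms at 2% relative tolerance.
- Parameter-recovery tests generate 10,000-participant cohorts; recovery is
  asserted within 3 standard errors of the generating values.
- Degenerate inputs are flagged, not raised, wherever "undefined" is
  scientifically meaningful: zero-total BaPeq shares, 0/0 diagnostic
  ratios, constant vectors in correlation or distribution fitting,
  zero-variance paired tests.
- CSV round-trips are exact to 6 significant digits (`%.6g`).

## Limitations

- Inhalation is the only exposure route; dermal and dietary PAH intake are
  out of scope, so absolute risks are route-specific lower bounds.
- The TEF scheme, slope factor and acceptable-risk threshold are
  conventions; risk levels shift proportionally under alternatives (both
  are configurable).
- Diagnostic-ratio source attribution is semi-quantitative; no receptor
  modelling (PMF/CMB) is attempted.
- The deterministic per-participant path treats each child's single
  personal sample as their season-long exposure concentration.
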