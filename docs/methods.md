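# Methods

`seascreen` implements a screening-level risk pipeline for chemical
contaminants in edible seaweeds: from long-format, left-censored tissue
concentration surveys to exceedance flags, site-specific consumption
advisories and per-portion diet comparisons.  This note records the model,
its parameters, the design choices made where the design was genuinely
open, and the limits of what the synthetic tests demonstrate.

## Concentrations, units and censoring

A measurement is one analyte concentration for one site × species ×
collection date, in mg/kg or µg/kg on a dry-weight (DW) or wet-weight (WW)
basis.  The canonical internal representation is **mg/kg DW**; unit
conversion (exact factor 1000) and basis conversion
(`C_ww = C_dw · (1 − m)` with moisture fraction m) happen once at ingest.
Wet-basis rows without per-sample moisture or a per-species default fail
loudly per row — nothing is imputed.  A quantified value below its stated
LOQ is accepted with a warning rather than rejected, because lab exports
occasionally contain such rows.

Values below the lower limit of quantitation (LOQ) are left-censored.
Every downstream statistic substitutes censored values by `f · LOQ` with
`f ∈ {0, ½, 1}`; the half-LOQ policy is the default (moderately
conservative from a consumer's standpoint).  Substitution happens at the
individual congener level *before* group summation.  Because substitution
is linear, for any mean or sum the zero and full-LOQ results bracket the
half-LOQ result, and the half-LOQ sum is exactly the midpoint of the other
two — both facts are enforced as exact tests.  Maximum-likelihood or
Kaplan–Meier censored estimators are deliberately out of scope: simple
substitution is the procedure being implemented, and its policy
sensitivity is surfaced (via `bound_interval` and the three-policy sum
report) rather than modelled away.

Summary conventions: sample SD (n−1); even-length medians by midpoint;
percent-above-LOQ stored unrounded, displayed to the nearest integer and
capped at 100; an n = 1 series reports SD 0 with a degenerate flag so
single-site pilot tables still render.  Display rounding is 3 significant
figures; internal math is never rounded.

## Group sums and toxic equivalents

Congener groups (the 40-congener PCB sum, 11-congener PBDE sum, the
4,4′-DDT family, chlordanes, chrysenes, and the 17-congener PCDD/F toxic
equivalent) are configuration, not code: the shipped analyte registry
declares members and mode, and users can edit the lists to match a lab
panel.  TEQ mode weights each congener by its WHO-2005 toxic equivalency
factor relative to 2,3,7,8-TCDD.  A sample missing a declared member is an
error, never a silent zero.  Summation order is fixed (ascending
analyte id) so floating-point output is permutation-invariant.  Whether
the DDT total should include the 2,4′ isomers is ambiguous in the source
material (summaries list only 4,4′ forms); the fixture includes the three
4,4′ forms only.  An optional linear estimator of total PCBs from a
measured subset sum is provided without default coefficients, since those
are calibration constants of a particular monitoring program.

## Screening levels

For an analyte with an oral reference dose RfD (mg per kg body weight per
day) the noncancer screening level in seaweed tissue is

    SL_RfD = RfD · BW / CR · 1000        [mg/kg DW]

and for a cancer slope factor CSF ((mg/kg-day)⁻¹) at acceptable excess
lifetime cancer risk ARL,

    SL_CSF = (ARL · BW / CSF) / (CR / 1000)   [mg/kg DW]

with defaults BW = 80 kg, CR = 5 g DW/day (a typical meal-sized seaweed
portion) and ARL = 1×10⁻⁶.  Both are linear in BW and inversely
proportional to CR (doubling CR halves every level — tested exactly).

Toxicity constants are shipped as a frozen data registry, not fetched
live: agency databases drift over time, and reproducing a fixed survey's
levels requires era-appropriate constants.  Each registry entry is
back-derived from the screening level it must reproduce at the default
parameters and annotated with the IRIS chemical it corresponds to; several
of the back-derived slope factors land exactly on well-known IRIS values
(heptachlor 4.5, dieldrin 16, aldrin 17), corroborating the derivation.
`seascreen registry lint` recomputes every level and checks it against the
expected value stored beside the constant, at that value's printed
precision — this check *is* the registry's definition of correctness.
Unspeciated metals conservatively use the speciated surrogate (methyl Hg
for total Hg, inorganic As for total As, Cr(VI) for total Cr, V pentoxide
for V); the surrogate note propagates into every report.

Exceedance uses strict inequality on unrounded values (a rate that rounds
to the baseline can still bind).  Lead has no RfD or CSF; it is screened
against international limits only.  The lowest applicable international
limit is chosen per analyte on the dry basis, converting wet-basis limits
with per-sample moisture (or a per-species default, 0.85 for the kelp);
limits whose basis is unspecified in the source are stored but excluded
from comparisons.  Ties break alphabetically by jurisdiction.

## Consumption advisories

Solving the screening equations for CR with the level set to the measured
concentration gives the maximum consumption rate

    rate = baseline_CR · reference / conc     [g DW/day]

per site, species, date and contaminant; the minimum over the advisory set
is the binding rate.  The default advisory set and references are: Cd and
total Hg against their noncancer levels, benzo[a]pyrene and the PCB sum
against their cancer levels (the stricter of their two levels at these
parameters), and Pb against the French 5 mg/kg DW limit.  The French
rather than the lowest (Chinese, 1 mg/kg DW) Pb limit is the default
because it reproduces the published advisory table; the Chinese limit is
one flag away (`--limit-source China`).  Display rounds half-to-even to
one decimal and caps at "≥ baseline"; binding decisions use unrounded
rates.  Advisories are computed from the half-LOQ policy by default,
matching how the reported PCB sums were built.  Child-specific advisories
(lead biokinetic modelling) are out of scope.

## Diet comparisons

Per-portion amounts are `conc · portion_mass / 1000` mg: seaweed at 5 g DW
per portion, foods at their customary wet-weight portion masses; the two
bases are never mixed without labelling.  Per species × contaminant, sites
whose per-portion amount strictly exceeds the across-site mean + 2 SD are
flagged as statistical outliers and a trimmed mean/SD excluding them is
reported for the remaining-sites bar.  Flagging is single-pass by design —
one mean + 2 SD computation, no iteration.  A single pass can miss
visually obvious outliers when the outlier itself inflates the SD (with
n = 5, a lone extreme value can *never* exceed mean + 2 SD, since its
z-score is bounded by (n−1)/√n ≈ 1.79); an optional iterated mode reapplies
the rule to the unflagged remainder until stable, default off.  The
shipped food registry mixes two surveyed shellfish Cd values with
synthetic illustrative placeholders (marked as such) — it is editable
context, not an authoritative diet database.

## Paired comparisons and trend tests

Species are compared at shared sites with classical paired t-tests
(two-sided p, n−1 df), Bonferroni-corrected across the family (0.05/3 ≈
0.017 for the three focal metals).  Normality of the differences is
checked (Shapiro–Wilk) and reported as a warning only; it never gates the
test.  Latitude and collection-date trends use Spearman rank correlation
with average-rank ties; dates enter as days-since-epoch ordinals, an
arbitrary but harmless choice since Spearman is invariant to any strictly
monotone encoding.  The implementation delegates to scipy; tests verify it
against hand-written closed-form, sign-flip-permutation and
rank-enumeration oracles.

## Synthetic surveys and what they show

The generator draws concentrations lognormally on the mg/kg DW scale
(positive, right-skewed, matching ranges that span >10× across sites),
applies multiplicative species effects, multiplies selected analytes at a
few planted "urban" outlier sites, and censors deterministically at the
LOQ (truth < LOQ ⇒ censored — LOQs are thresholds, not coin flips).  A
truth manifest records every uncensored value.  Identical config + seed
gives a bit-identical survey.

Default conditions (`salishlike_config`): 43 sites, a fucoid at 38 sites,
a second fucoid at 3, a kelp at 17 (16 shared with the first); metals on
all species with a 0.1 mg/kg DW LOQ, organics (benzo[a]pyrene and 40 PCB
congeners, LOQs 1.6 and 0.33 µg/kg) on the fucoids only; three planted
outlier sites at ×10.  Lognormal parameters are moment-matched to the
motivating survey's species means and SDs (total As fucoid mean 26.8,
kelp 72.5 mg/kg DW), kelp:fucoid median multipliers are the observed
paired differences (2.84 total As, 2.11 Cd, 2.51 total Hg), and the
mostly-censored analytes are parameterised so detection fractions land
near the observed ones (~18% Hg, ~25% Pb, ~26% of PCB congener
measurements).

Recovery scoring reports exceedance sensitivity/specificity against truth
at each policy, planted-outlier recall under the single-pass flagging
rule, and agreement between survey-based and truth-based binding
analytes.  What passing these tests shows: the pipeline's algebra is
correct and its decisions degrade gracefully under censoring.  What they
do **not** show: anything about real spatial covariance, temporal trends,
matrix effects, analytical error structure, or correlated congener
profiles — the generator draws congeners independently, which real
mixtures do not.

## Numerical choices

* Exceedance and binding: strict `>` on unrounded values.
* Rate display: round-half-to-even to one decimal; "≥5" when at/above baseline.
* Zero or censored-at-zero concentration inverts to an unbounded rate
  (∞, displayed "≥5"), not an error.
* Sig-figure display helper used for reporting only; comparisons in code
  are never made on rounded values except where a published cell *is* the
  rounded value.
* Group sums iterate members in ascending analyte-id order for
  reproducible floating point.

## Problem sizes

The test suite generates surveys of ~1,900 measurements (43 sites × 45
analyte models × up to 3 species) and scores recovery across 12 fixed
seeds; property tests run a few hundred randomized cases each.  The whole
suite completes in well under a minute on one CPU.

## Known limitations

* Substitution-based censoring only; no distributional censored estimators.
* No hazard-index summation across analytes, no probabilistic exposure.
* Total-PCB estimation from a congener subset requires user-supplied
  coefficients.
* The food registry is illustrative; per-portion comparisons inherit its
  quality.
* Arsenic is screened via the inorganic-As surrogate without speciation,
  so its exceedances are conservative upper bounds, not risk statements.
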