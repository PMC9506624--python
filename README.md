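# seascreen

Screening-level risk analysis of chemical contaminants in edible seaweeds.

Coastal seaweeds (fucoids, kelps) concentrate metals and persistent
organic pollutants from their environment.  Agencies and harvesters —
Tribes and First Nations, recreational foragers, small seaweed businesses
— need to know whether tissue concentrations at a harvest site warrant
limiting consumption.  `seascreen` implements the standard screening-level
workflow for that question, end to end:

* **Censored survey handling** — long-format site × species × date ×
  analyte tables with values below the limit of quantitation (LOQ)
  left-censored; substitution policies (0, ½·LOQ, LOQ) with exact
  bracketing of every mean and sum.
* **Congener aggregation** — configurable group sums (Σ₄₀PCBs, ΣPBDEs,
  ΣDDTs, chlordanes, chrysenes) and WHO-2005 TEF-weighted PCDD/F toxic
  equivalents.
* **Screening levels** — tissue concentrations corresponding to the oral
  reference dose (noncancer) or an acceptable lifetime cancer risk via the
  cancer slope factor, at assumed body weight and consumption rate:

      SL_RfD = RfD · BW / CR · 1000
      SL_CSF = (ARL · BW / CSF) / (CR / 1000)      [mg/kg DW]

  with defaults BW = 80 kg, CR = 5 g DW/day, ARL = 10⁻⁶, plus comparison
  against the lowest applicable international limit.
* **Consumption advisories** — inverting the screening equations per site
  for the maximum daily intake, `rate = CR · SL / conc`, and identifying
  the binding (most conservative) contaminant.
* **Diet context** — per-portion contaminant mass versus common foods,
  with a mean + 2 SD statistical-outlier flag for hot-spot sites.
* **Synthetic surveys** — a lognormal, deterministically-censored
  generator with planted outlier sites and a full truth manifest, so every
  stage is testable without any download.

## Worked example

```python
import seascreen as ss

params = ss.ExposureParams()          # BW 80 kg, CR 5 g DW/day, ARL 1e-6
toxrefs = ss.default_toxrefs()
print("SL_RfD(Cd)  =", ss.sl_rfd(toxrefs["Cd"], params), "mg/kg DW")
print("SL_CSF(PCB) =", 1000 * ss.sl_csf(toxrefs["SUM_PCB40"], params), "ug/kg DW")

levels = ss.screening_levels(toxrefs, params)
rate = ss.max_rate(conc=0.0646, reference=levels["BaP"].sl_csf, baseline_cr=5.0)
print("max rate    =", round(rate, 1), "g DW/day")
```

prints

```
SL_RfD(Cd)  = 16.0 mg/kg DW
SL_CSF(PCB) = 7.999999999999998 ug/kg DW
max rate    = 1.2 g DW/day
```

So a cadmium concentration up to 16 mg/kg dry weight is below the
noncancer screening level at a 5 g/day habit, the PCB sum screens at
8 µg/kg DW against a one-in-a-million cancer risk, and a site whose
benzo[a]pyrene tissue concentration is 64.6 µg/kg DW (0.0646 mg/kg)
supports at most **1.2 g DW/day** — about a quarter of a typical portion —
before the cancer-based level is exceeded.

The same pipeline runs from the shell:

```sh
seascreen simulate --seed 7 --out survey.csv     # synthetic 43-site survey
seascreen summarize survey.csv --policy half     # censored summary table
seascreen screen survey.csv                      # exceedance records
seascreen advise survey.csv                      # per-site advisories
seascreen registry lint                          # recompute all screening levels
```

`seascreen advise` output begins:

```
site_code,species,date,Cd,Hg,Pb,BaP,SUM_PCB40,binding_analyte,binding_rate
S01,F_distichus,2015-08-24,>=5,>=5,>=5,>=5,4.0,SUM_PCB40,4.021
S02,F_distichus,2015-08-16,>=5,>=5,>=5,>=5,3.6,SUM_PCB40,3.616
```

i.e. at site S01 every contaminant but the PCB sum supports at least the
baseline 5 g DW/day; PCBs bind the advisory at 4.0 g DW/day.

Registries (toxicity constants, international limits, congener groups,
food portions) are editable YAML shipped under `src/seascreen/data/`; see
`docs/methods.md` for the science, the parameter choices, and known
limitations.

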