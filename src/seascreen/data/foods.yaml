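# Common-food contaminant concentrations (mg/kg wet weight) and portion
# masses (g wet weight).  Illustrative, editable data for per-portion
# comparisons; not authoritative.
foods:
- food_name: Manila clam (uncooked)
  contaminant: Cd
  conc: 0.3
  portion_mass: 110
  citation: regional shellfish survey
- food_name: Miyagi oyster (uncooked)
  contaminant: Cd
  conc: 3.56
  portion_mass: 110
  citation: regional shellfish survey
- food_name: white rice (cooked)
  contaminant: Cd
  conc: 0.005
  portion_mass: 158
  citation: synthetic illustrative value
- food_name: spinach (raw)
  contaminant: Cd
  conc: 0.08
  portion_mass: 85
  citation: synthetic illustrative value
- food_name: beef liver (cooked)
  contaminant: Cd
  conc: 0.06
  portion_mass: 85
  citation: synthetic illustrative value
- food_name: marine fish (mixed)
  contaminant: SUM_PCB40
  conc: 0.012
  portion_mass: 227
  citation: synthetic illustrative value
- food_name: chicken (grilled, well done)
  contaminant: BaP
  conc: 0.0003
  portion_mass: 140
  citation: synthetic illustrative value
- food_name: steak (grilled, very well done)
  contaminant: BaP
  conc: 0.009
  portion_mass: 140
  citation: synthetic illustrative value
- food_name: marine fish (mixed)
  contaminant: tAs
  conc: 2.0
  portion_mass: 227
  citation: synthetic illustrative value
- food_name: tuna (canned)
  contaminant: Hg
  conc: 0.13
  portion_mass: 85
  citation: synthetic illustrative value
- food_name: root vegetables (mixed)
  contaminant: Pb
  conc: 0.01
  portion_mass: 85
  citation: synthetic illustrative value
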