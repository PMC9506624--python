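# Frozen oral toxicity constants (data, not code).
# rfd: mg per kg body weight per day; csf: (mg/kg-day)^-1.
# Values are back-derived from the screening levels they must reproduce
# at BW=80 kg, CR=5 g DW/day, ARL=1e-6 (the expected_sl_* fields;
# metals in mg/kg DW, organics in ug/kg DW) because agency databases
# drift over time; iris_chemical names the corresponding IRIS entry.
# `seascreen registry lint` recomputes and checks every expected value.
toxrefs:
- analyte_id: Cd
  rfd: 0.001
  iris_chemical: Cadmium (dietary)
  expected_sl_rfd:
    value: 16
    unit: mg/kg
- analyte_id: Hg
  rfd: 0.0001
  surrogate_note: methyl Hg used for total Hg
  iris_chemical: Methylmercury
  expected_sl_rfd:
    value: 1.6
    unit: mg/kg
- analyte_id: tAs
  rfd: 0.0003
  csf: 1.5
  surrogate_note: inorganic As used for total As
  iris_chemical: Arsenic, inorganic
  expected_sl_rfd:
    value: 4.8
    unit: mg/kg
  expected_sl_csf:
    value: 0.0107
    unit: mg/kg
- analyte_id: Cr
  rfd: 0.003
  surrogate_note: Cr(VI) used for total Cr
  iris_chemical: Chromium(VI)
  expected_sl_rfd:
    value: 48
    unit: mg/kg
- analyte_id: V
  rfd: 0.009
  surrogate_note: V pentoxide used for V
  iris_chemical: Vanadium pentoxide
  expected_sl_rfd:
    value: 144
    unit: mg/kg
- analyte_id: Ba
  rfd: 0.2
  iris_chemical: Barium
  expected_sl_rfd:
    value: 3200
    unit: mg/kg
- analyte_id: Be
  rfd: 0.002
  iris_chemical: Beryllium
  expected_sl_rfd:
    value: 32
    unit: mg/kg
- analyte_id: Mn
  rfd: 0.14
  iris_chemical: Manganese
  expected_sl_rfd:
    value: 2240
    unit: mg/kg
- analyte_id: Mo
  rfd: 0.005
  iris_chemical: Molybdenum
  expected_sl_rfd:
    value: 80
    unit: mg/kg
- analyte_id: Ni
  rfd: 0.02
  iris_chemical: Nickel, soluble salts
  expected_sl_rfd:
    value: 320
    unit: mg/kg
- analyte_id: Se
  rfd: 0.005
  iris_chemical: Selenium
  expected_sl_rfd:
    value: 80
    unit: mg/kg
- analyte_id: Zn
  rfd: 0.3
  iris_chemical: Zinc
  expected_sl_rfd:
    value: 4800
    unit: mg/kg
- analyte_id: aHCH
  csf: 6.3
  iris_chemical: alpha-HCH
  expected_sl_csf:
    value: 2.5
    unit: ug/kg
- analyte_id: bHCH
  csf: 1.8
  iris_chemical: beta-HCH
  expected_sl_csf:
    value: 8.9
    unit: ug/kg
- analyte_id: gHCH
  rfd: 0.0003
  iris_chemical: gamma-HCH (lindane)
  expected_sl_rfd:
    value: 4800
    unit: ug/kg
- analyte_id: Heptachlor
  rfd: 0.0005
  csf: 4.5
  iris_chemical: Heptachlor
  expected_sl_rfd:
    value: 8000
    unit: ug/kg
  expected_sl_csf:
    value: 3.6
    unit: ug/kg
- analyte_id: HPE
  rfd: 1.3e-05
  csf: 9.1
  iris_chemical: Heptachlor epoxide
  expected_sl_rfd:
    value: 208
    unit: ug/kg
  expected_sl_csf:
    value: 1.8
    unit: ug/kg
- analyte_id: HCB
  rfd: 0.0008
  csf: 1.6
  iris_chemical: Hexachlorobenzene
  expected_sl_rfd:
    value: 12800
    unit: ug/kg
  expected_sl_csf:
    value: 10
    unit: ug/kg
- analyte_id: SUM_CHLORDANES
  rfd: 0.0005
  csf: 0.35
  iris_chemical: Chlordane (technical)
  expected_sl_rfd:
    value: 8000
    unit: ug/kg
  expected_sl_csf:
    value: 46
    unit: ug/kg
- analyte_id: Mirex
  rfd: 0.0002
  iris_chemical: Mirex
  expected_sl_rfd:
    value: 3200
    unit: ug/kg
- analyte_id: Endosulfan
  rfd: 0.006
  iris_chemical: Endosulfan
  expected_sl_rfd:
    value: 96000
    unit: ug/kg
- analyte_id: Dieldrin
  rfd: 5.0e-05
  csf: 16.0
  iris_chemical: Dieldrin
  expected_sl_rfd:
    value: 800
    unit: ug/kg
  expected_sl_csf:
    value: 1
    unit: ug/kg
- analyte_id: Aldrin
  rfd: 3.0e-05
  csf: 17.0
  iris_chemical: Aldrin
  expected_sl_rfd:
    value: 480
    unit: ug/kg
  expected_sl_csf:
    value: 0.94
    unit: ug/kg
- analyte_id: 44DDD
  csf: 0.24
  iris_chemical: p,p'-DDD
  expected_sl_csf:
    value: 67
    unit: ug/kg
- analyte_id: 44DDE
  csf: 0.34
  iris_chemical: p,p'-DDE
  expected_sl_csf:
    value: 47
    unit: ug/kg
- analyte_id: 44DDT
  rfd: 0.0005
  csf: 0.34
  iris_chemical: p,p'-DDT
  expected_sl_rfd:
    value: 8000
    unit: ug/kg
  expected_sl_csf:
    value: 47
    unit: ug/kg
- analyte_id: SUM_DDT
  rfd: 0.0005
  csf: 0.34
  iris_chemical: p,p'-DDT (applied to the sum)
  expected_sl_rfd:
    value: 8000
    unit: ug/kg
  expected_sl_csf:
    value: 47
    unit: ug/kg
- analyte_id: SUM_PCB40
  rfd: 2.0e-05
  csf: 2.0
  iris_chemical: PCBs (upper-bound slope, high risk and persistence tier)
  expected_sl_rfd:
    value: 320
    unit: ug/kg
  expected_sl_csf:
    value: 8
    unit: ug/kg
- analyte_id: 2378-TCDD
  rfd: 7.0e-10
  iris_chemical: 2,3,7,8-TCDD
  expected_sl_rfd:
    value: 0.011
    unit: ug/kg
- analyte_id: PCDDF_TEQ
  rfd: 7.0e-10
  iris_chemical: 2,3,7,8-TCDD (applied to the TEQ)
  expected_sl_rfd:
    value: 0.011
    unit: ug/kg
- analyte_id: PBDE47
  rfd: 0.0001
  iris_chemical: BDE-47
  expected_sl_rfd:
    value: 1600
    unit: ug/kg
- analyte_id: PBDE99
  rfd: 0.0001
  iris_chemical: BDE-99
  expected_sl_rfd:
    value: 1600
    unit: ug/kg
- analyte_id: PBDE153
  rfd: 0.0002
  iris_chemical: BDE-153
  expected_sl_rfd:
    value: 3200
    unit: ug/kg
- analyte_id: SUM_PBDE
  rfd: 0.0001
  iris_chemical: BDE-47 (applied to the sum)
  expected_sl_rfd:
    value: 1600
    unit: ug/kg
- analyte_id: Acenaphthene
  rfd: 0.06
  iris_chemical: Acenaphthene
  expected_sl_rfd:
    value: 960000
    unit: ug/kg
- analyte_id: Anthracene
  rfd: 0.3
  iris_chemical: Anthracene
  expected_sl_rfd:
    value: 4800000
    unit: ug/kg
- analyte_id: BaP
  rfd: 3.0e-05
  csf: 1.0
  iris_chemical: Benzo[a]pyrene (era slope factor; back-derived)
  expected_sl_rfd:
    value: 480
    unit: ug/kg
  expected_sl_csf:
    value: 16
    unit: ug/kg
- analyte_id: SUM_CHRYSENES
  csf: 0.0727
  iris_chemical: Chrysene-family slope (back-derived)
  expected_sl_csf:
    value: 220
    unit: ug/kg
- analyte_id: Fluoranthene
  rfd: 0.04
  iris_chemical: Fluoranthene
  expected_sl_rfd:
    value: 640000
    unit: ug/kg
- analyte_id: Fluorene
  rfd: 0.04
  iris_chemical: Fluorene
  expected_sl_rfd:
    value: 640000
    unit: ug/kg
- analyte_id: Naphthalene
  rfd: 0.02
  iris_chemical: Naphthalene
  expected_sl_rfd:
    value: 320000
    unit: ug/kg
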