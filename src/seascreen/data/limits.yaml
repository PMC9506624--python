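# International regulatory limits for contaminants in edible seaweed.
# Limits with basis 'unspecified' are stored for reference but excluded
# from lowest-limit comparisons.
limits:
- analyte_id: Cd
  jurisdiction: Australia/New Zealand
  limit_value: 0.2
  unit: mg/kg
  basis: DW
- analyte_id: Cd
  jurisdiction: France
  limit_value: 0.5
  unit: mg/kg
  basis: DW
- analyte_id: Cd
  jurisdiction: China
  limit_value: 1.0
  unit: mg/kg
  basis: DW
  applies_to: basis reported as 'appears to be DW'
- analyte_id: Cd
  jurisdiction: European Commission
  limit_value: 3.0
  unit: mg/kg
  basis: WW
  applies_to: food supplements consisting mainly of dried seaweed
- analyte_id: Hg
  jurisdiction: France
  limit_value: 0.1
  unit: mg/kg
  basis: DW
  applies_to: Hg species not specified
- analyte_id: Hg
  jurisdiction: European Commission
  limit_value: 0.1
  unit: mg/kg
  basis: unspecified
  applies_to: food supplements; basis unreadable in source
- analyte_id: iAs
  jurisdiction: Australia/New Zealand
  limit_value: 6.7
  unit: mg/kg
  basis: DW
  applies_to: calculated from 1 mg/kg WW at 85% hydration
- analyte_id: iAs
  jurisdiction: China
  limit_value: 1.0
  unit: mg/kg
  basis: DW
  applies_to: '''pollutant-free'' food standard; basis ''appears to be DW'''
- analyte_id: iAs
  jurisdiction: China (alternate)
  limit_value: 1.5
  unit: mg/kg
  basis: DW
  applies_to: basis 'appears to be DW'
- analyte_id: iAs
  jurisdiction: France
  limit_value: 3.0
  unit: mg/kg
  basis: DW
- analyte_id: Pb
  jurisdiction: China
  limit_value: 1.0
  unit: mg/kg
  basis: DW
- analyte_id: Pb
  jurisdiction: France
  limit_value: 5.0
  unit: mg/kg
  basis: DW
- analyte_id: Pb
  jurisdiction: Mauritius
  limit_value: 10.0
  unit: mg/kg
  basis: unspecified
  applies_to: WW or DW not specified
- analyte_id: Pb
  jurisdiction: European Commission
  limit_value: 3.0
  unit: mg/kg
  basis: WW
  applies_to: food supplements
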