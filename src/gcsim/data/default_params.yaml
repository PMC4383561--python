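complications:
  hormone:
    duration_months: null
    onset_monthly: 0.03
    utility: 0.88
  radiation:
    duration_months: null
    onset_monthly: 0.05
    utility: 0.85
cycle_length_months: 1
discount_rate: 0.0
durations:
  adjuvant_hormone_months: 6
  radiation_months: 2
  recurrence_hormone_months: 24
  salvage_hormone_months: 6
horizon_months: 120
life_table_path: life_table_male_synthetic.csv
pc_death_from_met: 0.02
policies:
  adjuvant:
    gc_high:
      ht: 0.15
      observation: 0.25
      rt: 0.4
      rt_ht: 0.2
    gc_low:
      ht: 0.04
      observation: 0.85
      rt: 0.08
      rt_ht: 0.03
    usual_care:
      ht: 0.1
      observation: 0.55
      rt: 0.25
      rt_ht: 0.1
  salvage:
    gc_high:
      ht: 0.2
      observation: 0.1
      rt: 0.45
      rt_ht: 0.25
    gc_low:
      ht: 0.07
      observation: 0.55
      rt: 0.3
      rt_ht: 0.08
    usual_care:
      ht: 0.15
      observation: 0.35
      rt: 0.35
      rt_ht: 0.15
salvage_success_monthly: 0.12
transitions:
  treated:
    bcr_from_ned: 0.005
    met_from_bcr: 0.0035
    met_from_ned: 0.0007
  untreated:
    bcr_from_ned: 0.0105
    met_from_bcr: 0.0055
    met_from_ned: 0.0012
utilities:
  bcr: 0.83
  ht: 0.85
  met: 0.45
  ned: 0.92
  rt: 0.9
  rt_ht: 0.78
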