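# Synthetic boundary fixture: every criterion at its greenest condition.
# No inhibitor removal needed, no hazardous masses, self-polymerization,
# macro-format sorbent, hazard-free aqueous elution assisted by ultrasound,
# and ten or more reuse cycles.
schema_version: 1
metadata:
  title: "synthetic boundary case: greenest procedure"
  notes: "synthetic fixture exercising the upper score boundary"
inhibitor_removal: not_needed_or_no_waste
initiation: self_polymerization
particle_size: macro_extraction_device
elution_solvents:
  - name: water
    h_codes: []
elution_technique: ultrasound_or_microwave
reuse_cycles: 12
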