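# Synthetic boundary fixture: every criterion at its least green printed
# condition. Large masses of maximally hazardous reagents in every role,
# combined solid+liquid inhibitor waste, plain heating/mixing initiation,
# quantum-dot particles (the lowest particle-size score, 0.2), an elution
# solvent past the 40-penalty-point cutoff, Soxhlet elution, single use.
schema_version: 1
metadata:
  title: "synthetic boundary case: worst procedure"
  notes: "synthetic fixture exercising the lower score boundary"
inhibitor_removal: solid_and_liquid_waste
substances:
  functional_monomer:
    - name: hazardous monomer
      mass_g: 30
      h_codes: [H300, H310]
  template:
    - name: hazardous template
      mass_g: 25
      h_codes: [H300, H330]
  cross_linker:
    - name: hazardous cross-linker
      mass_g: 40
      h_codes: [H300, H310]
  porogen:
    - name: hazardous porogen
      mass_g: 150
      h_codes: [H300, H310]
  other_reagent:
    - name: hazardous adjuvant
      mass_g: 100
      h_codes: [H300, H310, H330]
  core_surface:
    - name: hazardous surface modifier
      mass_g: 120
      h_codes: [H300, H330]
initiation: heating_mixing_only
particle_size: quantum_dots
elution_solvents:
  - name: highly hazardous solvent blend
    h_codes: [H225, H301, H311, H331, H370, H411]
elution_technique: soxhlet
reuse_cycles: 1
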