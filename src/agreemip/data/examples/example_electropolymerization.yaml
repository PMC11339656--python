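# Approximate - for illustration. Sketch of an electropolymerized imprinted
# film for solid-phase microextraction: pyrrole electropolymerized by cyclic
# voltammetry on an electrode, sulfadimethoxine template (5 mmol ~ 1.55 g),
# 4 mL of acetonitrile as porogen, small-volume ethanol wash. The full
# reagent inventory lives in the original publication; masses and H-codes
# here are plausible reconstructions, not transcriptions.
schema_version: 1
metadata:
  title: "electropolymerized film for SPME (approximate)"
  reference: "approximate - for illustration"
inhibitor_removal: not_needed_or_no_waste
substances:
  functional_monomer:
    - name: pyrrole
      mass_g: 0.3
      h_codes: [H226, H302, H311, H319]
  template:
    - name: sulfadimethoxine
      mass_g: 1.55
      h_codes: [H317]
  cross_linker:
    - name: ethylene glycol dimethacrylate
      mass_g: 0.5
      h_codes: [H315, H317, H319, H335]
  porogen:
    - name: acetonitrile
      volume_ml: 4
      h_codes: [H225, H302, H312, H319, H332]
  other_reagent:
    - name: potassium chloride (supporting electrolyte)
      mass_g: 0.1
      h_codes: []
initiation: electropolymerization
particle_size: macro_extraction_device
elution_solvents:
  - name: ethanol
    h_codes: [H225]
elution_technique: mixing_or_shaking
reuse_cycles: 5
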