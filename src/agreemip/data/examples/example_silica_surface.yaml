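# Approximate - for illustration. Sketch of a dual-template surface-imprinted
# polymer on silica gel: large toluene volumes as solvent and porogen, silica
# modified with acryloyl chloride/trimethylamine/pyridine, methacrylic acid
# monomer, methanol elution. The full reagent inventory lives in the original
# publication; masses and H-codes here are plausible reconstructions.
schema_version: 1
metadata:
  title: "dual-template silica-surface MIP (approximate)"
  reference: "approximate - for illustration"
inhibitor_removal: liquid_waste
substances:
  functional_monomer:
    - name: methacrylic acid
      mass_g: 2.0
      h_codes: [H226, H302, H311, H314, H335]
  template:
    - name: imidacloprid
      mass_g: 0.5
      h_codes: [H302, H410]
    - name: acetamiprid
      mass_g: 0.5
      h_codes: [H302, H410]
  cross_linker:
    - name: ethylene glycol dimethacrylate
      mass_g: 4.0
      h_codes: [H315, H317, H319, H335]
  porogen:
    - name: toluene
      volume_ml: 60
      h_codes: [H225, H304, H315, H336, H361D, H373]
  other_reagent:
    - name: pyridine
      volume_ml: 10
      h_codes: [H225, H302, H312, H319, H332]
    - name: hydrochloric acid solution
      mass_g: 20
      h_codes: [H290, H314, H335]
  core_surface:
    - name: acryloyl chloride
      mass_g: 5
      h_codes: [H225, H302, H314, H331]
    - name: trimethylamine
      mass_g: 3
      h_codes: [H220, H302, H314, H331]
    - name: toluene (surface-modification wash)
      volume_ml: 40
      density_g_per_ml: 0.867
      h_codes: [H225, H304, H315, H336, H361D, H373]
initiation: heating_mixing_with_initiator
particle_size: micrometer_crushed_sieved
elution_solvents:
  - name: methanol
    h_codes: [H225, H301, H311, H331, H370]
elution_technique: mixing_or_shaking
reuse_cycles: 1
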