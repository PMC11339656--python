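# agreemip

Quantitative greenness assessment of molecularly imprinted polymer (MIP)
synthesis procedures, as a Python library and command-line tool.

MIPs — selective sorbents built by polymerizing functional monomers and
cross-linkers around a template molecule — are popular in sample preparation
and sensing, but their synthesis can consume large volumes of hazardous
solvents, energy-intensive initiation, and single-use materials.  `agreemip`
turns a declarative description of a synthesis procedure into a transparent
greenness score.

## The metric

Twelve criteria cover the whole workflow.  Each is standardized onto a 0–1
scale (1 = greenest) and combined as a weighted average:

```
overall = Σᵢ wᵢ·sᵢ / Σᵢ wᵢ ,   i = 1…12,  wᵢ ∈ {1,2,3,4}
```

| # | Criterion | Input | Transformation |
|---|-----------|-------|----------------|
| 1 | Inhibitor removal | waste category | 1 / 0.5 / 0.2 / 0 |
| 2–4 | Monomer, template, cross-linker | x = Σ massᵢ·pointsᵢ (g·pt) | exp(−x/40), 2-dec. rounded |
| 5–7 | Porogen, other reagents, core/surface | same x | exp(−x/250), 2-dec. rounded |
| 8 | Initiation | category | 0 … 1 (self-polymerization best) |
| 9 | Particle size | category | 1 (macro) … 0.2 (quantum dots) |
| 10 | Elution solvent | GHS penalty points p | max(0, 1 − p/40) |
| 11 | Elution technique | category | Soxhlet 0 … ultrasound/microwave 1 |
| 12 | Reusability | cycles | 1 cycle 0; 2–9 cycles 0.5; ≥10 cycles 1 |

Hazards enter through GHS H-statements: each statement carries integer
penalty points (packaged default table, severity-graded and fully
user-overridable), and a reagent's burden is its mass in grams times the sum
of its points.  The default weight vector `(1,2,1,3,4,3,2,3,1,4,3,3)` puts
the most emphasis on the two solvent-dominated criteria (5 and 10).  The
result renders as a traffic-light pictogram: a central circle with the
overall score ringed by 12 criterion circles, color red→yellow→green with
score, size and proximity to the center growing with weight.

See `docs/methods.md` for the model details, calibration choices and
limitations.

## Worked example

A bundled example describes (approximately) an electropolymerized imprinted
film for solid-phase microextraction: pyrrole electropolymerized by cyclic
voltammetry with 4 mL of acetonitrile as porogen and a small-volume ethanol
wash.

```sh
agreemip assess src/agreemip/data/examples/example_electropolymerization.yaml
```

prints

```
Greenness assessment: electropolymerized film for SPME (approximate)
  penalty table: builtin-synthetic
   1. Removal of polymerization inhibitors                 score 1.00  (weight 1)
   2. Functional monomer                                   score 0.87  (weight 2)
   3. Template                                             score 0.86  (weight 1)
   4. Cross-linking agent                                  score 0.87  (weight 3)
   5. Porogen/solvent                                      score 0.78  (weight 4)
   6. Other reagents, adjuvants, or carriers               score 1.00  (weight 3)
   7. Core/particles preparation and surface modification  score 1.00  (weight 2)
   8. Polymerization initiation                            score 0.90  (weight 3)
   9. Size of polymer particles                            score 1.00  (weight 1)
  10. Template elution solvent                             score 0.85  (weight 4)
  11. Template elution technique                           score 0.50  (weight 3)
  12. Final product reusability                            score 0.50  (weight 3)
  overall score: 0.81
```

Reading it: the procedure is green almost everywhere — no inhibitor removal,
initiator-free low-energy electropolymerization (0.90), a macro-format film
(1.00), small reagent masses (criteria 2–4 near 0.87) — and loses most
ground on the moderately hazardous acetonitrile porogen (0.78), shake-based
elution (0.50) and limited reusability (0.50).  The overall 0.81 is the
weighted mean of the column.

Useful variations:

```sh
agreemip assess procedure.yaml --pictogram out.svg --report out.json -v
agreemip compare a.yaml b.yaml c.yaml --outdir results/
agreemip init my_procedure.yaml      # commented template to fill in
agreemip assess procedure.yaml --penalty-table my_points.csv --weights w.yaml
```

From Python:

```python
from agreemip import read_procedure, assess, layout, render

result, report = assess(read_procedure("procedure.yaml"))
print(result.display_overall, result.score_values())
render(layout(result), "pictogram.svg")
```

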