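# Methods

## Model

A synthesis procedure is scored on 12 criteria, each standardized to [0, 1]
with 1 the greenest condition, then aggregated as a weighted mean
`overall = Σ wᵢsᵢ / Σ wᵢ` with integer weights on a four-point scale.
Continuous transformations are used wherever the input is continuous (so
that resolution is not thrown away by binning); stepwise maps are reserved
for inputs that are inherently categorical.

### Hazard penalties

Chemical risk enters through GHS hazard statements.  Every H-code has a
nonnegative integer penalty; a substance's penalty is the sum over its
deduplicated codes.  Lookups are strict by default — an H-code missing from
the table is an error, because silently counting it as zero would inflate
apparent greenness.  A lenient mode (for exploratory use) falls back from a
suffixed code (H360FD) to its stem (H360) and otherwise warns and counts 0.

The packaged default table is a severity-graded assignment authored for
this package (`data/penalty_points_synthetic.csv`, labelled synthetic):
fatal-if-swallowed/inhaled and CMR category 1 statements carry 8–10 points,
serious irreversible effects 6–8, moderate acute and chronic hazards 4–6,
irritation 2–3, with physical and environmental hazards graded analogously.
It is not an official registry; any two-column `code,points` CSV or YAML
mapping can replace it (`--penalty-table`, or `penalty_table:` in the
procedure file), and every report records which table produced its scores.

### Criteria 2–7: mass × hazard burden

Each reagent of the polymerization mixture is charged to exactly one
criterion by role (functional monomer → 2, template → 3, cross-linker → 4,
porogen/solvent → 5, other reagents/adjuvants/carriers → 6, core/particle
preparation and surface modification → 7).  The criterion's burden is

```
x = Σ over reagents ( mass_grams × penalty_points )   [gram·points]
```

Mixtures aggregate additively — order-independent, and reducing to the
single-substance product for one reagent.  The additive form is isolated
behind `criteria.burden` so an alternative pooling rule could be swapped in.
An absent stage (e.g. no core or surface modification) has x = 0 and scores
1.00: a step that is not performed cannot contribute harm.

The burden maps to a score through an exponential decay, rounded to two
decimals (half away from zero):

* criteria 2–4: `score = exp(−x/40)`
* criteria 5–7: `score = exp(−x/250)`

Both anchors are exact at the ends — x = 0 gives 1.00, and the rounding
closes the lower boundary (the continuous curve never reaches 0; it rounds
to 0.00 once x exceeds ≈ 5.3 decay scales, i.e. ≈ 212 g·pt for criteria 2–4
and ≈ 1325 g·pt for criteria 5–7).  The two decay scales are this package's
calibration of the "map the 0–1 range onto the expected input range"
principle: monomer/template/cross-linker entries in reviewed procedures are
at most a few grams of moderately hazardous material (burdens of order
10–200 g·pt), while porogens, carriers and surface-modification washes
routinely reach tens of grams of solvent (order 100–1500 g·pt).  A single
curve would crush one class against an endpoint; the slower solvent curve
keeps discrimination where solvent masses actually live.

Masses may be entered in g, mg, or mL (converted via an explicit
`density_g_per_ml` or the packaged handbook density table for common
solvents).  The decay constants are in gram·points; conversion always
happens before the curve is applied.

### Criterion 10: elution solvent

Solvent volumes for template elution are rarely reported, so only hazards
count: with p the penalty-point sum over the union of all elution solvents'
H-codes (worst-case pooled operator exposure),

```
score = max(0, 1 − p/40)
```

a linear ramp that is exactly 0 at p = 40 and for every sum above 39 (the
published cutoff), and 1.00 for a hazard-free solvent such as water.  The
same two-decimal rounding is applied for uniformity with criteria 2–7.

### Categorical criteria (1, 8, 9, 11) and reusability (12)

The published score maps are used verbatim:

* inhibitor removal: none needed/no waste 1.0, solid waste 0.5, liquid
  waste 0.2, solid + liquid 0.0;
* initiation: heating/mixing only 0.0, mixing + initiator 0.2,
  heating/mixing + initiator 0.4, sonication/microwave 0.6, UV 0.8,
  electropolymerization 0.9, self-polymerization 1.0;
* particle size: macro extraction device 1.0, >1000 nm 0.9, 100–1000 nm
  0.8, µm after crushing/sieving 0.6, 10–100 nm 0.5, carbon dots 0.4,
  quantum dots 0.2;
* elution technique: Soxhlet 0, mixing/shaking 0.5, supercritical fluid
  0.8, ultrasound/microwave 1.0;
* reusability: 1 cycle 0; 2–9 cycles 0.5; ≥10 cycles 1.  The metric's prose
  definition is ambiguous at exactly 10 cycles; this implementation places
  10 in the top band, so 10 scores 1.
* Combinations not listed (e.g. UV plus sonication) are entered as the
  closest equivalent; an `initiation_note` in the file makes the CLI print
  a notice so the approximation is visible.

### Aggregation and rounding

The overall score is kept at full floating precision internally and rounded
to two decimals only for display, avoiding double-rounding drift when
procedures are compared.  Weights are integers 1–4 (fractional or zero
weights are rejected; zero would silently disable a criterion).  A modified
weight vector is marked provenance "user" and its justification string is
echoed into every report.

A consequence worth knowing: because the lowest particle-size score is 0.2,
the worst describable procedure does not reach overall 0.00 — with default
weights its floor is 0.2 × 1/30 ≈ 0.0067, displayed as 0.01.

## Pictogram

The result renders as the sorbent's own cartoon: a central circle (the
imprinted cavity) labelled with the two-decimal overall score, ringed by 12
satellite circles (the functional monomers), criterion 1 at twelve o'clock
and ids increasing clockwise at 30° spacing — the angular convention is this
package's documented choice.  Color is a piecewise-linear red(0) →
yellow(0.5) → green(1) gradient; a criterion's weight shows twice, as
satellite radius (affine in weight, bigger = heavier) and distance to the
center (affine, closer = heavier).  Palette and geometry constants live in a
`Theme` and are presentation, not contract; the contract is endpoint colors
and the bigger-and-closer weight encoding.  SVG output is plain generated
text and byte-stable for identical inputs; PNG rasterizes the same resolved
geometry through matplotlib.

## Synthetic procedure generator

`generate_synthetic(seed, n)` produces schema-valid random procedures for
property testing: reagent masses log-uniform per role (5 mg–5 g for
monomers/templates, up to 50 g for porogens), 0–4 H-codes per reagent drawn
from the active penalty table (so strict lookups always succeed),
categorical fields uniform over their categories, reuse cycles uniform on
1–15, and a random valid weight vector in 20 % of cases.  The generator
emulates the *shape* of reported procedures — ranges and co-occurrence of
fields — not their real-world correlations (e.g. toluene volumes do not
co-vary with bulk polymerization here).  Tests passing on this population
therefore demonstrate the metric's algebraic contracts (bounds,
monotonicity, determinism, totality), not empirical agreement with any
published corpus.

## Numerical and design choices

* Two-decimal rounding is half-away-from-zero via `decimal.Decimal`, not
  banker's rounding (0.025 → 0.03).
* Unknown H-codes: strict error by default; lenient stem-fallback behind a
  flag, never silent.
* The penalty table, density table and example procedures are plain text
  inside the package and user-replaceable.
* Reports are JSON with the input echoed back, the per-criterion trace
  (`-v` logs raw input → burden → score), tool version and timestamp; two
  assessments of one input are identical except for the timestamp.
* CLI exit codes: 0 success, 2 schema/validation errors, 3 I/O errors.

## Limitations

* The default penalty table and the two burden-decay constants are this
  package's calibration; absolute overall scores shift under a different
  penalty convention, though orderings are stable under monotone point
  rescalings.  Scores should be read comparatively, not as absolutes.
* The bundled literature-style examples are approximate reconstructions
  from narrative summaries ("approximate — for illustration"); they are not
  reproductions of any published assessment.
* No H-codes, masses or categories are inferred from free text or chemical
  databases; the CAS field is metadata only.
* Energy and time are only reflected indirectly through the initiation and
  elution-technique categories.
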