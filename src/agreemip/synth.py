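"""Seeded generator of synthetic, schema-valid synthesis procedures.

Used by the property-test suites and for demonstration.  The generated
procedures are statistically shaped like the reviewed literature rather
than copies of any one protocol:

* reagent masses are log-uniform between 5 mg and 50 g — monomer/template/
  cross-linker entries cluster at the low end (up to 5 g), porogen, carrier
  and surface-modification entries reach tens of grams;
* each reagent carries 0-4 H-codes drawn from the active penalty table, so
  strict-mode assessment of a generated procedure never hits unknown codes;
* every categorical field is uniform over its category set, and reuse
  cycles are uniform on 1-15 so all three reusability bands occur;
* most procedures keep the default weights; one in five draws a random
  valid (1-4) vector.
"""

from __future__ import annotations

import random

from .aggregate import DEFAULT_WEIGHTS
from .criteria import ElutionTechnique, InhibitorRemoval, Initiation, ParticleSize
from .hazards import PenaltyTable, load_penalty_table
from .io import ElutionSolvent, Metadata, ProcedureDescription, SubstanceSection, SubstanceSpec

__all__ = ["generate_synthetic"]

# mass ranges (grams, log-uniform) per reagent role
_MASS_RANGES = {
    "functional_monomer": (0.005, 5.0),
    "template": (0.005, 2.0),
    "cross_linker": (0.02, 10.0),
    "porogen": (0.5, 50.0),
    "other_reagent": (0.005, 10.0),
    "core_surface": (0.05, 20.0),
}

_SOLVENT_NAMES = [
    "water", "methanol", "ethanol", "acetonitrile", "toluene",
    "acetic acid", "acetone", "chloroform", "dimethyl sulfoxide",
]


def _substance(rng: random.Random, role: str, codes: list[str], index: int) -> SubstanceSpec:
    lo, hi = _MASS_RANGES[role]
    mass = rng.uniform(0.0, 1.0)
    mass = lo * (hi / lo) ** mass  # log-uniform on [lo, hi]
    n_codes = rng.randint(0, 4)
    return SubstanceSpec(
        name=f"{role}-{index}",
        mass_g=round(mass, 4),
        h_codes=sorted(rng.sample(codes, n_codes)),
    )


def generate_synthetic(
    seed: int, n: int, table: PenaltyTable | None = None
) -> list[ProcedureDescription]:
    """Generate ``n`` reproducible random procedures from ``seed``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if table is None:
        table = load_penalty_table()
    codes = table.codes()
    rng = random.Random(seed)
    procedures = []
    for i in range(n):
        substances = {}
        for role in _MASS_RANGES:
            count = rng.randint(0, 2) if role != "functional_monomer" else rng.randint(1, 2)
            substances[role] = [_substance(rng, role, codes, j + 1) for j in range(count)]
        n_solvents = rng.randint(1, 2)
        solvents = [
            ElutionSolvent(
                name=rng.choice(_SOLVENT_NAMES),
                h_codes=sorted(rng.sample(codes, rng.randint(0, 3))),
            )
            for _ in range(n_solvents)
        ]
        weights = None
        if rng.random() < 0.2:
            weights = [rng.randint(1, 4) for _ in DEFAULT_WEIGHTS]
        procedures.append(
            ProcedureDescription(
                metadata=Metadata(title=f"synthetic procedure {i + 1} (seed {seed})"),
                inhibitor_removal=rng.choice(list(InhibitorRemoval)),
                substances=SubstanceSection(**substances),
                initiation=rng.choice(list(Initiation)),
                particle_size=rng.choice(list(ParticleSize)),
                elution_solvents=solvents,
                elution_technique=rng.choice(list(ElutionTechnique)),
                reuse_cycles=rng.randint(1, 15),
                weights=weights,
            )
        )
    return procedures
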