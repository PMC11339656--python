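"""The twelve greenness criteria and their score transformations.

A molecularly imprinted polymer (MIP) synthesis is assessed on 12 criteria.
Each criterion maps raw procedure facts onto a standardized 0-1 scale where
1 is the greenest attainable condition and 0 the worst:

1.  Removal of polymerization inhibitors (categorical, by waste generated)
2.  Functional monomer        (mass x hazard burden, fast-decay curve)
3.  Template                  (mass x hazard burden, fast-decay curve)
4.  Cross-linking agent       (mass x hazard burden, fast-decay curve)
5.  Porogen / solvent         (mass x hazard burden, slow-decay curve)
6.  Other reagents, adjuvants, carriers (mass x hazard burden, slow-decay)
7.  Core/particle preparation and surface modification (slow-decay)
8.  Polymerization initiation (categorical, by energy input and initiator use)
9.  Size of the polymer particles (categorical, by operator exposure)
10. Template elution solvent  (hazard points only, linear ramp to 0 at 40)
11. Template elution technique (categorical)
12. Final product reusability (stepwise in sorption-desorption cycles)

Criteria 2-7 multiply each reagent's mass in grams by the sum of its GHS
penalty points and sum over the reagents assigned to the criterion; this
gram-point burden ``x`` is pushed through a continuous decay curve and the
result rounded to two decimals (half away from zero).  Continuous curves
favor nonhazardous reagents in small quantities and avoid the resolution
loss of stepwise scoring; stepwise maps are used only where the input is
inherently categorical.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .hazards import HazardCode, PenaltyTable, normalize_code, penalty_sum

__all__ = [
    "Role",
    "InhibitorRemoval",
    "Initiation",
    "ParticleSize",
    "ElutionTechnique",
    "SubstanceUse",
    "Burden",
    "CriterionScore",
    "CRITERION_NAMES",
    "burden",
    "round_score",
    "score_c2_c3_c4",
    "score_c5_c6_c7",
    "score_inhibitor_removal",
    "score_initiation",
    "score_particle_size",
    "score_elution_solvent",
    "score_elution_technique",
    "score_reusability",
]

CRITERION_NAMES: dict[int, str] = {
    1: "Removal of polymerization inhibitors",
    2: "Functional monomer",
    3: "Template",
    4: "Cross-linking agent",
    5: "Porogen/solvent",
    6: "Other reagents, adjuvants, or carriers",
    7: "Core/particles preparation and surface modification",
    8: "Polymerization initiation",
    9: "Size of polymer particles",
    10: "Template elution solvent",
    11: "Template elution technique",
    12: "Final product reusability",
}


class Role(str, enum.Enum):
    """Which mass-and-hazard criterion a reagent is charged to."""

    functional_monomer = "functional_monomer"  # criterion 2
    template = "template"                      # criterion 3
    cross_linker = "cross_linker"              # criterion 4
    porogen = "porogen"                        # criterion 5
    other_reagent = "other_reagent"            # criterion 6
    core_surface = "core_surface"              # criterion 7

    @property
    def criterion_id(self) -> int:
        return _ROLE_CRITERION[self]


_ROLE_CRITERION = {
    Role.functional_monomer: 2,
    Role.template: 3,
    Role.cross_linker: 4,
    Role.porogen: 5,
    Role.other_reagent: 6,
    Role.core_surface: 7,
}


class InhibitorRemoval(str, enum.Enum):
    not_needed_or_no_waste = "not_needed_or_no_waste"
    solid_waste = "solid_waste"
    liquid_waste = "liquid_waste"
    solid_and_liquid_waste = "solid_and_liquid_waste"


class Initiation(str, enum.Enum):
    heating_mixing_only = "heating_mixing_only"
    mixing_with_initiator = "mixing_with_initiator"
    heating_mixing_with_initiator = "heating_mixing_with_initiator"
    sonication_or_microwave = "sonication_or_microwave"
    uv_mediated = "uv_mediated"
    electropolymerization = "electropolymerization"
    self_polymerization = "self_polymerization"


class ParticleSize(str, enum.Enum):
    macro_extraction_device = "macro_extraction_device"
    above_1000nm = "above_1000nm"
    nm_100_to_1000 = "nm_100_to_1000"
    micrometer_crushed_sieved = "micrometer_crushed_sieved"
    nm_10_to_100 = "nm_10_to_100"
    carbon_dots = "carbon_dots"
    quantum_dots = "quantum_dots"


class ElutionTechnique(str, enum.Enum):
    soxhlet = "soxhlet"
    mixing_or_shaking = "mixing_or_shaking"
    supercritical_fluid = "supercritical_fluid"
    ultrasound_or_microwave = "ultrasound_or_microwave"


# Printed categorical score maps.  No waste beats solid waste beats liquid
# waste for inhibitor removal; initiation scores rise with energy efficiency
# and fall with initiator need; particle-size scores fall with operator
# exposure to fine particles; elution-technique scores reflect solvent and
# energy demand (Soxhlet worst, ultrasound/microwave best).
INHIBITOR_REMOVAL_SCORES: dict[InhibitorRemoval, float] = {
    InhibitorRemoval.not_needed_or_no_waste: 1.0,
    InhibitorRemoval.solid_waste: 0.5,
    InhibitorRemoval.liquid_waste: 0.2,
    InhibitorRemoval.solid_and_liquid_waste: 0.0,
}

INITIATION_SCORES: dict[Initiation, float] = {
    Initiation.heating_mixing_only: 0.0,
    Initiation.mixing_with_initiator: 0.2,
    Initiation.heating_mixing_with_initiator: 0.4,
    Initiation.sonication_or_microwave: 0.6,
    Initiation.uv_mediated: 0.8,
    Initiation.electropolymerization: 0.9,
    Initiation.self_polymerization: 1.0,
}

PARTICLE_SIZE_SCORES: dict[ParticleSize, float] = {
    ParticleSize.macro_extraction_device: 1.0,
    ParticleSize.above_1000nm: 0.9,
    ParticleSize.nm_100_to_1000: 0.8,
    ParticleSize.micrometer_crushed_sieved: 0.6,
    ParticleSize.nm_10_to_100: 0.5,
    ParticleSize.carbon_dots: 0.4,
    ParticleSize.quantum_dots: 0.2,
}

ELUTION_TECHNIQUE_SCORES: dict[ElutionTechnique, float] = {
    ElutionTechnique.soxhlet: 0.0,
    ElutionTechnique.mixing_or_shaking: 0.5,
    ElutionTechnique.supercritical_fluid: 0.8,
    ElutionTechnique.ultrasound_or_microwave: 1.0,
}

# Decay scales (gram-points) of the continuous burden curves.  Chosen so the
# 0-1 range spans the burdens reported for each reagent class: monomers,
# templates and cross-linkers enter at up to a few grams of moderately
# hazardous material (burdens of order 10-200 g-pt), while porogens and
# carriers routinely reach tens of grams of solvent (burdens of order
# 100-1500 g-pt), so their curve decays more slowly to keep discrimination.
MONOMER_BURDEN_SCALE = 40.0
SOLVENT_BURDEN_SCALE = 250.0

# Elution-solvent penalty points at and above which the score is exactly 0.
ELUTION_ZERO_POINTS = 40


@dataclass(frozen=True)
class SubstanceUse:
    """One reagent in the synthesis: identity, mass and hazard statements."""

    name: str
    mass_grams: float
    codes: frozenset[HazardCode] = frozenset()
    role: Role = Role.other_reagent
    cas: str | None = None

    def __post_init__(self) -> None:
        if self.mass_grams < 0:
            raise ValueError(
                f"mass of {self.name!r} must be nonnegative, got {self.mass_grams}"
            )
        object.__setattr__(
            self, "codes", frozenset(normalize_code(c) for c in self.codes)
        )
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class Burden:
    """Mass-and-hazard product x (gram-points) aggregated over one criterion."""

    x: float

    def __post_init__(self) -> None:
        if self.x < 0 or not math.isfinite(self.x):
            raise ValueError(f"burden must be finite and nonnegative, got {self.x}")


@dataclass(frozen=True)
class CriterionScore:
    """One criterion's standardized score with provenance text."""

    criterion_id: int
    score: float
    detail: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.criterion_id <= 12:
            raise ValueError(f"criterion_id must be 1-12, got {self.criterion_id}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(
                f"criterion {self.criterion_id} score out of [0, 1]: {self.score}"
            )
        if self.score != round_score(self.score):
            raise ValueError(
                f"criterion {self.criterion_id} score {self.score} is not "
                "two-decimal rounded"
            )


def round_score(value: float) -> float:
    """Round to two decimals, half away from zero (0.025 -> 0.03)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def burden(
    substances: Sequence[SubstanceUse],
    table: PenaltyTable,
    *,
    strict: bool = True,
) -> Burden:
    """Aggregate burden x = sum_i mass_i * penalty_sum(codes_i) for one criterion.

    Mixtures (multimonomer, multitemplate, solvent mixtures) contribute
    additively, each component with its own mass and hazards; the empty list
    (stage absent from the procedure) gives x = 0, the greenest condition.
    All substances must be charged to the same criterion role.
    """
    roles = {s.role for s in substances}
    if len(roles) > 1:
        raise ValueError(
            "all substances in one burden must share a role; got "
            + ", ".join(sorted(r.value for r in roles))
        )
    x = 0.0
    for s in substances:
        x += s.mass_grams * penalty_sum(s.codes, table, strict=strict)
    return Burden(x)


def _decay_score(x: Burden | float, scale: float, criterion_id: int, label: str) -> CriterionScore:
    x_val = x.x if isinstance(x, Burden) else float(x)
    if x_val < 0:
        raise ValueError(f"burden must be nonnegative, got {x_val}")
    raw = math.exp(-x_val / scale)
    return CriterionScore(
        criterion_id=criterion_id,
        score=round_score(raw),
        detail=f"{label}: x = {x_val:g} g-pt -> exp(-x/{scale:g}) = {raw:.4f}",
    )


def score_c2_c3_c4(x: Burden | float, criterion_id: int = 2) -> CriterionScore:
    """Fast-decay burden curve for criteria 2-4 (monomer, template, cross-linker).

    score = exp(-x / 40) rounded to two decimals: 1.00 at x = 0, below 0.005
    (hence 0.00) for x >~ 212 g-pt.
    """
    if criterion_id not in (2, 3, 4):
        raise ValueError(f"criterion_id must be 2, 3 or 4, got {criterion_id}")
    return _decay_score(x, MONOMER_BURDEN_SCALE, criterion_id, "fast-decay")


def score_c5_c6_c7(x: Burden | float, criterion_id: int = 5) -> CriterionScore:
    """Slow-decay burden curve for criteria 5-7 (porogen, other reagents, core).

    score = exp(-x / 250): same form as the criteria 2-4 curve but scaled to
    the much larger solvent/carrier masses, so the two curves discriminate
    differently over their expected input ranges.
    """
    if criterion_id not in (5, 6, 7):
        raise ValueError(f"criterion_id must be 5, 6 or 7, got {criterion_id}")
    return _decay_score(x, SOLVENT_BURDEN_SCALE, criterion_id, "slow-decay")


def _categorical(criterion_id: int, choice, enum_cls, table) -> CriterionScore:
    try:
        choice = enum_cls(choice)
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ValueError(
            f"criterion {criterion_id}: unknown category {choice!r}; expected one of {valid}"
        ) from None
    return CriterionScore(criterion_id, table[choice], detail=choice.value)


def score_inhibitor_removal(choice: InhibitorRemoval | str) -> CriterionScore:
    """Criterion 1: waste generated while removing polymerization inhibitors."""
    return _categorical(1, choice, InhibitorRemoval, INHIBITOR_REMOVAL_SCORES)


def score_initiation(choice: Initiation | str) -> CriterionScore:
    """Criterion 8: how the polymerization is initiated."""
    return _categorical(8, choice, Initiation, INITIATION_SCORES)


def score_particle_size(choice: ParticleSize | str) -> CriterionScore:
    """Criterion 9: size class of the polymer particles produced."""
    return _categorical(9, choice, ParticleSize, PARTICLE_SIZE_SCORES)


def score_elution_technique(choice: ElutionTechnique | str) -> CriterionScore:
    """Criterion 11: technique used to elute the template."""
    return _categorical(11, choice, ElutionTechnique, ELUTION_TECHNIQUE_SCORES)


def score_elution_solvent(
    codes: Iterable[HazardCode],
    table: PenaltyTable,
    *,
    strict: bool = True,
) -> CriterionScore:
    """Criterion 10: hazards of the template elution solvent.

    Solvent volumes are rarely reported, so only the hazard statements count:
    score = max(0, 1 - points/40), i.e. a linear ramp from 1.00 for a
    hazard-free solvent (water) to exactly 0 at 40 penalty points and for
    every sum above 39.  For mixed elution solvents pass the union of all
    components' H-codes (worst-case pooled exposure).
    """
    points = penalty_sum(codes, table, strict=strict)
    raw = max(0.0, 1.0 - points / ELUTION_ZERO_POINTS)
    return CriterionScore(
        criterion_id=10,
        score=round_score(raw),
        detail=f"{points} penalty points -> max(0, 1 - points/{ELUTION_ZERO_POINTS})",
    )


def score_reusability(cycles: int) -> CriterionScore:
    """Criterion 12: usable sorption-desorption cycles.

    Single use scores 0; 2-9 cycles score 0.5; 10 or more score 1.  Reported
    reusability is rarely more precise than "a few times", so a finer scale
    would be spurious.  Exactly 10 cycles takes the top score.
    """
    if not isinstance(cycles, int) or isinstance(cycles, bool):
        raise ValueError(f"reuse cycles must be an integer, got {cycles!r}")
    if cycles < 1:
        raise ValueError(f"reuse cycles must be >= 1, got {cycles}")
    score = 0.0 if cycles == 1 else (0.5 if cycles < 10 else 1.0)
    return CriterionScore(12, score, detail=f"{cycles} cycle(s)")
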