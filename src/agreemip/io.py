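"""Procedure-description schema, assessment pipeline and comparison tables.

A synthesis procedure is described declaratively in YAML or JSON: the
categorical choices for criteria 1, 8, 9, 11 and 12, the reagent lists for
criteria 2-7 (name, mass, GHS H-codes), and the elution solvent(s) for
criterion 10.  Reagent masses may be given in grams, milligrams, or as a
volume in mL converted through a density (supplied inline or looked up in
the packaged density table by solvent name).

:func:`assess` runs the full pipeline — per-criterion scoring, weighted
aggregation — and assembles a JSON-serializable report echoing the input,
so every score can be audited back to its raw facts.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from . import __version__
from .aggregate import AssessmentResult, WeightScheme, overall_score, validate_weights
from .criteria import (
    CRITERION_NAMES,
    CriterionScore,
    ElutionTechnique,
    InhibitorRemoval,
    Initiation,
    ParticleSize,
    Role,
    SubstanceUse,
    burden,
    score_c2_c3_c4,
    score_c5_c6_c7,
    score_elution_solvent,
    score_elution_technique,
    score_inhibitor_removal,
    score_initiation,
    score_particle_size,
    score_reusability,
)
from .hazards import PenaltyTable, load_penalty_table, normalize_code

__all__ = [
    "SchemaError",
    "Metadata",
    "SubstanceSpec",
    "ElutionSolvent",
    "SubstanceSection",
    "ProcedureDescription",
    "read_procedure",
    "write_procedure",
    "assess",
    "compare",
    "solvent_density",
]

log = logging.getLogger("agreemip")


class SchemaError(ValueError):
    """The procedure file violates the schema; messages name the fields."""

    def __init__(self, source: str, problems: list[str]):
        self.source = source
        self.problems = problems
        super().__init__(
            f"invalid procedure description ({source}):\n  - " + "\n  - ".join(problems)
        )


@lru_cache(maxsize=1)
def _density_table() -> dict[str, float]:
    text = resources.files("agreemip").joinpath("data", "solvent_densities.csv").read_text("utf-8")
    rows = [r for r in csv.reader(text.splitlines()) if r and not r[0].startswith("#")]
    return {name.strip().lower(): float(d) for name, d in rows[1:]}


def solvent_density(name: str) -> float:
    """Density (g/mL) of a common solvent from the packaged table."""
    try:
        return _density_table()[name.strip().lower()]
    except KeyError:
        raise KeyError(
            f"no packaged density for {name!r}; give density_g_per_ml explicitly"
        ) from None


class Metadata(BaseModel):
    model_config = ConfigDict(extra="forbid")
    title: str = ""
    reference: str = ""
    notes: str = ""


class SubstanceSpec(BaseModel):
    """One reagent entry; exactly one of mass_g / mass_mg / volume_ml."""

    model_config = ConfigDict(extra="forbid")
    name: str
    cas: Optional[str] = None
    mass_g: Optional[float] = Field(default=None, ge=0)
    mass_mg: Optional[float] = Field(default=None, ge=0)
    volume_ml: Optional[float] = Field(default=None, ge=0)
    density_g_per_ml: Optional[float] = Field(default=None, gt=0)
    h_codes: list[str] = Field(default_factory=list)

    @field_validator("h_codes")
    @classmethod
    def _canon_codes(cls, v: list[str]) -> list[str]:
        return sorted({normalize_code(c) for c in v})

    @model_validator(mode="after")
    def _one_amount(self) -> "SubstanceSpec":
        given = [f for f in ("mass_g", "mass_mg", "volume_ml") if getattr(self, f) is not None]
        if len(given) != 1:
            raise ValueError(
                f"substance {self.name!r}: give exactly one of mass_g, mass_mg, "
                f"volume_ml (got {given or 'none'})"
            )
        if self.volume_ml is None and self.density_g_per_ml is not None:
            raise ValueError(
                f"substance {self.name!r}: density_g_per_ml only applies with volume_ml"
            )
        return self

    def mass_grams(self) -> float:
        if self.mass_g is not None:
            return self.mass_g
        if self.mass_mg is not None:
            return self.mass_mg / 1000.0
        density = self.density_g_per_ml
        if density is None:
            density = solvent_density(self.name)
        return self.volume_ml * density

    def to_substance(self, role: Role) -> SubstanceUse:
        return SubstanceUse(
            name=self.name,
            mass_grams=self.mass_grams(),
            codes=frozenset(self.h_codes),
            role=role,
            cas=self.cas,
        )


class ElutionSolvent(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    h_codes: list[str] = Field(default_factory=list)

    @field_validator("h_codes")
    @classmethod
    def _canon_codes(cls, v: list[str]) -> list[str]:
        return sorted({normalize_code(c) for c in v})


class SubstanceSection(BaseModel):
    """Reagent lists keyed by role; absent stages stay empty (greenest)."""

    model_config = ConfigDict(extra="forbid")
    functional_monomer: list[SubstanceSpec] = Field(default_factory=list)
    template: list[SubstanceSpec] = Field(default_factory=list)
    cross_linker: list[SubstanceSpec] = Field(default_factory=list)
    porogen: list[SubstanceSpec] = Field(default_factory=list)
    other_reagent: list[SubstanceSpec] = Field(default_factory=list)
    core_surface: list[SubstanceSpec] = Field(default_factory=list)

    def by_role(self, role: Role) -> list[SubstanceSpec]:
        return getattr(self, role.value)


class ProcedureDescription(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = Field(default=1, ge=1, le=1)
    metadata: Metadata = Field(default_factory=Metadata)
    inhibitor_removal: InhibitorRemoval
    substances: SubstanceSection = Field(default_factory=SubstanceSection)
    initiation: Initiation
    initiation_note: Optional[str] = None
    particle_size: ParticleSize
    elution_solvents: list[ElutionSolvent]
    elution_technique: ElutionTechnique
    reuse_cycles: int = Field(ge=1)
    weights: Optional[list[int]] = None
    weights_justification: Optional[str] = None
    penalty_table: Optional[str] = None


def _format_validation_error(exc: ValidationError) -> list[str]:
    problems = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        problems.append(f"{loc}: {err['msg']}")
    return problems


def read_procedure(path: str | Path) -> ProcedureDescription:
    """Read and schema-validate a YAML/JSON procedure description.

    Unknown keys are rejected with their location; schema violations raise
    :class:`SchemaError` listing every offending field.
    """
    path = Path(path)
    try:
        text = path.read_text("utf-8")
    except OSError as exc:
        raise OSError(f"cannot read procedure file {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(str(path), [f"not parseable as YAML/JSON: {exc}"]) from exc
    if not isinstance(data, dict):
        raise SchemaError(str(path), ["top level must be a mapping"])
    try:
        return ProcedureDescription.model_validate(data)
    except ValidationError as exc:
        raise SchemaError(str(path), _format_validation_error(exc)) from exc


def write_procedure(description: ProcedureDescription, path: str | Path) -> Path:
    """Write the canonical YAML form (stable key order, no nulls)."""
    path = Path(path)
    data = description.model_dump(mode="json", exclude_none=True)
    path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True), "utf-8")
    return path


def _criterion_scores(
    description: ProcedureDescription, table: PenaltyTable, strict: bool
) -> list[CriterionScore]:
    scores: list[CriterionScore] = [score_inhibitor_removal(description.inhibitor_removal)]
    for role in Role:
        subs = [s.to_substance(role) for s in description.substances.by_role(role)]
        x = burden(subs, table, strict=strict)
        cid = role.criterion_id
        fn = score_c2_c3_c4 if cid in (2, 3, 4) else score_c5_c6_c7
        scores.append(fn(x, cid))
        log.debug("criterion %d (%s): x = %.4g g-pt -> %.2f", cid, role.value, x.x, scores[-1].score)
    scores.append(score_initiation(description.initiation))
    scores.append(score_particle_size(description.particle_size))
    pooled = {c for solvent in description.elution_solvents for c in solvent.h_codes}
    scores.append(score_elution_solvent(pooled, table, strict=strict))
    scores.append(score_elution_technique(description.elution_technique))
    scores.append(score_reusability(description.reuse_cycles))
    return scores


def assess(
    description: ProcedureDescription,
    *,
    penalty_table: PenaltyTable | None = None,
    weights: WeightScheme | None = None,
    strict: bool = True,
) -> tuple[AssessmentResult, dict]:
    """Score all 12 criteria, aggregate, and assemble the audit report.

    Deterministic in its inputs.  Precedence for the penalty table: explicit
    argument, then the path named in the description, then the packaged
    default; likewise an explicit ``weights`` argument overrides the
    description's vector.
    """
    if penalty_table is None:
        penalty_table = load_penalty_table(description.penalty_table)
    if weights is None:
        weights = validate_weights(description.weights, description.weights_justification)
    scores = _criterion_scores(description, penalty_table, strict)
    result = overall_score(scores, weights)
    report = {
        "tool": "agreemip",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "input": description.model_dump(mode="json", exclude_none=True),
        "penalty_table_source": penalty_table.source_label,
        "weights": {
            "values": list(weights.weights),
            "provenance": weights.provenance,
            "justification": weights.justification,
        },
        "criteria": [
            {
                "id": s.criterion_id,
                "name": CRITERION_NAMES[s.criterion_id],
                "score": s.score,
                "weight": w,
                "detail": s.detail,
            }
            for s, w in zip(result.scores, weights.weights)
        ],
        "overall": result.overall,
        "overall_display": result.display_overall,
    }
    return result, report


def compare(
    paths: list[str | Path],
    *,
    penalty_table: PenaltyTable | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assess several procedure files and rank them by overall score.

    Returns the ranked table (one row per valid file, columns ``c1``-``c12``
    and ``overall``) together with a mapping of failed file -> error message;
    invalid files do not abort the rest.
    """
    if len(paths) < 2:
        raise ValueError("compare needs at least two procedure files")
    rows, failures = [], {}
    for p in paths:
        try:
            description = read_procedure(p)
            result, _ = assess(description, penalty_table=penalty_table, strict=strict)
        except (SchemaError, OSError, ValueError, KeyError) as exc:
            failures[str(p)] = str(exc)
            continue
        row: dict[str, object] = {
            "file": str(p),
            "title": description.metadata.title,
        }
        for s in result.scores:
            row[f"c{s.criterion_id}"] = s.score
        row["overall"] = result.display_overall
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("overall", ascending=False, kind="stable").reset_index(drop=True)
    return table, failures
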