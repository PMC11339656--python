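"""GHS hazard-statement registry and penalty-point arithmetic.

Greenness criteria that deal with chemicals penalize them through their GHS
hazard statements (H-codes, e.g. ``H225`` "Highly flammable liquid and
vapour").  Each statement carries a nonnegative integer penalty; the more
serious and less avoidable the effect, the higher the penalty.  A substance's
total penalty is the sum over its (deduplicated) H-codes.

The packaged default table (``data/penalty_points_synthetic.csv``) is a
synthetic severity-graded assignment over the standard GHS catalog, authored
for this package: statements implying fatal, carcinogenic, mutagenic or
reprotoxic effects sit at the top of the scale (8-10 points), irritants at
the bottom (2-3), with flammability, corrosivity and aquatic toxicity graded
in between.  It is deliberately user-overridable so that any alternative
penalty convention can be assessed instead.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "HazardCode",
    "PenaltyTable",
    "PenaltyTableError",
    "UnknownHazardError",
    "load_penalty_table",
    "penalty_sum",
]

_H_CODE_RE = re.compile(r"^H\d{3}[A-Z]*$")

_DEFAULT_RESOURCE = "penalty_points_synthetic.csv"


class PenaltyTableError(ValueError):
    """Malformed penalty-table file or invalid entry."""


class UnknownHazardError(KeyError):
    """An H-code was looked up that the table does not contain (strict mode)."""

    def __init__(self, code: str) -> None:
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return f"unknown hazard statement {self.code!r} not present in the penalty table"


def normalize_code(code: str) -> str:
    """Validate and canonicalize an H-code (case-insensitive, stored uppercase).

    >>> normalize_code("h360fd")
    'H360FD'
    """
    canon = str(code).strip().upper()
    if not _H_CODE_RE.match(canon):
        raise PenaltyTableError(
            f"invalid GHS hazard statement {code!r}: expected 'H' followed by "
            "three digits and optional suffix letters (e.g. H225, H360FD)"
        )
    return canon


# ``HazardCode`` is a plain canonicalized string; use :func:`normalize_code`
# to construct one.  Keeping it a ``str`` lets codes live in sets and YAML
# without ceremony.
HazardCode = str


@dataclass(frozen=True)
class PenaltyTable:
    """Mapping from H-codes to nonnegative integer penalty points."""

    entries: Mapping[HazardCode, int]
    source_label: str = "builtin-synthetic"

    def __post_init__(self) -> None:
        canon: dict[str, int] = {}
        for code, points in self.entries.items():
            c = normalize_code(code)
            if c in canon:
                raise PenaltyTableError(f"duplicate hazard code {c!r} in penalty table")
            try:
                p = int(points)
            except (TypeError, ValueError) as exc:
                raise PenaltyTableError(
                    f"penalty points for {c!r} must be an integer, got {points!r}"
                ) from exc
            if isinstance(points, float) and points != p:
                raise PenaltyTableError(
                    f"penalty points for {c!r} must be an integer, got {points!r}"
                )
            if p < 0:
                raise PenaltyTableError(
                    f"penalty points must be nonnegative, got {p} for {c!r}"
                )
            canon[c] = p
        object.__setattr__(self, "entries", dict(canon))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return normalize_code(code) in self.entries

    def codes(self) -> list[HazardCode]:
        return sorted(self.entries)

    def lookup(self, code: str, *, strict: bool = True) -> int:
        """Penalty points for one H-code.

        Exact match first.  In lenient mode an unmatched suffixed code (e.g.
        ``H360FD``) falls back to its four-character stem (``H360``); a code
        that still has no entry contributes 0 with a warning.  In strict mode
        any miss raises :class:`UnknownHazardError` — silent zeros would
        inflate apparent greenness.
        """
        c = normalize_code(code)
        if c in self.entries:
            return self.entries[c]
        if not strict:
            stem = c[:4]
            if stem != c and stem in self.entries:
                return self.entries[stem]
            warnings.warn(
                f"hazard statement {c!r} not in penalty table "
                f"({self.source_label!r}); counting 0 points",
                stacklevel=2,
            )
            return 0
        raise UnknownHazardError(c)

    def save(self, path: str | Path) -> Path:
        """Write the table as canonical ``code,points`` CSV (sorted by code)."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write("code,points\n")
            for code in self.codes():
                fh.write(f"{code},{self.entries[code]}\n")
        return path


def _parse_csv(text: str) -> dict[str, int]:
    rows = [
        row
        for row in csv.reader(io.StringIO(text))
        if row and not row[0].lstrip().startswith("#")
    ]
    if not rows:
        raise PenaltyTableError("empty penalty table file")
    header = [c.strip().lower() for c in rows[0]]
    if header[:2] != ["code", "points"]:
        raise PenaltyTableError(
            f"penalty table CSV must have header 'code,points', got {rows[0]!r}"
        )
    entries: dict[str, int] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 2:
            raise PenaltyTableError(f"row {lineno}: expected 'code,points', got {row!r}")
        code = normalize_code(row[0])
        if code in entries:
            raise PenaltyTableError(f"row {lineno}: duplicate hazard code {code!r}")
        try:
            points = int(row[1])
        except ValueError as exc:
            raise PenaltyTableError(
                f"row {lineno}: points for {code!r} must be an integer, got {row[1]!r}"
            ) from exc
        entries[code] = points
    return entries


def _parse_yaml(text: str) -> dict[str, int]:
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise PenaltyTableError("penalty table YAML must be a non-empty mapping code -> points")
    # YAML mappings cannot hold duplicate keys that survive parsing, but two
    # case variants of one code can; PenaltyTable.__post_init__ catches that.
    return data


def load_penalty_table(path: str | Path | None = None) -> PenaltyTable:
    """Load a penalty table from CSV/YAML, or the packaged default.

    CSV files need a ``code,points`` header; ``#`` lines are comments.  YAML
    files are a flat ``code: points`` mapping.  Duplicate codes, malformed
    codes and negative points are errors.
    """
    if path is None:
        text = (
            resources.files("agreemip").joinpath("data", _DEFAULT_RESOURCE).read_text("utf-8")
        )
        return PenaltyTable(_parse_csv(text), source_label="builtin-synthetic")
    path = Path(path)
    try:
        text = path.read_text("utf-8")
    except OSError as exc:
        raise OSError(f"cannot read penalty table {path}: {exc}") from exc
    if path.suffix.lower() in {".yaml", ".yml"}:
        entries = _parse_yaml(text)
    else:
        entries = _parse_csv(text)
    return PenaltyTable(entries, source_label=str(path))


def penalty_sum(
    codes: Iterable[str], table: PenaltyTable, *, strict: bool = True
) -> int:
    """Sum of penalty points over a set of H-codes.

    Duplicates (after canonicalization) count once; an empty set sums to 0.
    """
    canon = {normalize_code(c) for c in codes}
    return sum(table.lookup(c, strict=strict) for c in sorted(canon))
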