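"""Accessors for the bundled example procedure files.

The bundled fixtures are illustrative: the two synthetic extremes exercise
the score boundaries, and the two literature-style examples are approximate
reconstructions from published narrative summaries (an electropolymerized
film for solid-phase microextraction, and a dual-template silica-surface
polymer with large toluene volumes) — labelled approximate because the full
reagent inventories live in the original publications.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["example_path", "list_examples"]

_EXAMPLES = (
    "example_greenest.yaml",
    "example_worst.yaml",
    "example_electropolymerization.yaml",
    "example_silica_surface.yaml",
)


def list_examples() -> tuple[str, ...]:
    return _EXAMPLES


def example_path(name: str) -> Path:
    """Filesystem path of a bundled example (name with or without .yaml)."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    ref = resources.files("agreemip").joinpath("data", "examples", name)
    with resources.as_file(ref) as p:
        path = Path(p)
    if not path.exists():
        raise FileNotFoundError(
            f"no bundled example {name!r}; available: {', '.join(_EXAMPLES)}"
        )
    return path
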