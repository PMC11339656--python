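"""Traffic-light pictogram of an assessment result.

The pictogram mirrors the imprinted sorbent itself: a large central circle
(the template cavity) carrying the two-decimal overall score, ringed by 12
satellite circles (the functional monomers), one per criterion.  Color
encodes the score along a red-yellow-green gradient from 0 to 1; a
criterion's weight is encoded twice, as satellite size (heavier = bigger)
and as proximity to the center (heavier = closer).  Criterion 1 sits at
twelve o'clock and ids increase clockwise.

Colors and geometry constants live in a :class:`Theme` so alternative
palettes can be swapped in; the contract is the gradient's endpoints and the
bigger-and-closer weight encoding, not particular hex values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .aggregate import AssessmentResult

__all__ = ["Theme", "DEFAULT_THEME", "PictogramSpec", "Satellite", "score_to_color", "layout", "render"]

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class Theme:
    """Palette and geometry of the pictogram (presentation constants)."""

    red: RGB = (214, 39, 38)
    yellow: RGB = (255, 205, 60)
    green: RGB = (35, 148, 58)
    canvas: float = 400.0
    center_radius: float = 70.0
    # satellite radius grows affinely with weight 1..4
    satellite_radius_min: float = 16.0
    satellite_radius_max: float = 28.0
    # distance from center shrinks affinely with weight 1..4
    ring_distance_min: float = 118.0
    ring_distance_max: float = 150.0
    text_color: str = "#1a1a1a"

    def stops(self) -> list[tuple[float, RGB]]:
        return [(0.0, self.red), (0.5, self.yellow), (1.0, self.green)]


DEFAULT_THEME = Theme()


def score_to_color(score: float, theme: Theme = DEFAULT_THEME) -> RGB:
    """Piecewise-linear red -> yellow -> green interpolation over [0, 1]."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    stops = theme.stops()
    for (v0, c0), (v1, c1) in zip(stops, stops[1:]):
        if score <= v1:
            t = 0.0 if v1 == v0 else (score - v0) / (v1 - v0)
            return tuple(round(a + t * (b - a)) for a, b in zip(c0, c1))
    return stops[-1][1]


@dataclass(frozen=True)
class Satellite:
    criterion_id: int
    angle_deg: float      # 0 = twelve o'clock, increasing clockwise
    distance: float       # center-to-center, canvas units
    radius: float
    fill: RGB
    label: str

    def position(self, cx: float, cy: float) -> tuple[float, float]:
        theta = math.radians(self.angle_deg - 90.0)  # SVG y grows downward
        return cx + self.distance * math.cos(theta), cy + self.distance * math.sin(theta)


@dataclass(frozen=True)
class PictogramSpec:
    canvas: float
    center_radius: float
    center_fill: RGB
    center_label: str
    satellites: tuple[Satellite, ...]
    text_color: str = "#1a1a1a"

    def __post_init__(self) -> None:
        ids = sorted(s.criterion_id for s in self.satellites)
        if ids != list(range(1, 13)):
            raise ValueError(f"expected satellites for criteria 1-12, got ids {ids}")


def _affine(weight: int, lo: float, hi: float) -> float:
    return lo + (weight - 1) / 3.0 * (hi - lo)


def layout(result: AssessmentResult, theme: Theme = DEFAULT_THEME) -> PictogramSpec:
    """Place the 12 satellites at equal 30-degree spacing; pure in its inputs."""
    satellites = []
    for score, weight in zip(result.scores, result.weights.weights):
        satellites.append(
            Satellite(
                criterion_id=score.criterion_id,
                angle_deg=(score.criterion_id - 1) * 30.0,
                distance=_affine(weight, theme.ring_distance_max, theme.ring_distance_min),
                radius=_affine(weight, theme.satellite_radius_min, theme.satellite_radius_max),
                fill=score_to_color(score.score, theme),
                label=str(score.criterion_id),
            )
        )
    return PictogramSpec(
        canvas=theme.canvas,
        center_radius=theme.center_radius,
        center_fill=score_to_color(result.display_overall, theme),
        center_label=f"{result.display_overall:.2f}",
        satellites=tuple(satellites),
        text_color=theme.text_color,
    )


def _rgb(c: RGB) -> str:
    return f"rgb({c[0]},{c[1]},{c[2]})"


def _svg(spec: PictogramSpec) -> str:
    cx = cy = spec.canvas / 2.0
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.canvas:g}" '
        f'height="{spec.canvas:g}" viewBox="0 0 {spec.canvas:g} {spec.canvas:g}">',
        f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{spec.center_radius:g}" '
        f'fill="{_rgb(spec.center_fill)}" stroke="{spec.text_color}" stroke-width="1.5"/>',
        f'<text x="{cx:.2f}" y="{cy:.2f}" text-anchor="middle" dominant-baseline="central" '
        f'font-family="Helvetica,Arial,sans-serif" font-size="34" font-weight="bold" '
        f'fill="{spec.text_color}">{spec.center_label}</text>',
    ]
    for sat in sorted(spec.satellites, key=lambda s: s.criterion_id):
        x, y = sat.position(cx, cy)
        parts.append(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{sat.radius:.2f}" '
            f'fill="{_rgb(sat.fill)}" stroke="{spec.text_color}" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{x:.2f}" y="{y:.2f}" text-anchor="middle" dominant-baseline="central" '
            f'font-family="Helvetica,Arial,sans-serif" font-size="{sat.radius * 0.9:.1f}" '
            f'fill="{spec.text_color}">{sat.label}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _png(spec: PictogramSpec, path: Path) -> None:
    # Raster output goes through matplotlib but draws the same geometry
    # resolved by layout(); the SVG branch stays byte-stable plain text.
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    cx = cy = spec.canvas / 2.0
    fig, ax = plt.subplots(figsize=(spec.canvas / 100.0, spec.canvas / 100.0), dpi=100)
    ax.set_xlim(0, spec.canvas)
    ax.set_ylim(spec.canvas, 0)  # match SVG's downward y-axis
    ax.set_aspect("equal")
    ax.axis("off")

    def norm(c: RGB) -> tuple[float, float, float]:
        return tuple(v / 255.0 for v in c)

    ax.add_patch(
        Circle((cx, cy), spec.center_radius, facecolor=norm(spec.center_fill),
               edgecolor=spec.text_color, linewidth=1.5)
    )
    ax.text(cx, cy, spec.center_label, ha="center", va="center",
            fontsize=24, fontweight="bold", color=spec.text_color)
    for sat in spec.satellites:
        x, y = sat.position(cx, cy)
        ax.add_patch(
            Circle((x, y), sat.radius, facecolor=norm(sat.fill),
                   edgecolor=spec.text_color, linewidth=1)
        )
        ax.text(x, y, sat.label, ha="center", va="center",
                fontsize=sat.radius * 0.65, color=spec.text_color)
    fig.savefig(path, format="png")
    plt.close(fig)


def render(spec: PictogramSpec, path: str | Path) -> Path:
    """Write the pictogram; the extension picks SVG (vector) or PNG (raster).

    SVG output is deterministic text: identical specs give identical bytes.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".svg":
        try:
            path.write_text(_svg(spec), encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot write pictogram to {path}: {exc}") from exc
    elif suffix == ".png":
        if not path.parent.exists():
            raise OSError(f"cannot write pictogram to {path}: directory does not exist")
        _png(spec, path)
    else:
        raise ValueError(f"unsupported pictogram format {suffix!r}; use .svg or .png")
    return path
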