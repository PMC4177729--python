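"""The RAG "pizza" plot: a circular patient report whose sectors are the
matched categories, with angles proportional to group weight — a red lesion
(weight 3) draws a sector three times the size of a green one (weight 1).

Rendering is a pure function of the plot spec: no timestamps, no random
ids, fixed colour palette (#d7191c red / #fdae61 amber / #1a9641 green,
colour-blind safe), so the same spec always yields byte-identical SVG.
"""

from __future__ import annotations

import math
from fractions import Fraction
from pathlib import Path
from typing import Union

from pydantic import BaseModel, ConfigDict, Field

from .knowledge_base import GroupLabel
from .scoring import RagResult

__all__ = ["PlotSegment", "PizzaPlotSpec", "PlotError", "build_plot_spec", "render_svg"]

PALETTE = {
    GroupLabel.RED: "#d7191c",
    GroupLabel.AMBER: "#fdae61",
    GroupLabel.GREEN: "#1a9641",
}

_GROUP_ORDER = {GroupLabel.RED: 0, GroupLabel.AMBER: 1, GroupLabel.GREEN: 2}


class PlotError(ValueError):
    """The result cannot be plotted (e.g. unscorable: nothing to draw)."""


class PlotSegment(BaseModel):
    model_config = ConfigDict(frozen=True)

    category: str
    group: GroupLabel
    angle: float = Field(gt=0, le=360)  # sweep, degrees
    start: float = Field(ge=0, lt=360)  # clockwise from twelve o'clock


class PizzaPlotSpec(BaseModel):
    """Renderable segment list; angles sum to 360 degrees."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    segments: tuple[PlotSegment, ...] = Field(min_length=1)
    score: float
    band: str
    total: float = 360.0


def build_plot_spec(result: RagResult) -> PizzaPlotSpec:
    """Lay out one sector per matched category.

    Sector sweep = 360 × weight / Σ weights (exact rational arithmetic, so
    the sweeps sum to 360).  Segments run red → amber → green, alphabetical
    within a group, clockwise from twelve o'clock.
    """
    if not result.matches:
        raise PlotError(
            f"sample {result.sample_id!r} is unscorable (no matched categories); no plot"
        )
    cats = sorted(
        (m.category for m in result.matches),
        key=lambda c: (_GROUP_ORDER[c.group.label], c.name.lower()),
    )
    total_weight = sum(c.weight_int for c in cats)
    segments = []
    start = Fraction(0)
    for c in cats:
        sweep = Fraction(360 * c.weight_int, total_weight)
        segments.append(
            PlotSegment(
                category=c.name,
                group=c.group.label,
                angle=float(sweep),
                start=float(start),
            )
        )
        start += sweep
    return PizzaPlotSpec(
        sample_id=result.sample_id,
        segments=tuple(segments),
        score=result.score,
        band=result.band.value,
    )


_CX, _CY, _R = 200.0, 190.0, 150.0
_LABEL_R = 0.62 * _R


def _point(angle_deg: float) -> tuple[float, float]:
    # clockwise from twelve o'clock on SVG's y-down canvas
    rad = math.radians(angle_deg)
    return (_CX + _R * math.sin(rad), _CY - _R * math.cos(rad))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _sector_path(start: float, sweep: float) -> str:
    x0, y0 = _point(start)
    if sweep >= 360.0 - 1e-9:  # full circle: two half-arcs
        xm, ym = _point(start + 180.0)
        return (
            f"M {_fmt(x0)} {_fmt(y0)} "
            f"A {_fmt(_R)} {_fmt(_R)} 0 1 1 {_fmt(xm)} {_fmt(ym)} "
            f"A {_fmt(_R)} {_fmt(_R)} 0 1 1 {_fmt(x0)} {_fmt(y0)} Z"
        )
    x1, y1 = _point(start + sweep)
    large = 1 if sweep > 180.0 else 0
    return (
        f"M {_fmt(_CX)} {_fmt(_CY)} L {_fmt(x0)} {_fmt(y0)} "
        f"A {_fmt(_R)} {_fmt(_R)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)} Z"
    )


def render_svg(spec: PizzaPlotSpec, path: Union[str, Path]) -> None:
    """Write the plot as standalone SVG 1.1; byte-deterministic per spec."""
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="400" height="440" '
        'viewBox="0 0 400 440" font-family="Helvetica, Arial, sans-serif">',
        f'<title>RAG pizza plot — {spec.sample_id}</title>',
    ]
    for seg in spec.segments:
        parts.append(
            f'<path d="{_sector_path(seg.start, seg.angle)}" fill="{PALETTE[seg.group]}" '
            'stroke="#ffffff" stroke-width="1.5"/>'
        )
    for seg in spec.segments:
        mid = math.radians(seg.start + seg.angle / 2.0)
        lx = _CX + _LABEL_R * math.sin(mid)
        ly = _CY - _LABEL_R * math.cos(mid)
        parts.append(
            f'<text x="{_fmt(lx)}" y="{_fmt(ly)}" font-size="11" text-anchor="middle" '
            f'fill="#000000">{_escape(seg.category)}</text>'
        )
    parts.append(
        f'<text x="{_fmt(_CX)}" y="392" font-size="18" text-anchor="middle" '
        f'fill="#000000">RAG score {spec.score:.2f}</text>'
    )
    parts.append(
        f'<text x="{_fmt(_CX)}" y="414" font-size="13" text-anchor="middle" '
        f'fill="#444444">{_escape(spec.sample_id)} — {_escape(spec.band)}</text>'
    )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n", encoding="utf-8")


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )
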