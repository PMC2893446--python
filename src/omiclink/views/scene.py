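"""Scene description and SVG export.

Every view renders to a :class:`Scene`: a flat list of typed drawing
primitives (rect, line, tick, text, polyline), each carrying the
identifier of the data object it depicts (its *provenance*) and a
highlight flag.  Highlighting is therefore a scene-level attribute driven
by the programmatic selection API — the headless equivalent of linked
brushing.  Scenes serialize to SVG deterministically: re-exporting an
identical scene yields a byte-identical file, and each element carries
its provenance as a ``data-id`` attribute (which is what an optional
HTML/ECMAScript wrapper would hook linked views onto).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Primitive", "Scene", "DivergingScale", "STATE_COLORS",
           "MISSING_COLOR", "HIGHLIGHT_COLOR", "export_svg", "svg_string"]

MISSING_COLOR = "#bdbdbd"
HIGHLIGHT_COLOR = "#000000"

#: fixed categorical scale for copy-number states
STATE_COLORS = {-1.0: "#2166ac", 0.0: "#f7f7f7", 1.0: "#b2182b"}

KINDS = ("rect", "line", "tick", "text", "polyline")


@dataclass(frozen=True)
class Primitive:
    """One drawing element.

    geometry by kind: rect ``(x, y, w, h)``; line/tick ``(x1, y1, x2, y2)``;
    text ``(x, y, string)``; polyline ``((x1, y1), (x2, y2), ...)``.
    """

    kind: str
    geometry: tuple
    color: str
    provenance: str | None = None
    highlighted: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass
class Scene:
    width: float
    height: float
    primitives: list[Primitive] = field(default_factory=list)

    def add(self, kind: str, geometry: tuple, color: str,
            provenance: str | None = None, highlighted: bool = False) -> None:
        self.primitives.append(Primitive(kind, geometry, color, provenance, highlighted))

    def by_kind(self, kind: str) -> list[Primitive]:
        return [p for p in self.primitives if p.kind == kind]

    def highlighted_ids(self) -> set[str]:
        return {p.provenance for p in self.primitives
                if p.highlighted and p.provenance is not None}

    def data_ids(self) -> set[str]:
        return {p.provenance for p in self.primitives if p.provenance is not None}


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    h = h.lstrip("#")
    return tuple(int(h[i:i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#" + "".join(f"{int(round(v)):02x}" for v in rgb)


@dataclass(frozen=True)
class DivergingScale:
    """Symmetric diverging colorscale (default blue–white–red).

    Values are mapped linearly on each side of the midpoint; values beyond
    ``vmin``/``vmax`` clip.  A value exactly at the midpoint maps to the
    mid color exactly; missing values map to the designated missing color.
    """

    vmin: float
    vmax: float
    low: str = "#2166ac"
    mid: str = "#ffffff"
    high: str = "#b2182b"
    missing: str = MISSING_COLOR

    @property
    def midpoint(self) -> float:
        return (self.vmin + self.vmax) / 2.0

    @classmethod
    def from_matrix(cls, values, clip: tuple[float, float] = (1.0, 99.0)) -> "DivergingScale":
        """Symmetric scale clipped at the given percentiles of the data."""
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return cls(-1.0, 1.0)
        lo, hi = np.percentile(v, clip)
        bound = float(max(abs(lo), abs(hi))) or 1.0
        return cls(-bound, bound)

    def __call__(self, value: float) -> str:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return self.missing
        value = min(max(float(value), self.vmin), self.vmax)
        mid = self.midpoint
        if value == mid:
            return self.mid
        if value < mid:
            t = (value - self.vmin) / (mid - self.vmin)
            a, b = _hex_to_rgb(self.low), _hex_to_rgb(self.mid)
        else:
            t = (value - mid) / (self.vmax - mid)
            a, b = _hex_to_rgb(self.mid), _hex_to_rgb(self.high)
        return _rgb_to_hex(tuple(x + (y - x) * t for x, y in zip(a, b)))


# --------------------------------------------------------------------------
# SVG serialization (deterministic: fixed attribute order, fixed number
# formatting, insertion-order elements)

def _num(v: float) -> str:
    s = f"{float(v):.3f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _attrs(p: Primitive) -> str:
    parts = []
    if p.provenance is not None:
        parts.append(f'data-id="{_escape(p.provenance)}"')
    if p.highlighted:
        parts.append('data-highlighted="true"')
        parts.append(f'stroke="{HIGHLIGHT_COLOR}" stroke-width="1.5"')
    return (" " + " ".join(parts)) if parts else ""


def _escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;")
             .replace(">", "&gt;").replace('"', "&quot;"))


def svg_string(scene: Scene) -> str:
    """Serialize a scene to SVG markup (one element per primitive)."""
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_num(scene.width)}" '
        f'height="{_num(scene.height)}" '
        f'viewBox="0 0 {_num(scene.width)} {_num(scene.height)}">\n'
    ]
    for p in scene.primitives:
        if p.kind == "rect":
            x, y, w, h = p.geometry
            out.append(f'<rect x="{_num(x)}" y="{_num(y)}" width="{_num(w)}" '
                       f'height="{_num(h)}" fill="{p.color}"{_attrs(p)}/>\n')
        elif p.kind in ("line", "tick"):
            x1, y1, x2, y2 = p.geometry
            extra = _attrs(p)
            stroke = "" if "stroke=" in extra else f' stroke="{p.color}"'
            out.append(f'<line x1="{_num(x1)}" y1="{_num(y1)}" x2="{_num(x2)}" '
                       f'y2="{_num(y2)}"{stroke}{extra}/>\n')
        elif p.kind == "text":
            x, y, s = p.geometry
            out.append(f'<text x="{_num(x)}" y="{_num(y)}" '
                       f'fill="{p.color}"{_attrs(p)}>{_escape(str(s))}</text>\n')
        elif p.kind == "polyline":
            pts = " ".join(f"{_num(x)},{_num(y)}" for x, y in p.geometry)
            out.append(f'<polyline points="{pts}" fill="none" '
                       f'stroke="{p.color}"{_attrs(p)}/>\n')
    out.append("</svg>\n")
    return "".join(out)


def export_svg(scene: Scene, path) -> None:
    """Write the scene as a valid, deterministic SVG file."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(svg_string(scene))
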