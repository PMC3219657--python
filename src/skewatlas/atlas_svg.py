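"""Static SVG genome-atlas rendering: linear and circular tracks.

Feature tracks are drawn in solid colors; property tracks as
histograms, data dots, or a two-color gradient.  Each track gets a
named SVG group plus a legend (min/max/mean/sd at the legend corners
and the condensation window size below it).  The six exploratory
manipulations (move, rotate, size, opacity, width, flip) are honoured
as static per-track transforms, and the caterpillar device flanks a
linear track with two <use> replicas so horizontal shifts wrap around
like a circular chromosome.

Angle convention for circular layout: position 0 at 12 o'clock,
increasing clockwise.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import yaml
from lxml import etree

from . import genome_io, properties
from .genome_io import FeatureTrack
from .properties import PropertyTrack
from .signal_analysis import resample_weighted

import numpy as np

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"
_NSMAP = {None: SVG_NS, "xlink": XLINK_NS}

#: NCBI COG functional-category color conventions (overridable in config).
COG_PALETTE = {
    "J": "#ff0000", "A": "#ff4500", "K": "#ff7f50", "L": "#ffa500",
    "B": "#ffd700", "D": "#ffff00", "Y": "#adff2f", "V": "#7fff00",
    "T": "#00ff00", "M": "#00fa9a", "N": "#00ffff", "Z": "#00bfff",
    "W": "#1e90ff", "U": "#0000ff", "O": "#8a2be2", "C": "#9400d3",
    "G": "#ff00ff", "E": "#ff1493", "F": "#c71585", "H": "#db7093",
    "I": "#f08080", "P": "#cd5c5c", "Q": "#a0522d", "R": "#808080",
    "S": "#c0c0c0", "X": "#696969",
}

#: default palette for customized features without explicit colors
DEFAULT_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]

FORWARD_CDS_COLOR = "#0000ff"
REVERSE_CDS_COLOR = "#ff0000"

FEATURE_STYLES = ("solid",)
PROPERTY_STYLES = ("histogram", "dots", "gradient")


@dataclass
class TrackTransform:
    """Static analogue of the interactive track manipulations."""

    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0  # degrees, circular layout only
    flip_h: bool = False
    flip_v: bool = False
    caterpillar: bool = False  # linear layout only
    radial_offset: float = 0.0  # "size" manipulation on circular tracks

    def __post_init__(self) -> None:
        self.rotation = self.rotation % 360.0

    def compose(self, other: "TrackTransform") -> "TrackTransform":
        """Apply ``other`` after this transform (translations add,
        rotations add mod 360, flips toggle)."""
        return TrackTransform(
            dx=self.dx + other.dx,
            dy=self.dy + other.dy,
            rotation=(self.rotation + other.rotation) % 360.0,
            flip_h=self.flip_h ^ other.flip_h,
            flip_v=self.flip_v ^ other.flip_v,
            caterpillar=self.caterpillar or other.caterpillar,
            radial_offset=self.radial_offset + other.radial_offset,
        )

    @property
    def is_identity(self) -> bool:
        return (
            self.dx == 0 and self.dy == 0 and self.rotation == 0
            and not self.flip_h and not self.flip_v and self.radial_offset == 0
        )


@dataclass
class TrackSpec:
    """One configured chromosome track."""

    source: Union[FeatureTrack, PropertyTrack]
    style: str = "histogram"
    width: float = 30.0
    opacity: float = 1.0
    colors: tuple[str, str] = ("#00008b", "#8b0000")
    threshold: float | None = None  # default: track mean
    transform: TrackTransform = field(default_factory=TrackTransform)
    seq_length: int | None = None  # display length basis; default source extent

    def validate(self) -> None:
        is_feature = isinstance(self.source, FeatureTrack)
        if is_feature and self.style not in FEATURE_STYLES:
            raise ValueError(
                f"track {self.source.name!r}: style {self.style!r} is only valid "
                "for property tracks (feature tracks are drawn solid)"
            )
        if not is_feature and self.style not in PROPERTY_STYLES:
            raise ValueError(
                f"track {self.source.name!r}: style {self.style!r} invalid for a "
                f"property track; choose one of {PROPERTY_STYLES}"
            )
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must lie in [0, 1]")

    @property
    def length(self) -> int:
        if self.seq_length is not None:
            return self.seq_length
        if isinstance(self.source, PropertyTrack):
            return self.source.coverage_length
        return max((f.end for f in self.source.features), default=1)


@dataclass
class AtlasConfig:
    layout: str = "linear"
    canvas_size: float = 1000.0
    resolution: int = 3000
    spacer: float = 45.0
    scale_mode: str = "proportional"
    tracks: list[TrackSpec] = field(default_factory=list)
    values_outward: bool = True  # circular property values grow outward

    def validate(self) -> None:
        if self.layout not in ("linear", "circular"):
            raise ValueError(f"layout must be linear or circular, got {self.layout!r}")
        if self.canvas_size <= 0:
            raise ValueError("canvas_size must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if self.scale_mode not in ("proportional", "scale_independent"):
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")
        if not self.tracks:
            raise ValueError("an atlas needs at least one track")
        for spec in self.tracks:
            spec.validate()
            if self.layout == "circular" and spec.transform.caterpillar:
                raise ValueError("caterpillar is a linear-layout device")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def linear_x(t: float, display_length: float, span: float, left_margin: float = 0.0) -> float:
    """Map sequence position t (bp) onto the horizontal span."""
    return left_margin + span * (t / display_length)


def circular_point(
    t: float, display_length: float, radius: float,
    center: tuple[float, float], rotation_deg: float = 0.0,
) -> tuple[float, float]:
    """Map position t onto a circle: t=0 at 12 o'clock, clockwise."""
    theta = 2.0 * math.pi * (t / display_length) + math.radians(rotation_deg)
    cx, cy = center
    return (cx + radius * math.sin(theta), cy - radius * math.cos(theta))


def scale_lengths(records, scale_mode: str) -> list[float]:
    """Display lengths for a set of sequences.

    proportional: display length proportional to true bp length;
    scale_independent: every sequence drawn at the same display length.
    """
    lengths = [float(getattr(r, "length", r)) for r in records]
    if not lengths:
        raise ValueError("at least one record required")
    if scale_mode == "scale_independent":
        return [max(lengths)] * len(lengths)
    if scale_mode == "proportional":
        return lengths
    raise ValueError(f"unknown scale_mode {scale_mode!r}")


def _lerp_color(c0: str, c1: str, t: float) -> str:
    r0, g0, b0 = (int(c0[i : i + 2], 16) for i in (1, 3, 5))
    r1, g1, b1 = (int(c1[i : i + 2], 16) for i in (1, 3, 5))
    return "#{:02x}{:02x}{:02x}".format(
        round(r0 + (r1 - r0) * t), round(g0 + (g1 - g0) * t), round(b0 + (b1 - b0) * t)
    )


def style_property(
    values, style: str, colors: tuple[str, str] = ("#00008b", "#8b0000"),
    threshold: float | None = None,
) -> list[dict]:
    """Translate property values into abstract drawable units.

    histogram -> bars from the threshold baseline; dots -> one mark per
    unit at value height; gradient -> per-unit color interpolated
    between the two scheme ends (darkest at min and max).  For
    histogram/dots a two-color rule applies: colors[0] above the
    threshold (default mean), colors[1] at or below it.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("property values must be finite")
    if style not in PROPERTY_STYLES:
        raise ValueError(f"unknown property style {style!r}")
    baseline = float(arr.mean()) if threshold is None else float(threshold)
    units: list[dict] = []
    if style == "gradient":
        lo, hi = float(arr.min()), float(arr.max())
        span = hi - lo
        for i, v in enumerate(arr):
            t = 0.5 if span == 0 else (float(v) - lo) / span
            units.append({"kind": "cell", "unit": i, "value": float(v),
                          "color": _lerp_color(colors[0], colors[1], t)})
        return units
    kind = "bar" if style == "histogram" else "dot"
    for i, v in enumerate(arr):
        above = float(v) > baseline
        units.append({
            "kind": kind, "unit": i, "value": float(v),
            "height": abs(float(v) - baseline), "above": above,
            "color": colors[0] if above else colors[1],
        })
    return units


def assign_feature_colors(track: FeatureTrack, seed: int = 0) -> FeatureTrack:
    """Color a feature track deterministically.

    Tracks named as forward/reverse CDS strands get the conventional
    blue/red; other features lacking an explicit color draw from the
    default palette with a seeded generator.  Explicit colors are
    never touched.
    """
    lowered = track.name.lower()
    strand_color = None
    if "forward" in lowered:
        strand_color = FORWARD_CDS_COLOR
    elif "reverse" in lowered:
        strand_color = REVERSE_CDS_COLOR
    rng = random.Random(seed)
    colored = []
    for f in track.features:
        if f.color:
            colored.append(f)
        elif strand_color:
            colored.append(replace(f, color=strand_color))
        else:
            colored.append(replace(f, color=rng.choice(DEFAULT_PALETTE)))
    return FeatureTrack(name=track.name, seq_id=track.seq_id, features=colored)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_LEGEND_WIDTH = 220.0
_LEGEND_HEIGHT = 64.0


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def _condense_track(track: PropertyTrack, resolution: int) -> np.ndarray:
    """Condense a property to exactly ``resolution`` display units."""
    length = track.coverage_length
    # resolution beyond bp resolution would create sub-bp windows
    units = min(resolution, length)
    properties.window_size_for(length, units)  # validates the pairing
    return resample_weighted(
        np.asarray(track.starts), track.window_size,
        np.asarray(track.values), float(length), units,
    )


def _transform_attr(spec: TrackSpec, config: AtlasConfig, center: tuple[float, float]) -> str:
    t = spec.transform
    parts = []
    if t.dx or t.dy:
        parts.append(f"translate({_fmt(t.dx)},{_fmt(t.dy)})")
    cx, cy = center
    if config.layout == "circular" and t.rotation:
        parts.append(f"rotate({_fmt(t.rotation)},{_fmt(cx)},{_fmt(cy)})")
    if t.flip_h:
        parts.append(f"translate({_fmt(2 * cx)},0) scale(-1,1)")
    if t.flip_v:
        parts.append(f"translate(0,{_fmt(2 * cy)}) scale(1,-1)")
    return " ".join(parts)


def layout_linear(
    spec: TrackSpec, config: AtlasConfig, baseline_y: float,
    display_length: float, span: float, left_margin: float = 0.0,
) -> list[etree._Element]:
    """Draw one track as SVG elements along a horizontal span."""
    elements: list[etree._Element] = []
    scale = display_length / spec.length  # expands shorter sequences
    if isinstance(spec.source, FeatureTrack):
        track = assign_feature_colors(spec.source)
        for f in track.features:
            segments = [(f.start, f.end)] if f.start <= f.end else [
                (f.start, spec.length), (1, f.end)
            ]
            for s, e in segments:
                x0 = linear_x((s - 1) * scale, display_length, span, left_margin)
                x1 = linear_x(e * scale, display_length, span, left_margin)
                elements.append(etree.Element(
                    "rect", x=_fmt(x0), y=_fmt(baseline_y - spec.width),
                    width=_fmt(max(x1 - x0, 0.25)), height=_fmt(spec.width),
                    fill=f.color or "#000000",
                ))
        return elements
    values = _condense_track(spec.source, config.resolution)
    units = style_property(values, spec.style, spec.colors, spec.threshold)
    n = len(units)
    unit_w = span / n
    vmax = max((u.get("height", 0.0) for u in units), default=0.0) or 1.0
    for u in units:
        x = left_margin + u["unit"] * unit_w
        if u["kind"] == "cell":
            elements.append(etree.Element(
                "rect", x=_fmt(x), y=_fmt(baseline_y - spec.width),
                width=_fmt(unit_w), height=_fmt(spec.width), fill=u["color"],
            ))
        elif u["kind"] == "bar":
            h = spec.width * u["height"] / vmax
            y = baseline_y - h if u["above"] else baseline_y
            elements.append(etree.Element(
                "rect", x=_fmt(x), y=_fmt(y), width=_fmt(max(unit_w, 0.1)),
                height=_fmt(max(h, 0.05)), fill=u["color"],
            ))
        else:  # dot
            h = spec.width * u["height"] / vmax
            y = baseline_y - h if u["above"] else baseline_y + h
            elements.append(etree.Element(
                "circle", cx=_fmt(x + unit_w / 2), cy=_fmt(y), r=_fmt(max(unit_w / 2, 0.4)),
                fill=u["color"],
            ))
    return elements


def layout_circular(
    spec: TrackSpec, config: AtlasConfig, radius: float,
    display_length: float, center: tuple[float, float],
) -> list[etree._Element]:
    """Draw one track as an annulus around ``center``."""
    elements: list[etree._Element] = []
    scale = display_length / spec.length
    base_r = radius + spec.transform.radial_offset
    sign = 1.0 if config.values_outward else -1.0
    if isinstance(spec.source, FeatureTrack):
        track = assign_feature_colors(spec.source)
        for f in track.features:
            segments = [(f.start, f.end)] if f.start <= f.end else [
                (f.start, spec.length), (1, f.end)
            ]
            for s, e in segments:
                p0 = circular_point((s - 1) * scale, display_length, base_r, center)
                p1 = circular_point(e * scale, display_length, base_r, center)
                frac = (e - s + 1) * scale / display_length
                large = 1 if frac > 0.5 else 0
                d = (
                    f"M {_fmt(p0[0])} {_fmt(p0[1])} "
                    f"A {_fmt(base_r)} {_fmt(base_r)} 0 {large} 1 {_fmt(p1[0])} {_fmt(p1[1])}"
                )
                el = etree.Element("path", d=d, fill="none")
                el.set("stroke", f.color or "#000000")
                el.set("stroke-width", _fmt(spec.width))
                elements.append(el)
        return elements
    values = _condense_track(spec.source, config.resolution)
    units = style_property(values, spec.style, spec.colors, spec.threshold)
    n = len(units)
    vmax = max((u.get("height", 0.0) for u in units), default=0.0) or 1.0
    for u in units:
        t = (u["unit"] + 0.5) * display_length / n
        if u["kind"] == "cell":
            p0 = circular_point(t, display_length, base_r, center)
            p1 = circular_point(t, display_length, base_r + sign * spec.width, center)
            el = etree.Element(
                "line", x1=_fmt(p0[0]), y1=_fmt(p0[1]), x2=_fmt(p1[0]), y2=_fmt(p1[1])
            )
            el.set("stroke", u["color"])
            elements.append(el)
        elif u["kind"] == "bar":
            h = spec.width * u["height"] / vmax
            r1 = base_r + sign * (h if u["above"] else -h)
            p0 = circular_point(t, display_length, base_r, center)
            p1 = circular_point(t, display_length, r1, center)
            el = etree.Element(
                "line", x1=_fmt(p0[0]), y1=_fmt(p0[1]), x2=_fmt(p1[0]), y2=_fmt(p1[1])
            )
            el.set("stroke", u["color"])
            elements.append(el)
        else:
            h = spec.width * u["height"] / vmax
            r1 = base_r + sign * (h if u["above"] else -h)
            p = circular_point(t, display_length, r1, center)
            elements.append(etree.Element(
                "circle", cx=_fmt(p[0]), cy=_fmt(p[1]), r="0.8", fill=u["color"]
            ))
    return elements


def apply_caterpillar(group: etree._Element, span: float) -> list[etree._Element]:
    """Flank a linear track group with two <use> replicas.

    The replicas sit flush on the left and right of the original so a
    horizontal shift that pushes content off one canvas edge brings it
    back in from the other (circular rotation effect for linear tracks).
    """
    gid = group.get("id")
    if gid is None:
        raise ValueError("caterpillar requires the track group to carry an id")
    uses = []
    for shift in (-span, span):
        use = etree.Element("use")
        use.set("{%s}href" % XLINK_NS, f"#{gid}")
        use.set("href", f"#{gid}")
        use.set("transform", f"translate({_fmt(shift)},0)")
        uses.append(use)
    return uses


def _legend_group(spec: TrackSpec, config: AtlasConfig, index: int, x: float, y: float):
    g = etree.Element("g", id=f"legend-{index}")
    g.set("class", "legend")
    rect = etree.Element(
        "rect", x=_fmt(x), y=_fmt(y), width=_fmt(_LEGEND_WIDTH),
        height=_fmt(_LEGEND_HEIGHT), fill="none"
    )
    rect.set("stroke", "#555555")
    g.append(rect)
    title = etree.Element("text", x=_fmt(x + _LEGEND_WIDTH / 2), y=_fmt(y + _LEGEND_HEIGHT / 2))
    title.set("text-anchor", "middle")
    title.text = spec.source.name
    g.append(title)
    if isinstance(spec.source, PropertyTrack):
        st = spec.source.stats
        corners = [
            (x + 4, y + 12, "start", f"min {_fmt(st['min'])}"),
            (x + _LEGEND_WIDTH - 4, y + 12, "end", f"max {_fmt(st['max'])}"),
            (x + 4, y + _LEGEND_HEIGHT - 4, "start", f"mean {_fmt(st['mean'])}"),
            (x + _LEGEND_WIDTH - 4, y + _LEGEND_HEIGHT - 4, "end", f"sd {_fmt(st['sd'])}"),
        ]
        for cx, cy, anchor, text in corners:
            el = etree.Element("text", x=_fmt(cx), y=_fmt(cy))
            el.set("text-anchor", anchor)
            el.set("font-size", "10")
            el.text = text
            g.append(el)
        length = spec.source.coverage_length
        wsize = properties.window_size_for(length, min(config.resolution, length))
        below = etree.Element("text", x=_fmt(x + _LEGEND_WIDTH / 2), y=_fmt(y + _LEGEND_HEIGHT + 12))
        below.set("text-anchor", "middle")
        below.set("font-size", "10")
        below.text = f"window size = {wsize} bp"
        g.append(below)
    return g


def render_atlas(config: AtlasConfig) -> etree._Element:
    """Render a full genome atlas as an SVG 1.1 element tree.

    One ``<g id="track-i">`` per configured track (in order) plus one
    legend group per track in a right-hand panel.
    """
    config.validate()
    size = config.canvas_size
    legends_x = size + 20.0
    total_w = size + 40.0 + _LEGEND_WIDTH
    n = len(config.tracks)
    total_h = max(size, n * (_LEGEND_HEIGHT + 24.0) + 20.0)
    svg = etree.Element("svg", nsmap=_NSMAP)
    svg.set("version", "1.1")
    svg.set("width", _fmt(total_w))
    svg.set("height", _fmt(total_h))
    svg.set("viewBox", f"0 0 {_fmt(total_w)} {_fmt(total_h)}")

    display = scale_lengths([s.length for s in config.tracks], config.scale_mode)
    center = (size / 2.0, size / 2.0)
    span = size * 0.9
    left_margin = size * 0.05
    for i, (spec, dlen) in enumerate(zip(config.tracks, display)):
        g = etree.Element("g", id=f"track-{i}")
        g.set("class", "track")
        if spec.opacity != 1.0:
            g.set("opacity", _fmt(spec.opacity))
        tattr = _transform_attr(spec, config, center)
        if tattr:
            g.set("transform", tattr)
        if config.layout == "linear":
            baseline = 40.0 + i * (spec.width + config.spacer)
            inner = etree.Element("g", id=f"track-{i}-content")
            for el in layout_linear(spec, config, baseline, dlen, span, left_margin):
                inner.append(el)
            g.append(inner)
            if spec.transform.caterpillar:
                for use in apply_caterpillar(inner, span):
                    g.append(use)
        else:
            margin = 30.0
            available = size / 2.0 - margin
            ring = available / max(n, 1)
            radius = margin * 0.5 + (i + 0.5) * ring
            for el in layout_circular(spec, config, radius, dlen, center):
                g.append(el)
        svg.append(g)
        svg.append(_legend_group(spec, config, i, legends_x, 20.0 + i * (_LEGEND_HEIGHT + 24.0)))
    return svg


def svg_to_string(svg: etree._Element) -> str:
    return etree.tostring(
        svg, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


def write_svg(svg: etree._Element, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(etree.tostring(svg, pretty_print=True, xml_declaration=True, encoding="UTF-8"))
    return path


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> AtlasConfig:
    """Load an atlas configuration from a YAML file.

    Track sources are GDF paths resolved relative to the config file.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base = path.parent
    tracks = []
    for i, t in enumerate(raw.get("tracks", [])):
        src_path = t.get("source")
        if src_path is None:
            raise ValueError(f"{path}: tracks[{i}].source is required")
        src_file = (base / src_path).resolve()
        if not src_file.exists():
            raise FileNotFoundError(f"{path}: tracks[{i}].source: no such file {src_file}")
        source = genome_io.read_gdf(src_file)
        tr = t.get("transform", {}) or {}
        colors = t.get("colors")
        spec = TrackSpec(
            source=source,
            style=t.get("style", "histogram" if isinstance(source, PropertyTrack) else "solid"),
            width=float(t.get("width", 30.0)),
            opacity=float(t.get("opacity", 1.0)),
            colors=tuple(colors) if colors else ("#00008b", "#8b0000"),
            threshold=t.get("threshold"),
            transform=TrackTransform(
                dx=float(tr.get("dx", 0.0)), dy=float(tr.get("dy", 0.0)),
                rotation=float(tr.get("rotation", 0.0)),
                flip_h=bool(tr.get("flip_h", False)), flip_v=bool(tr.get("flip_v", False)),
                caterpillar=bool(tr.get("caterpillar", False)),
                radial_offset=float(tr.get("radial_offset", 0.0)),
            ),
            seq_length=t.get("seq_length"),
        )
        tracks.append(spec)
    return AtlasConfig(
        layout=raw.get("layout", "linear"),
        canvas_size=float(raw.get("canvas_size", 1000.0)),
        resolution=int(raw.get("resolution", 3000)),
        spacer=float(raw.get("spacer", 45.0)),
        scale_mode=raw.get("scale_mode", "proportional"),
        tracks=tracks,
        values_outward=bool(raw.get("values_outward", True)),
    )
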