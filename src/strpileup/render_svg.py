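"""SVG rendering of a haplotype-resolved pileup.

One track per haplotype: flanks in grey, each repeat tract in its own shade
with an allele-length label ("30 x CGG"); below the track, reads packed into
lanes as rectangles. Glyphs: mismatched bases drawn as small rectangles in
the conventional base colors, deletions as a thin connector line across the
gap, insertions as a caret at the insertion point; read pairs whose
haplotype assignment is ambiguous are drawn at reduced opacity. Output is
deterministic for fixed inputs.

Repeats longer than the page are compressed with a piecewise-linear x-map
(constant segments keep their scale) and the compression factor is annotated.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence
from xml.etree import ElementTree as ET

from .catalog_io import StrSpec
from .haplotype_model import Haplotype, HaplotypePair
from .pileup import Pileup, PileupMetrics

BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728", "N": "#7f7f7f"}
REPEAT_SHADES = ["#4878a8", "#8a5fa8", "#3f8f6a", "#a8684a"]


@dataclass(frozen=True)
class RenderOptions:
    px_per_bp: float = 3.0
    lane_height_px: int = 8
    track_height_px: int = 14
    flank_color: str = "#b0b0b0"
    read_color: str = "#6f8fb4"
    clip_color: str = "#d9d9d9"
    indel_color: str = "#222222"
    insertion_color: str = "#7b2d8b"
    faint_opacity: float = 0.35
    show_allele_labels: bool = True
    max_width_px: int = 4000
    margin_px: int = 20
    label_height_px: int = 14
    draw_mate_connectors: bool = False

    def __post_init__(self):
        if self.px_per_bp <= 0:
            raise ValueError("px_per_bp must be positive")
        if not 0 < self.faint_opacity < 1:
            raise ValueError("faint_opacity must lie in (0, 1)")


class _XMap:
    """Piecewise-linear bp -> px map; repeat tracts may be scale-compressed."""

    def __init__(self, hap: Haplotype, opts: RenderOptions):
        ppb = opts.px_per_bp
        segs = list(zip(hap.locus.segments, hap.segment_map))
        const_bp = sum(b - a for seg, (a, b) in segs if not isinstance(seg, StrSpec))
        repeat_bp = len(hap.sequence) - const_bp
        natural = len(hap.sequence) * ppb
        self.repeat_scale = 1.0
        self.global_ppb = ppb
        if natural > opts.max_width_px:
            if repeat_bp > 0:
                f = (opts.max_width_px / ppb - const_bp) / repeat_bp
                if f > 0.01:
                    self.repeat_scale = min(f, 1.0)
                else:
                    self.global_ppb = opts.max_width_px / max(len(hap.sequence), 1)
            else:
                self.global_ppb = opts.max_width_px / max(len(hap.sequence), 1)
        self._bp: list = [0]
        self._px: list = [0.0]
        self._scale: list = []
        x = 0.0
        for seg, (a, b) in segs:
            scale = self.global_ppb * (
                self.repeat_scale if isinstance(seg, StrSpec) else 1.0
            )
            x += (b - a) * scale
            self._bp.append(b)
            self._px.append(x)
            self._scale.append(scale)
        self.width = x

    def x(self, pos: int) -> float:
        i = bisect.bisect_right(self._bp, pos) - 1
        i = min(max(i, 0), len(self._scale) - 1)
        return self._px[i] + (pos - self._bp[i]) * self._scale[i]


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _rect(parent, x, y, w, h, fill, cls, opacity=None):
    attrs = {
        "x": _fmt(x), "y": _fmt(y), "width": _fmt(max(w, 0.5)), "height": _fmt(h),
        "fill": fill, "class": cls,
    }
    if opacity is not None:
        attrs["opacity"] = _fmt(opacity)
    return ET.SubElement(parent, "rect", attrs)


def _draw_read(parent, placed, xmap, y, opts: RenderOptions):
    aln = placed.aln
    h = opts.lane_height_px - 2
    opacity = opts.faint_opacity if placed.faint else None
    group = ET.SubElement(parent, "g", {"class": "read", "data-class": placed.read_class})
    if opacity is not None:
        group.set("opacity", _fmt(opacity))
    pos = aln.start
    read_off = 0
    for op, ln, payload in aln.ops:
        if op in ("match", "mismatch"):
            x0, x1 = xmap.x(pos), xmap.x(pos + ln)
            _rect(group, x0, y, x1 - x0, h, opts.read_color, "readseg")
            if op == "mismatch":
                for k, base in enumerate(payload or ""):
                    bx0, bx1 = xmap.x(pos + k), xmap.x(pos + k + 1)
                    _rect(group, bx0, y, bx1 - bx0, h,
                          BASE_COLORS.get(base, BASE_COLORS["N"]), "mismatch")
            pos += ln
            read_off += ln
        elif op == "deletion":
            x0, x1 = xmap.x(pos), xmap.x(pos + ln)
            _rect(group, x0, y + h / 2 - 0.5, x1 - x0, 1.0, opts.indel_color, "deletion")
            pos += ln
        elif op == "insertion":
            x0 = xmap.x(pos)
            pts = f"{_fmt(x0 - 2)},{_fmt(y + h)} {_fmt(x0 + 2)},{_fmt(y + h)} {_fmt(x0)},{_fmt(y + h - 4)}"
            ET.SubElement(group, "polygon", {
                "points": pts, "fill": opts.insertion_color, "class": "insertion",
            })
            read_off += ln
        elif op == "softclip":
            # clipped bases drawn pale, extending outward from the aligned core
            width_bp = ln
            if read_off == 0:
                x0, x1 = xmap.x(max(pos - width_bp, 0)), xmap.x(pos)
            else:
                x0, x1 = xmap.x(pos), xmap.x(pos + width_bp)
            _rect(group, x0, y, x1 - x0, h, opts.clip_color, "softclip", opacity=0.6)
            read_off += ln


def render(
    pileup: Pileup,
    pair: Optional[HaplotypePair] = None,
    metrics: Optional[PileupMetrics] = None,
    opts: Optional[RenderOptions] = None,
) -> str:
    """Render the pileup to an SVG 1.1 document string."""
    pair = pair or pileup.pair
    opts = opts or RenderOptions()
    haps = pair.haplotypes
    xmaps = [_XMap(h, opts) for h in haps]
    width = max(xm.width for xm in xmaps) + 2 * opts.margin_px

    root = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
    })
    y = float(opts.margin_px)
    for hi, (hap, xmap) in enumerate(zip(haps, xmaps)):
        track = ET.SubElement(root, "g", {"class": "track", "data-hap": str(hi)})
        # allele labels
        if opts.show_allele_labels:
            for seg, (a, b) in zip(hap.locus.segments, hap.segment_map):
                if isinstance(seg, StrSpec):
                    count = hap.count_for(seg.str_id)
                    lbl = ET.SubElement(track, "text", {
                        "x": _fmt(opts.margin_px + (xmap.x(a) + xmap.x(b)) / 2),
                        "y": _fmt(y + opts.label_height_px - 4),
                        "class": "allele-label",
                        "text-anchor": "middle",
                        "font-size": "11",
                        "font-family": "monospace",
                    })
                    lbl.text = f"{count} × {seg.repeat_unit}"
        y += opts.label_height_px
        # haplotype bar
        for si, (seg, (a, b)) in enumerate(zip(hap.locus.segments, hap.segment_map)):
            if b <= a:
                continue
            if isinstance(seg, StrSpec):
                fill = REPEAT_SHADES[seg.index_in_locus % len(REPEAT_SHADES)]
                cls = "repeat-tract"
            else:
                fill, cls = opts.flank_color, "flank"
            _rect(track, opts.margin_px + xmap.x(a), y, xmap.x(b) - xmap.x(a),
                  opts.track_height_px, fill, cls)
        if xmap.repeat_scale < 1.0:
            note = ET.SubElement(track, "text", {
                "x": _fmt(opts.margin_px), "y": _fmt(y - 2),
                "class": "scale-note", "font-size": "9", "font-family": "monospace",
            })
            note.text = f"repeat x-scale ×{xmap.repeat_scale:.2f}"
        y += opts.track_height_px + 4
        # lanes
        placed = sorted(
            pileup.by_hap(hi),
            key=lambda p: (p.lane, p.aln.start, p.aln.mate_index, p.fragment_id),
        )
        n_lanes = max((p.lane for p in placed), default=-1) + 1
        lanes_g = ET.SubElement(track, "g", {"class": "lanes"})
        lanes_g.set("transform", f"translate({_fmt(float(opts.margin_px))},0)")
        if opts.draw_mate_connectors:
            by_frag: dict = {}
            for p in placed:
                by_frag.setdefault(p.fragment_id, []).append(p)
            for members in by_frag.values():
                if len(members) == 2 and members[0].lane == members[1].lane:
                    a, b = sorted(members, key=lambda p: p.aln.start)
                    if a.aln.end < b.aln.start:
                        ly = y + a.lane * opts.lane_height_px + (opts.lane_height_px - 2) / 2
                        ET.SubElement(lanes_g, "line", {
                            "x1": _fmt(xmap.x(a.aln.end)), "x2": _fmt(xmap.x(b.aln.start)),
                            "y1": _fmt(ly), "y2": _fmt(ly),
                            "stroke": "#cccccc", "class": "mate-connector",
                        })
        for p in placed:
            _draw_read(lanes_g, p, xmap, y + p.lane * opts.lane_height_px, opts)
        y += max(n_lanes, 1) * opts.lane_height_px + opts.margin_px

    if not pileup.placed:
        banner = ET.SubElement(root, "text", {
            "x": _fmt(opts.margin_px), "y": _fmt(y),
            "class": "banner", "font-size": "12", "font-family": "monospace",
            "fill": "#a00000",
        })
        banner.text = "no reads placed at this locus"
        y += opts.label_height_px

    root.set("width", _fmt(width))
    root.set("height", _fmt(y + opts.margin_px))
    body = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
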