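"""Windowed rendering of annotated alignments.

Two emitters share one layout computation:

* :func:`render_html` — a self-contained HTML document (inline CSS, no
  scripts, no network fetches) with a region track, a notification row of
  red asterisks over modified columns, the colour-coded alignment grid with
  annotated cells drawn round and CSS-only hover pop-ups, an optional
  consensus row, and row labels hyperlinked to their source database.
* :func:`render_svg` — the same grid semantics as a static vector figure
  (pop-ups omitted), rasterizable to PNG.

Both emit only the columns inside the plan's window and the rows not
excluded, and both are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field, replace

from .annotations import (
    AnnotationSet,
    ColumnIndex,
    ModificationAnnotation,
    RegionAnnotation,
    VariantAnnotation,
    index_by_column,
)
from .coords import build_position_map, ungapped_to_column
from .errors import RenderError
from .io import Alignment, consensus as _consensus
from .schemes import ColorScheme

__all__ = ["RenderPlan", "render_html", "render_svg", "paginate"]

_LANE_PX = 14  # height of one region-track lane and of the notification row
_TAG_RE = re.compile(r"<[^>]*>")


@dataclass(frozen=True)
class RenderPlan:
    """Resolved rendering options consumed by both emitters."""

    scheme: ColorScheme
    window: tuple[int, int] | None = None  # inclusive columns; None = all
    show_consensus: bool = True
    excluded: frozenset = frozenset()
    cell_px: int = 18
    label_gutter: int = 120
    mark_annotated: bool = True
    sanitize: bool = False


def paginate(aln: Alignment, chunk: int) -> list[tuple[int, int]]:
    """Partition 1..n_columns into consecutive inclusive windows of width
    at most ``chunk`` — the static analogue of render-as-you-scroll."""
    if chunk < 1:
        raise ValueError(f"chunk must be >= 1, got {chunk}")
    n = aln.n_columns
    return [(a, min(a + chunk - 1, n)) for a in range(1, n + 1, chunk)]


# ---------------------------------------------------------------------------
# shared layout


@dataclass
class _Layout:
    rows: list[int]
    a: int
    b: int
    index: ColumnIndex
    annotated_cells: set  # {(seq_index, column)}
    modified_columns: set  # columns carrying >= 1 modification
    lanes: list[list[tuple[int, int, RegionAnnotation]]]  # stacked region spans
    consensus_letters: str

    @property
    def width_cols(self) -> int:
        return self.b - self.a + 1


def _region_span(region: RegionAnnotation, aln: Alignment) -> tuple[int, int]:
    if region.is_global:
        return region.start, region.end
    pmap = build_position_map(aln, region.seq_index)
    return (
        ungapped_to_column(pmap, region.start),
        ungapped_to_column(pmap, region.end),
    )


def _stack_lanes(
    spans: list[tuple[int, int, RegionAnnotation]]
) -> list[list[tuple[int, int, RegionAnnotation]]]:
    # Greedy interval-graph colouring by start column.
    lanes: list[list[tuple[int, int, RegionAnnotation]]] = []
    for start, end, region in sorted(spans, key=lambda s: (s[0], s[1])):
        for lane in lanes:
            if lane[-1][1] < start:
                lane.append((start, end, region))
                break
        else:
            lanes.append([(start, end, region)])
    return lanes


def _prepare(aln: Alignment, aset: AnnotationSet | None, plan: RenderPlan) -> _Layout:
    n = aln.n_columns
    a, b = plan.window if plan.window is not None else (1, n)
    if a > b:
        raise RenderError(f"empty window: {a}-{b}")
    if a < 1 or b > n:
        raise RenderError(f"window {a}-{b} outside alignment columns 1..{n}")
    rows = [i for i in range(len(aln.records)) if i not in plan.excluded]
    if not rows:
        raise RenderError("nothing to render: every sequence is excluded")

    aset = aset if aset is not None else AnnotationSet()
    index = index_by_column(aset, aln)
    annotated = set()
    modified = set()
    for col, bucket in index.buckets.items():
        for kind, ann in bucket:
            annotated.add((ann.seq_index, col))
            if kind == "modification":
                modified.add(col)

    spans = []
    for region in aset.regions:
        start, end = _region_span(region, aln)
        if end < a or start > b:
            continue
        spans.append((max(start, a), min(end, b), region))
    lanes = _stack_lanes(spans)

    cons = _consensus(aln).letters if plan.show_consensus else ""
    return _Layout(
        rows=rows,
        a=a,
        b=b,
        index=index,
        annotated_cells=annotated,
        modified_columns=modified,
        lanes=lanes,
        consensus_letters=cons,
    )


def _note_html(note: str, sanitize: bool) -> str:
    # Notes may deliberately carry raw HTML (images, links) for the pop-up;
    # sanitize strips every tag for untrusted inputs.
    return _TAG_RE.sub("", note) if sanitize else note


# ---------------------------------------------------------------------------
# HTML emitter


def _popup_entry(kind: str, ann, aln: Alignment, sanitize: bool) -> str:
    esc = _html.escape
    parts: list[str] = []
    label = aln.records[ann.seq_index].label
    if kind == "variant":
        head = ann.token or "variant"
        parts.append(f"<b>{esc(head)}</b> &mdash; {esc(label)} pos {ann.position}")
        if ann.variant_id:
            parts.append(f"ID: {esc(ann.variant_id)}")
        if ann.source:
            parts.append(f"Source: {esc(ann.source)}")
        for key, value in ann.attributes.items():
            parts.append(f"{esc(key)}: {esc(value)}")
        if ann.note:
            parts.append(_note_html(ann.note, sanitize))
        if ann.url:
            parts.append(f'<a href="{esc(ann.url)}">link</a>')
    else:
        head = ann.mod_type or "modification"
        parts.append(f"<b>{esc(head)}</b> &mdash; {esc(label)} pos {ann.position}")
        for key, value in ann.attributes.items():
            parts.append(f"{esc(key)}: {esc(value)}")
        if ann.note:
            parts.append(_note_html(ann.note, sanitize))
        if ann.url:
            parts.append(f'<a href="{esc(ann.url)}">link</a>')
    return '<div class="entry">' + "<br/>".join(parts) + "</div>"


_CSS = """\
body {{ font-family: monospace; margin: 12px; }}
.msa {{ white-space: nowrap; }}
.row {{ height: {cell}px; line-height: {cell}px; }}
.gutter {{ display: inline-block; width: {gutter}px; overflow: hidden;
  vertical-align: top; text-align: right; padding-right: 4px;
  box-sizing: border-box; }}
.gutter a {{ color: #1a4d8f; text-decoration: none; }}
.cell {{ display: inline-block; width: {cell}px; height: {cell}px;
  text-align: center; vertical-align: top; position: relative;
  box-sizing: border-box; }}
.an {{ border-radius: 50%; border: 1px solid #444; }}
.ncell {{ display: inline-block; width: {cell}px; text-align: center;
  color: #cc0000; font-weight: bold; }}
.ccell {{ display: inline-block; width: {cell}px; text-align: center;
  background: #eeeeee; }}
.lane {{ height: {lane}px; line-height: {lane}px; font-size: {lanefont}px; }}
.lane span {{ display: inline-block; height: {lane}px; overflow: hidden;
  vertical-align: top; box-sizing: border-box; text-align: center; }}
.region {{ border: 1px solid #666; }}
.region a {{ color: inherit; text-decoration: none; }}
.popup {{ display: none; position: absolute; left: 0; top: {cell}px;
  z-index: 10; background: #ffffff; border: 1px solid #888; padding: 6px;
  min-width: 220px; text-align: left; white-space: normal;
  font-size: 12px; line-height: 1.4; }}
.cell:hover .popup {{ display: block; }}
"""


def render_html(
    aln: Alignment, aset: AnnotationSet | None, plan: RenderPlan
) -> str:
    """Emit a self-contained annotated-alignment HTML document."""
    lay = _prepare(aln, aset, plan)
    aset = aset if aset is not None else AnnotationSet()
    esc = _html.escape
    cell = plan.cell_px
    out: list[str] = []
    out.append("<!DOCTYPE html>")
    out.append('<html><head><meta charset="utf-8"/>')
    out.append("<title>alignment</title>")
    out.append(
        "<style>\n"
        + _CSS.format(
            cell=cell,
            gutter=plan.label_gutter,
            lane=_LANE_PX,
            lanefont=_LANE_PX - 4,
        )
        + "</style></head><body>"
    )
    out.append('<div class="msa">')

    # region track lanes
    for lane in lay.lanes:
        out.append('<div class="row lane"><span class="gutter"></span>')
        cursor = lay.a
        for start, end, region in lane:
            if start > cursor:
                out.append(
                    f'<span style="width:{(start - cursor) * cell}px"></span>'
                )
            width = (end - start + 1) * cell
            color = region.color or "#d8d8ef"
            text = esc(region.label)
            if region.url:
                text = f'<a href="{esc(region.url)}">{text}</a>'
            out.append(
                f'<span class="region" style="width:{width}px;'
                f'background:{esc(color)}" title="{esc(region.label)}">{text}</span>'
            )
            cursor = end + 1
        out.append("</div>")

    # notification row: asterisk over every modified column
    out.append('<div class="row notifrow"><span class="gutter"></span>')
    for col in range(lay.a, lay.b + 1):
        mark = "*" if col in lay.modified_columns else "&nbsp;"
        out.append(f'<span class="ncell">{mark}</span>')
    out.append("</div>")

    # sequence rows
    for idx in lay.rows:
        rec = aln.records[idx]
        ident = rec.identity
        label = esc(rec.label)
        if ident.url:
            label = f'<a href="{esc(ident.url)}">{label}</a>'
        out.append(f'<div class="row"><span class="gutter">{label}</span>')
        for col in range(lay.a, lay.b + 1):
            ch = rec.letters[col - 1]
            color = plan.scheme.color_of(ch)
            if plan.mark_annotated and (idx, col) in lay.annotated_cells:
                popup = "".join(
                    _popup_entry(kind, ann, aln, plan.sanitize)
                    for kind, ann in lay.index.buckets.get(col, [])
                )
                out.append(
                    f'<span class="cell an" style="background:{color}">{ch}'
                    f'<span class="popup">{popup}</span></span>'
                )
            else:
                out.append(
                    f'<span class="cell sq" style="background:{color}">{ch}</span>'
                )
        out.append("</div>")

    # consensus row
    if plan.show_consensus:
        out.append('<div class="row"><span class="gutter">Consensus</span>')
        for col in range(lay.a, lay.b + 1):
            out.append(f'<span class="ccell">{lay.consensus_letters[col - 1]}</span>')
        out.append("</div>")

    out.append("</div></body></html>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# SVG emitter


def render_svg(aln: Alignment, aset: AnnotationSet | None, plan: RenderPlan) -> str:
    """Emit the alignment window as a static SVG figure.

    Canvas width is ``label_gutter + window_width * cell_px``; height is the
    track band (one lane per stacked region row plus the notification row)
    plus one ``cell_px`` row per visible sequence, plus the consensus row
    when enabled.
    """
    lay = _prepare(aln, aset, plan)
    cell = plan.cell_px
    gutter = plan.label_gutter
    tracks_h = len(lay.lanes) * _LANE_PX + _LANE_PX
    n_rows = len(lay.rows) + (1 if plan.show_consensus else 0)
    width = gutter + lay.width_cols * cell
    height = tracks_h + n_rows * cell
    font = max(6, round(cell * 0.6))
    lane_font = _LANE_PX - 4

    def x_of(col: int) -> int:
        return gutter + (col - lay.a) * cell

    esc = _html.escape
    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="monospace">'
    )
    out.append(f'<rect x="0" y="0" width="{width}" height="{height}" fill="#ffffff"/>')

    y = 0
    for lane in lay.lanes:
        for start, end, region in lane:
            rx = x_of(start)
            rw = (end - start + 1) * cell
            color = region.color or "#d8d8ef"
            out.append(
                f'<rect class="region" x="{rx}" y="{y + 1}" width="{rw}" '
                f'height="{_LANE_PX - 2}" fill="{esc(color)}" stroke="#666666"/>'
            )
            label = esc(region.label)
            text = (
                f'<text x="{rx + rw // 2}" y="{y + _LANE_PX - 3}" '
                f'font-size="{lane_font}" text-anchor="middle">{label}</text>'
            )
            if region.url:
                text = f'<a href="{esc(region.url)}">{text}</a>'
            out.append(text)
        y += _LANE_PX

    # notification row
    for col in sorted(lay.modified_columns):
        if lay.a <= col <= lay.b:
            out.append(
                f'<text class="notif" x="{x_of(col) + cell // 2}" y="{y + _LANE_PX - 2}" '
                f'font-size="{_LANE_PX}" text-anchor="middle" fill="#cc0000">*</text>'
            )
    y += _LANE_PX

    for idx in lay.rows:
        rec = aln.records[idx]
        label_text = (
            f'<text x="{gutter - 6}" y="{y + cell - font // 2}" font-size="{font}" '
            f'text-anchor="end">{esc(rec.label[:18])}</text>'
        )
        ident = rec.identity
        if ident.url:
            label_text = f'<a href="{esc(ident.url)}">{label_text}</a>'
        out.append(label_text)
        for col in range(lay.a, lay.b + 1):
            ch = rec.letters[col - 1]
            color = plan.scheme.color_of(ch)
            cx = x_of(col)
            if plan.mark_annotated and (idx, col) in lay.annotated_cells:
                r = cell // 2 - 1
                out.append(
                    f'<circle class="cell an" cx="{cx + cell // 2}" cy="{y + cell // 2}" '
                    f'r="{r}" fill="{color}" stroke="#444444"/>'
                )
            else:
                out.append(
                    f'<rect class="cell sq" x="{cx}" y="{y}" width="{cell}" '
                    f'height="{cell}" fill="{color}" stroke="#dddddd"/>'
                )
            out.append(
                f'<text x="{cx + cell // 2}" y="{y + cell - font // 2}" '
                f'font-size="{font}" text-anchor="middle">{ch}</text>'
            )
        y += cell

    if plan.show_consensus:
        out.append(
            f'<text x="{gutter - 6}" y="{y + cell - font // 2}" font-size="{font}" '
            f'text-anchor="end">Consensus</text>'
        )
        for col in range(lay.a, lay.b + 1):
            cx = x_of(col)
            out.append(
                f'<rect class="ccell" x="{cx}" y="{y}" width="{cell}" height="{cell}" '
                f'fill="#eeeeee" stroke="#dddddd"/>'
            )
            out.append(
                f'<text x="{cx + cell // 2}" y="{y + cell - font // 2}" '
                f'font-size="{font}" text-anchor="middle">{lay.consensus_letters[col - 1]}</text>'
            )

    out.append("</svg>")
    return "\n".join(out) + "\n"
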