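"""Rasterize the package's own SVG output to PNG.

:func:`render_svg` emits a small, fixed element vocabulary — ``rect``,
``circle``, ``text`` and ``a`` wrappers — so rasterization is a direct walk
of the SVG tree drawn onto a Pillow canvas.  Pixel dimensions equal the SVG
dimensions scaled by ``dpi / 96`` (rounded), 96 dpi being CSS reference
resolution.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET

from PIL import Image, ImageColor, ImageDraw, ImageFont

__all__ = ["rasterize_png", "png_size"]

_SVG_NS = "{http://www.w3.org/2000/svg}"
_BASE_DPI = 96.0


def _strip(tag: str) -> str:
    return tag[len(_SVG_NS):] if tag.startswith(_SVG_NS) else tag


def _rgb(color: str):
    try:
        return ImageColor.getrgb(color)
    except ValueError:
        return (255, 255, 255)


def _font(size: int):
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # very old Pillow
        return ImageFont.load_default()


def png_size(svg_text: str, dpi: int) -> tuple[int, int]:
    """Pixel dimensions the PNG will have at the given dpi."""
    root = ET.fromstring(svg_text)
    w = float(root.get("width"))
    h = float(root.get("height"))
    scale = dpi / _BASE_DPI
    return round(w * scale), round(h * scale)


def rasterize_png(svg_text: str, dpi: int = 96) -> bytes:
    """Render SVG text (as produced by :func:`~alnmark.render.render_svg`)
    to PNG bytes at the requested resolution."""
    if dpi < 1:
        raise ValueError(f"dpi must be >= 1, got {dpi}")
    root = ET.fromstring(svg_text)
    scale = dpi / _BASE_DPI
    size = png_size(svg_text, dpi)
    img = Image.new("RGB", size, (255, 255, 255))
    draw = ImageDraw.Draw(img)
    fonts: dict[int, object] = {}

    def font_for(px: float):
        key = max(4, round(px * scale))
        if key not in fonts:
            fonts[key] = _font(key)
        return fonts[key]

    def walk(elem) -> None:
        for child in elem:
            tag = _strip(child.tag)
            if tag == "a":
                walk(child)
                continue
            if tag == "rect":
                x = float(child.get("x", 0)) * scale
                y = float(child.get("y", 0)) * scale
                w = float(child.get("width", 0)) * scale
                h = float(child.get("height", 0)) * scale
                fill = child.get("fill", "none")
                stroke = child.get("stroke")
                draw.rectangle(
                    [x, y, x + w, y + h],
                    fill=_rgb(fill) if fill != "none" else None,
                    outline=_rgb(stroke) if stroke else None,
                )
            elif tag == "circle":
                cx = float(child.get("cx", 0)) * scale
                cy = float(child.get("cy", 0)) * scale
                r = float(child.get("r", 0)) * scale
                fill = child.get("fill", "none")
                stroke = child.get("stroke")
                draw.ellipse(
                    [cx - r, cy - r, cx + r, cy + r],
                    fill=_rgb(fill) if fill != "none" else None,
                    outline=_rgb(stroke) if stroke else None,
                )
            elif tag == "text":
                x = float(child.get("x", 0)) * scale
                y = float(child.get("y", 0)) * scale
                px = float(child.get("font-size", 12))
                fill = child.get("fill", "#000000")
                anchor = child.get("text-anchor", "start")
                text = child.text or ""
                fnt = font_for(px)
                # SVG y is the baseline; Pillow anchors give us the same.
                pil_anchor = {"start": "ls", "middle": "ms", "end": "rs"}[anchor]
                draw.text((x, y), text, fill=_rgb(fill), font=fnt, anchor=pil_anchor)
            else:
                walk(child)

    walk(root)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
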