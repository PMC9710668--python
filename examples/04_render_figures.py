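"""Render an annotated alignment window to HTML, SVG and PNG.

The HTML is self-contained (CSS-only hover pop-ups); the SVG/PNG carry the
same grid with annotated cells drawn round and modified columns starred.
"""

from pathlib import Path

from alnmark import (
    RenderPlan,
    ToySpec,
    get_scheme,
    load_annotations,
    make_fixture,
    rasterize_png,
    render_html,
    render_svg,
)

fx = make_fixture(ToySpec(seed=5, n_sequences=4, ungapped_length=60, gap_rate=0.1))
aln = fx.alignment
aset = load_annotations(fx.json_text, aln)

plan = RenderPlan(scheme=get_scheme("zappo"), window=(1, 40))
html = render_html(aln, aset, plan)
svg = render_svg(aln, aset, plan)
png = rasterize_png(svg, dpi=96)

out = Path("scratch")
out.mkdir(exist_ok=True)
(out / "example.html").write_text(html)
(out / "example.svg").write_text(svg)
(out / "example.png").write_bytes(png)

print(f"window 1-40 of a {len(aln)}x{aln.n_columns} alignment")
print(f"wrote {out}/example.html ({len(html)} bytes), .svg ({len(svg)}), .png ({len(png)})")
print("hover any circled cell in the HTML to see its variant pop-up")
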