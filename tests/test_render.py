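"""Rendering contracts: cell counts, annotated-cell correspondence,
windowing, determinism, SVG geometry and PNG rasterization."""

import json
import re
import xml.etree.ElementTree as ET

import pytest

from alnmark import (
    AnnotationSet,
    RenderError,
    RenderPlan,
    get_scheme,
    index_by_column,
    load_annotations,
    make_fixture,
    paginate,
    rasterize_png,
    render_html,
    render_svg,
    ToySpec,
)
from alnmark.raster import png_size

from conftest import make_alignment

SCHEME = get_scheme("clustal")


def plan(**kwargs) -> RenderPlan:
    kwargs.setdefault("scheme", SCHEME)
    return RenderPlan(**kwargs)


def html_cells(text: str) -> list[str]:
    """Sequence-grid cells only (annotated 'an' or plain 'sq')."""
    return re.findall(r'class="cell (an|sq)"', text)


def svg_cells(text: str) -> list[str]:
    root = ET.fromstring(text)
    ns = "{http://www.w3.org/2000/svg}"
    out = []
    for elem in root.iter():
        cls = elem.get("class", "")
        if cls in ("cell an", "cell sq"):
            out.append(cls.split()[1])
    return out


@pytest.fixture
def fixture():
    fx = make_fixture(ToySpec(seed=5, n_sequences=4, ungapped_length=40, gap_rate=0.1))
    aln = fx.alignment
    aset = load_annotations(fx.json_text, aln)
    return aln, aset


class TestPaginate:
    def test_partition(self):
        aln = make_alignment(["A" * 10])
        assert paginate(aln, 4) == [(1, 4), (5, 8), (9, 10)]

    def test_chunk_at_least_width_is_single_window(self):
        aln = make_alignment(["A" * 10])
        assert paginate(aln, 10) == [(1, 10)]
        assert paginate(aln, 99) == [(1, 10)]

    def test_chunk_one(self):
        aln = make_alignment(["ACG"])
        assert paginate(aln, 1) == [(1, 1), (2, 2), (3, 3)]

    def test_chunk_zero_rejected(self):
        aln = make_alignment(["ACG"])
        with pytest.raises(ValueError):
            paginate(aln, 0)

    def test_windows_cover_every_column_once(self):
        aln = make_alignment(["A" * 37])
        windows = paginate(aln, 5)
        covered = [c for a, b in windows for c in range(a, b + 1)]
        assert covered == list(range(1, 38))


class TestCellCounts:
    def test_html_cells_equal_rows_times_window(self, fixture):
        aln, aset = fixture
        text = render_html(aln, aset, plan(window=(3, 22)))
        assert len(html_cells(text)) == len(aln) * 20

    def test_svg_cells_equal_rows_times_window(self, fixture):
        aln, aset = fixture
        text = render_svg(aln, aset, plan(window=(3, 22)))
        assert len(svg_cells(text)) == len(aln) * 20

    def test_excluded_rows_are_dropped(self, fixture):
        aln, aset = fixture
        text = render_html(aln, aset, plan(window=(1, 10), excluded=frozenset({1})))
        assert len(html_cells(text)) == (len(aln) - 1) * 10

    def test_annotated_cells_match_column_index_in_window(self, fixture):
        aln, aset = fixture
        window = (1, aln.n_columns)
        index = index_by_column(aset, aln)
        expected = sum(
            1
            for col, bucket in index.buckets.items()
            if window[0] <= col <= window[1]
            for _ in {ann.seq_index for _, ann in bucket}
        )
        html = render_html(aln, aset, plan(window=window))
        svg = render_svg(aln, aset, plan(window=window))
        assert html_cells(html).count("an") == expected
        assert svg_cells(svg).count("an") == expected

    def test_annotations_outside_window_not_circled(self, fixture):
        aln, aset = fixture
        index = index_by_column(aset, aln)
        last_annotated = max(index.buckets)
        window = (1, last_annotated - 1)
        html = render_html(aln, aset, plan(window=window))
        in_window = sum(
            len({ann.seq_index for _, ann in bucket})
            for col, bucket in index.buckets.items()
            if col <= window[1]
        )
        assert html_cells(html).count("an") == in_window


class TestHtmlContent:
    def test_single_variant_popup_contains_note(self):
        aln = make_alignment(["MKCV", "MKCV"])
        aset = load_annotations(
            json.dumps(
                {
                    "variants": [
                        {
                            "sequence": 0,
                            "position": 3,
                            "token": "p.C3Y",
                            "note": "pathogenic substitution",
                        }
                    ]
                }
            ),
            aln,
        )
        text = render_html(aln, aset, plan())
        assert html_cells(text).count("an") == 1
        assert text.count('class="popup"') == 1
        assert "pathogenic substitution" in text

    def test_consensus_row_toggle(self, fixture):
        aln, aset = fixture
        with_row = render_html(aln, aset, plan(window=(1, 10)))
        without = render_html(aln, aset, plan(window=(1, 10), show_consensus=False))
        assert "Consensus" in with_row
        assert "Consensus" not in without

    def test_row_labels_link_to_database(self):
        aln_text = ">sp|P12345|X Homo sapiens\nMKCV\n>plainseq\nMKCV\n"
        from alnmark import read_fasta

        aln = read_fasta(aln_text)
        text = render_html(aln, None, plan())
        assert "https://www.uniprot.org/uniprotkb/P12345" in text

    def test_modification_marks_notification_asterisk(self):
        aln = make_alignment(["MKCV"])
        aset = load_annotations(
            json.dumps(
                {"modifications": [{"sequence": 0, "position": 2, "type": "ubiquitination"}]}
            ),
            aln,
        )
        text = render_html(aln, aset, plan())
        notif_row = text.split('class="row notifrow"')[1].split("</div>")[0]
        assert notif_row.count(">*<") == 1

    def test_region_track_labels_and_links(self):
        aln = make_alignment(["MKCVMKCV"])
        aset = load_annotations(
            json.dumps(
                {
                    "regions": [
                        {
                            "sequence": 0,
                            "start": 2,
                            "end": 6,
                            "label": "SH3 domain",
                            "url": "https://example.org/sh3",
                        }
                    ]
                }
            ),
            aln,
        )
        text = render_html(aln, aset, plan())
        assert "SH3 domain" in text
        assert "https://example.org/sh3" in text

    def test_sanitize_strips_tags_from_notes(self):
        aln = make_alignment(["MKCV"])
        aset = load_annotations(
            json.dumps(
                {
                    "variants": [
                        {
                            "sequence": 0,
                            "position": 1,
                            "note": '<img src="x"/>plain text',
                        }
                    ]
                }
            ),
            aln,
        )
        raw = render_html(aln, aset, plan())
        clean = render_html(aln, aset, plan(sanitize=True))
        assert "<img" in raw
        assert "<img" not in clean
        assert "plain text" in clean


class TestSvgGeometry:
    def test_width_arithmetic_contract(self):
        aln = make_alignment(["MKCVMKCVMK", "MKCVMKCVMK"])
        text = render_svg(aln, None, plan(window=(1, 10), cell_px=16, label_gutter=120))
        root = ET.fromstring(text)
        assert root.get("width") == "280"  # 120 + 10*16

    def test_height_tracks_plus_rows(self):
        aln = make_alignment(["MKCV", "MKCV"])
        text = render_svg(aln, None, plan(show_consensus=False))
        root = ET.fromstring(text)
        # no regions: tracks = notification row only (14px), 2 rows of 18px
        assert root.get("height") == str(14 + 2 * 18)

    def test_error_paths(self, fixture):
        aln, aset = fixture
        with pytest.raises(RenderError, match="empty window"):
            render_svg(aln, aset, plan(window=(5, 4)))
        with pytest.raises(RenderError, match="nothing to render"):
            render_svg(aln, aset, plan(excluded=frozenset(range(len(aln)))))
        with pytest.raises(RenderError, match="outside"):
            render_html(aln, aset, plan(window=(1, aln.n_columns + 1)))


class TestDeterminism:
    def test_repeated_renders_are_byte_identical(self, fixture):
        aln, aset = fixture
        p = plan(window=(1, 30))
        assert render_html(aln, aset, p) == render_html(aln, aset, p)
        assert render_svg(aln, aset, p) == render_svg(aln, aset, p)


class TestRasterize:
    def test_unit_scale_dimensions(self):
        aln = make_alignment(["MKCVMKCVMK", "MKCVMKCVMK"])
        svg = render_svg(aln, None, plan(window=(1, 10), cell_px=16))
        root = ET.fromstring(svg)
        w, h = int(root.get("width")), int(root.get("height"))
        assert png_size(svg, 96) == (w, h)
        png = rasterize_png(svg, dpi=96)
        assert png[:8] == b"\x89PNG\r\n\x1a\n"

    def test_double_dpi_doubles_pixels(self):
        aln = make_alignment(["MKCV"])
        svg = render_svg(aln, None, plan())
        w96, h96 = png_size(svg, 96)
        assert png_size(svg, 192) == (2 * w96, 2 * h96)

    def test_dpi_zero_rejected(self):
        aln = make_alignment(["MKCV"])
        svg = render_svg(aln, None, plan())
        with pytest.raises(ValueError):
            rasterize_png(svg, dpi=0)

    def test_pixel_dimensions_match_header(self):
        from PIL import Image
        import io as _io

        aln = make_alignment(["MKCVMKCV"])
        svg = render_svg(aln, None, plan())
        img = Image.open(_io.BytesIO(rasterize_png(svg, dpi=120)))
        assert img.size == png_size(svg, 120)
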