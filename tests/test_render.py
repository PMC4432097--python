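import json

import pytest
from lxml import etree

from specplot import (
    AnnotationSchema,
    ChartOptions,
    DataSeries,
    DataSet,
    LayoutError,
    Point,
    StyleConfig,
    make_chart,
    parse_annotations,
    render_chart,
)
from specplot.fixtures import make_molfiles

SVG_NS = "http://www.w3.org/2000/svg"


def parse_svg(svg_text: str):
    root = etree.fromstring(svg_text.encode("utf-8"))
    assert etree.QName(root).localname == "svg"
    return root


def series_groups(root):
    return root.findall(f".//{{{SVG_NS}}}g[@class='series']")


class TestRenderChart:
    def test_empty_dataset_yields_frame_and_axes_only(self):
        svg = render_chart(make_chart("ms"), ChartOptions(), DataSet())
        root = parse_svg(svg)
        assert root.get("width") == "800" and root.get("height") == "400"
        assert series_groups(root) == []
        assert root.findall(f".//{{{SVG_NS}}}g[@class='axes']")

    def test_impulse_count_equals_peak_count(self):
        pts = (Point(100.0, 5.0), Point(200.0, 3.0), Point(300.0, 9.0))
        ds = DataSet().add(DataSeries(pts, name="s"))
        root = parse_svg(render_chart(make_chart("ms"), ChartOptions(), ds))
        (g,) = series_groups(root)
        assert len(g.findall(f"{{{SVG_NS}}}line")) == 3

    def test_legend_entries_match_series_in_add_order(self):
        ds = DataSet()
        for i in range(3):
            ds = ds.add(DataSeries((Point(0, 0), Point(10, float(i + 1))),))
        root = parse_svg(render_chart(make_chart("nmr1d"), ChartOptions(legend=True), ds))
        entries = root.findall(f".//{{{SVG_NS}}}g[@class='legend-entry']")
        assert [e.find(f"{{{SVG_NS}}}text").text for e in entries] == [
            "series-1", "series-2", "series-3",
        ]
        assert len(series_groups(root)) == 3

    def test_byte_identical_across_runs(self, ms_dataset):
        opts = ChartOptions(legend=True, signal_labels=True, title="t")
        a = render_chart(make_chart("ms"), opts, ms_dataset)
        b = render_chart(make_chart("ms"), opts, ms_dataset)
        assert a.encode() == b.encode()

    @pytest.mark.parametrize("tid", ["ms", "nmr1d", "nmr2d", "ir", "timeseries"])
    def test_series_geometry_clipped_to_plot_rect(self, tid, ms_dataset, nmr_trace_60k):
        if tid == "nmr2d":
            pts = tuple(Point(float(i % 10), float(i * 3 % 160)) for i in range(40))
            ds = DataSet().add(DataSeries(sorted(pts, key=lambda p: p.x), kind="points2d"))
        elif tid == "ms":
            ds = ms_dataset
        else:
            ds = DataSet().add(nmr_trace_60k)
        opts = ChartOptions(y_window=(0.0, 5.0)) if tid != "nmr1d" else ChartOptions()
        root = parse_svg(render_chart(make_chart(tid), opts, ds))
        mt, mr, mb, ml = opts.margins
        x0, x1 = ml - 0.01, opts.width_px - mr + 0.01
        y0, y1 = mt - 0.01, opts.height_px - mb + 0.01
        coords = []
        for g in series_groups(root):
            for ln in g.findall(f"{{{SVG_NS}}}line"):
                coords += [(float(ln.get("x1")), float(ln.get("y1"))),
                           (float(ln.get("x2")), float(ln.get("y2")))]
            for c in g.findall(f"{{{SVG_NS}}}circle"):
                coords.append((float(c.get("cx")), float(c.get("cy"))))
            for pl in g.findall(f"{{{SVG_NS}}}polyline"):
                for pair in pl.get("points").split():
                    x, y = pair.split(",")
                    coords.append((float(x), float(y)))
        assert coords
        assert all(x0 <= x <= x1 and y0 <= y <= y1 for x, y in coords)

    def test_highlight_dims_other_series(self):
        ds = DataSet().add(DataSeries((Point(0, 1), Point(1, 2)), name="a")).add(
            DataSeries((Point(0, 2), Point(1, 3)), name="b")
        )
        root = parse_svg(
            render_chart(make_chart("timeseries"), ChartOptions(highlight="b"), ds)
        )
        by_id = {g.get("id"): g for g in series_groups(root)}
        assert by_id["series--a"].get("opacity") == "0.30"
        assert by_id["series--b"].get("opacity") is None

    def test_zero_area_plot_region_rejected(self, ms_dataset):
        opts = ChartOptions(width_px=50, height_px=50, margins=(40, 30, 50, 60))
        with pytest.raises(LayoutError):
            render_chart(make_chart("ms"), opts, ms_dataset)

    def test_custom_labels_override_type_defaults(self, ms_dataset):
        svg = render_chart(
            make_chart("ms"), ChartOptions(x_label="custom-x", y_label="custom-y"), ms_dataset
        )
        assert "custom-x" in svg and "custom-y" in svg
        default = render_chart(make_chart("ms"), ChartOptions(), ms_dataset)
        assert "m/z" in default and "intensity" in default


class TestRenderAnnotations:
    SCHEMA = AnnotationSchema(
        (("fragment", "text"), ("m/z", "tooltip"), ("structure", "structure-url"))
    )

    def _render(self, lookups, xw=None):
        pts = tuple(Point(float(x), 10.0) for x in (50, 113, 200, 300))
        ds = DataSet().add(DataSeries(pts, name="s"))
        rows = [["frag", x, "uracil", f"{x:.2f}", "uracil.mol"] for x in lookups]
        aset = parse_annotations(json.dumps(rows), self.SCHEMA)
        corpus = make_molfiles()
        svg = render_chart(
            make_chart("ms"),
            ChartOptions(x_window=xw),
            ds,
            ann=aset,
            ann_group="frag",
            ann_schema=self.SCHEMA,
            resolver=lambda url: corpus[url[:-4]],
        )
        return parse_svg(svg)

    def test_callout_lists_key_value_lines(self):
        root = self._render([113.0])
        texts = [t.text for t in root.findall(f".//{{{SVG_NS}}}g[@class='callout']/{{{SVG_NS}}}text")]
        assert "fragment: uracil" in texts
        assert "m/z: 113.00" in texts

    def test_structure_payload_embeds_molecule_group(self):
        root = self._render([113.0])
        mols = root.findall(f".//{{{SVG_NS}}}g[@class='molecule']")
        assert len(mols) == 1
        assert len(mols[0].findall(f"{{{SVG_NS}}}line")) == 11  # sum of uracil bond orders

    def test_anchor_outside_view_window_skipped(self):
        root = self._render([113.0, 300.0], xw=(100.0, 250.0))
        anns = root.findall(f".//{{{SVG_NS}}}g[@class='annotation']")
        assert len(anns) == 1
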