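import json

import numpy as np
import pytest

from _oracles import nearest_x_scan

from specplot import (
    AnnotationSchema,
    DataSeries,
    GroupNotFoundError,
    Point,
    SchemaError,
    anchor,
    build_tooltip,
    parse_annotations,
    serialize_annotations,
)
from specplot.annotations import local_file_resolver
from specplot.fixtures import make_molfiles

SCHEMA = AnnotationSchema((("name", "text"),))
RICH = AnnotationSchema((("fragment", "text"), ("m/z", "tooltip"), ("structure", "structure-url")))


class TestParse:
    def test_single_row_single_group(self):
        aset = parse_annotations('[["frag", 113.0, "uracil"]]', SCHEMA)
        assert aset.groups == ("frag",)
        (a,) = aset.group("frag")
        assert a.x_lookup == 113.0 and a.payload == (("name", "uracil"),)

    def test_groups_partition_in_file_order(self):
        aset = parse_annotations('[["a", 1, "p"], ["b", 2, "q"], ["a", 3, "r"]]', SCHEMA)
        assert aset.groups == ("a", "b")
        assert len(aset.group("a")) == 2 and len(aset.group("b")) == 1
        assert len(aset) == 3  # partition conserves row count

    def test_row_arity_mismatch_names_row(self):
        with pytest.raises(SchemaError, match="row 1"):
            parse_annotations('[["a", 1, "p"], ["b", 2]]', SCHEMA)

    def test_non_numeric_lookup_rejected(self):
        with pytest.raises(ValueError, match="x_lookup"):
            parse_annotations('[["a", "not-a-number", "p"]]', SCHEMA)

    def test_empty_structure_url_rejected(self):
        schema = AnnotationSchema((("structure", "structure-url"),))
        with pytest.raises(SchemaError, match="structure"):
            parse_annotations('[["a", 1, ""]]', schema)

    def test_parse_serialize_parse_identity(self):
        text = '[["a",1.5,"p"],["b",2.25,"q"],["a",3.75,"r"]]'
        aset = parse_annotations(text, SCHEMA)
        again = parse_annotations(serialize_annotations(aset), SCHEMA)
        assert again == aset


class TestAnchor:
    SERIES = DataSeries(tuple(Point(float(x), 1.0) for x in (0, 10, 20, 30, 100)), name="s")

    def _aset(self, lookups):
        rows = [["g", x, "p"] for x in lookups]
        return parse_annotations(json.dumps(rows), SCHEMA)

    def test_exact_hit_distance_zero(self):
        anchored, unmatched = anchor(self._aset([20.0]), "g", self.SERIES)
        assert not unmatched
        assert anchored[0].point.x == 20.0 and anchored[0].distance == 0.0

    def test_between_points_binds_nearer_left(self):
        anchored, _ = anchor(self._aset([14.0]), "g", self.SERIES, rel_tolerance=0.1)
        assert anchored[0].point.x == 10.0

    def test_tie_breaks_toward_smaller_x(self):
        anchored, _ = anchor(self._aset([15.0]), "g", self.SERIES, rel_tolerance=0.1)
        assert anchored[0].point.x == 10.0

    def test_far_outside_extent_reported_unmatched(self):
        anchored, unmatched = anchor(self._aset([500.0]), "g", self.SERIES)
        assert not anchored and len(unmatched) == 1

    def test_unknown_group_not_found(self):
        with pytest.raises(GroupNotFoundError):
            anchor(self._aset([1.0]), "other", self.SERIES)

    def test_matches_bruteforce_nearest_scan(self):
        rng = np.random.default_rng(5)
        xs = np.sort(rng.uniform(0, 1000, size=300))
        series = DataSeries(tuple(Point(float(x), 0.0) for x in xs), name="s")
        lookups = rng.uniform(-50, 1050, size=200)
        aset = self._aset([float(x) for x in lookups])
        anchored, unmatched = anchor(aset, "g", series, rel_tolerance=0.005)
        got = {a.annotation.x_lookup: a.point for a in anchored}
        tol = 0.005 * (xs[-1] - xs[0])
        for x in lookups:
            d, p = nearest_x_scan(series.points, float(x))
            if d <= tol:
                assert got[float(x)] == p
            else:
                assert float(x) not in got
        assert len(anchored) + len(unmatched) == 200


class TestTooltip:
    def test_key_value_line_format(self):
        aset = parse_annotations('[["g", 113.0, "uracil", "113.00", "uracil.mol"]]', RICH)
        (a,) = aset.group("g")
        corpus = make_molfiles()
        content = build_tooltip(a, RICH, resolver=lambda url: corpus[url[:-4]])
        assert content.lines[0] == "fragment: uracil"
        assert content.lines[1] == "m/z: 113.00"
        assert len(content.molecules) == 1
        assert len(content.molecules[0][1].atoms) == 8

    def test_resolver_miss_degrades_to_placeholder(self):
        aset = parse_annotations('[["g", 113.0, "uracil", "113.00", "missing.mol"]]', RICH)
        (a,) = aset.group("g")

        def failing(url):
            raise FileNotFoundError(url)

        content = build_tooltip(a, RICH, resolver=failing)
        assert content.lines[0] == "fragment: uracil"  # other columns intact
        assert "unavailable" in content.lines[2]
        assert content.molecules == ()

    def test_local_file_resolver_reads_molfiles(self, tmp_path, molfile_corpus):
        (tmp_path / "eth.mol").write_text(molfile_corpus["ethanol"])
        resolver = local_file_resolver(str(tmp_path))
        assert "V2000" in resolver("eth.mol")

    def test_duplicate_schema_columns_rejected(self):
        with pytest.raises(SchemaError):
            AnnotationSchema((("a", "text"), ("a", "tooltip")))
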