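import json

import numpy as np
import pytest

import microvasc as mv
from microvasc.network import SchemaError, ValidationError, build_incidence, merged_segment_count


@pytest.fixture
def y_tree():
    return mv.make_fixture("y_tree")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["json", "csv_pair"])
    def test_fixture_round_trip_identity(self, tmp_path, fmt, y_tree):
        path = tmp_path / ("net.json" if fmt == "json" else "net")
        mv.save_network(y_tree, path, fmt)
        back = mv.load_network(path, fmt)
        assert back.n_segments == 3 and back.n_nodes == 4
        assert len(back.inlet_idx) == 1 and len(back.outlet_idx) == 2
        np.testing.assert_array_equal(back.node_ids, y_tree.node_ids)
        np.testing.assert_array_equal(back.tails, y_tree.tails)
        np.testing.assert_array_equal(back.compartments, y_tree.compartments)
        np.testing.assert_allclose(back.positions, y_tree.positions, rtol=1e-12)
        np.testing.assert_allclose(back.diameters, y_tree.diameters, rtol=1e-12)
        np.testing.assert_allclose(back.lengths, y_tree.lengths, rtol=1e-12)

    def test_synthetic_sample_round_trip(self, tmp_path, small_sample):
        path = tmp_path / "sample.json"
        mv.save_network(small_sample, path, "json")
        back = mv.load_network(path, "json")
        assert back.n_segments == small_sample.n_segments
        np.testing.assert_allclose(back.lengths, small_sample.lengths, rtol=1e-12)
        np.testing.assert_allclose(back.positions, small_sample.positions, rtol=1e-12)
        # control points (Bezier splines) survive the trip
        k = next(i for i, cp in enumerate(back.control_points) if cp is not None)
        np.testing.assert_allclose(back.control_points[k], small_sample.control_points[k], rtol=1e-12)

    def test_csv_pair_writes_tables(self, tmp_path):
        net = mv.make_fixture("single_bifurcation")
        mv.save_network(net, tmp_path / "bif", "csv_pair")
        nodes = (tmp_path / "bif.nodes.csv").read_text().strip().splitlines()
        segs = (tmp_path / "bif.segments.csv").read_text().strip().splitlines()
        assert len(nodes) == 1 + 4 and len(segs) == 1 + 3


class TestSchemaValidation:
    def test_unknown_node_reference_is_schema_error(self, tmp_path, y_tree):
        path = tmp_path / "net.json"
        mv.save_network(y_tree, path, "json")
        doc = json.loads(path.read_text())
        doc["segments"][0]["tail"] = 999
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="999"):
            mv.load_network(path, "json")

    def test_nan_diameter_refused_on_write(self, tmp_path, y_tree):
        y_tree.diameters[1] = np.nan
        with pytest.raises(ValidationError):
            mv.save_network(y_tree, tmp_path / "bad.json", "json")

    def test_disconnected_network_rejected(self, tmp_path):
        net = mv.make_fixture("y_tree")
        other = mv.make_fixture("single_segment")
        merged = mv.VascularNetwork(
            node_ids=np.concatenate([net.node_ids, other.node_ids + 100]),
            positions=np.vstack([net.positions, other.positions + 5000]),
            roles=np.concatenate([net.roles, other.roles]),
            seg_ids=np.concatenate([net.seg_ids, other.seg_ids + 100]),
            tails=np.concatenate([net.tails, other.tails + 100]),
            heads=np.concatenate([net.heads, other.heads + 100]),
            diameters=np.concatenate([net.diameters, other.diameters]),
            lengths=np.concatenate([net.lengths, other.lengths]),
        )
        with pytest.raises(ValidationError, match="disconnected"):
            merged.check()


class TestIncidence:
    def test_single_segment_rows(self):
        net = mv.make_fixture("single_segment")
        inc = build_incidence(net)
        assert inc.C1.shape == (1, 2)
        np.testing.assert_array_equal(inc.C1.toarray(), [[1.0, -1.0]])
        assert inc.C2.shape == (0, 1)  # no interior nodes

    def test_y_tree_conservation_row(self, y_tree):
        inc = build_incidence(y_tree)
        assert inc.C2.shape == (1, 3)
        row = inc.C2.toarray()[0]
        assert sorted(row.tolist()) == [-1.0, -1.0, 1.0]

    def test_c1_rows_two_nonzeros_summing_to_zero(self, small_sample):
        C1 = build_incidence(small_sample).C1
        counts = np.diff(C1.indptr)
        assert np.all(counts == 2)
        np.testing.assert_allclose(np.asarray(C1.sum(axis=1)).ravel(), 0.0)

    def test_solver_flow_satisfies_c2(self, solved_small):
        net, field = solved_small
        inc = build_incidence(net)
        residual = inc.C2 @ field.Q
        assert np.max(np.abs(residual)) <= 1e-10 * np.max(np.abs(field.Q))


class TestDiagnostics:
    def test_honeycomb_has_no_multifurcations(self, honeycomb):
        assert mv.validate(honeycomb)["n_multifurcations"] == 0

    def test_four_way_junction_counted(self):
        nodes = [[0, 0, 0], [100, 0, -50], [200, 0, -100], [200, 100, -100], [200, -100, -100]]
        roles = ["arterial_inlet", "interior", "venous_outlet", "venous_outlet", "venous_outlet"]
        net = mv.VascularNetwork(
            node_ids=range(5), positions=np.array(nodes, float), roles=roles,
            seg_ids=range(4), tails=[0, 1, 1, 1], heads=[1, 2, 3, 4],
            diameters=[10, 6, 6, 6],
        )
        diag = mv.validate(net)
        assert diag["n_multifurcations"] == 1
        assert diag["n_segments_at_multifurcations"] == 4

    def test_tortuosity_at_least_one(self, small_sample):
        assert np.all(small_sample.tortuosity() >= 1.0 - 1e-9)

    def test_depths_never_negative(self, small_sample):
        assert np.all(small_sample.depths() >= -1e-9)


class TestSplineCounting:
    def test_subdividing_a_segment_preserves_count(self):
        net = mv.make_fixture("y_tree")
        base = merged_segment_count(net)
        # replace segment 0 (tail -> head) by tail -> waypoint -> head
        mid = 0.5 * (net.positions[net.tail_idx[0]] + net.positions[net.head_idx[0]])
        split = mv.VascularNetwork(
            node_ids=np.append(net.node_ids, 50),
            positions=np.vstack([net.positions, mid]),
            roles=np.append(net.roles, "interior"),
            seg_ids=np.append(net.seg_ids, 50),
            tails=np.array([net.tails[0], *net.tails[1:], 50]),
            heads=np.array([50, *net.heads[1:], net.heads[0]]),
            diameters=np.append(net.diameters, net.diameters[0]),
        )
        assert merged_segment_count(split) == base
        assert split.n_segments == net.n_segments + 1

    def test_sample_count_close_to_raw(self, small_sample):
        # generator produces junction-bounded splines except at the pial
        # entry points of penetrating vessels
        merged = merged_segment_count(small_sample)
        assert merged <= small_sample.n_segments
        assert merged >= 0.98 * small_sample.n_segments


class TestVtkExport:
    def test_polylines_and_cell_arrays(self, tmp_path, solved_small):
        net, field = solved_small
        out = tmp_path / "net.vtp"
        mv.export_vtk(net, out, field)
        from lxml import etree

        root = etree.parse(str(out)).getroot()
        piece = root.find(".//Piece")
        assert int(piece.get("NumberOfLines")) == net.n_segments
        names = {a.get("Name") for a in piece.findall(".//CellData/DataArray")}
        assert {"diameter_um", "compartment", "pressure_mmHg", "flow_nl_s", "hematocrit"} <= names

    def test_without_field_only_geometry_arrays(self, tmp_path):
        net = mv.make_fixture("y_tree")
        out = tmp_path / "y.vtp"
        mv.export_vtk(net, out)
        text = out.read_text()
        assert "diameter_um" in text and "pressure_mmHg" not in text

    def test_empty_network_refused(self, tmp_path):
        net = mv.make_fixture("y_tree")
        net.seg_ids = net.seg_ids[:0]
        net.tails = net.tails[:0]
        net.heads = net.heads[:0]
        net.tail_idx = net.tail_idx[:0]
        net.head_idx = net.head_idx[:0]
        net.diameters = net.diameters[:0]
        net.lengths = net.lengths[:0]
        net.compartments = net.compartments[:0]
        net.control_points = []
        with pytest.raises(ValueError):
            mv.export_vtk(net, tmp_path / "e.vtp")
        assert not (tmp_path / "e.vtp").exists()
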