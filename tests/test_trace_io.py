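"""Dataset model, SWC round trips, and adjacent-section superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pallidotrace import (
    Dataset,
    FiberTrace,
    Point3,
    SectionGeometry,
    SomaRecord,
    generate_dataset,
    read_dataset,
    superimpose_adjacent,
    to_atlas_point,
    write_dataset,
)
from pallidotrace.synthgen import small_config
from pallidotrace.trace_io import FormatError, ValidationError, dataset_digest

from conftest import SQUARE, one_trace_dataset, square_section


class TestPoint3:
    @pytest.mark.parametrize(
        "rc,dv,ml",
        [
            (np.nan, 0, 1), (0, np.inf, 1), (11.0, 0, 1),
            (0, -10.5, 1), (0, 0, -0.1), (0, 0, 10.5),
        ],
    )
    def test_rejects_out_of_bounds_or_nonfinite(self, rc, dv, ml):
        with pytest.raises(ValidationError):
            Point3(rc, dv, ml)

    def test_accepts_typical_atlas_coordinates(self):
        p = Point3(-0.45, -3.3, 1.9)
        assert p.as_array().tolist() == [-0.45, -3.3, 1.9]


class TestFiberTraceInvariants:
    def test_needs_two_distinct_points(self):
        with pytest.raises(ValidationError):
            FiberTrace("t", "GFP", 0, np.array([[0.0, 0.0]]))
        with pytest.raises(ValidationError):
            FiberTrace("t", "GFP", 0, np.array([[0.0, 0.0], [0.0, 0.0]]))

    def test_nonvaricose_cannot_carry_boutons(self):
        with pytest.raises(ValidationError):
            FiberTrace(
                "t", "GFP", 0, np.array([[0.0, 0.0], [0.1, 0.0]]),
                varicose=False, varicosity_positions=np.array([0.05]),
            )

    def test_varicosities_must_stay_on_polyline(self):
        with pytest.raises(ValidationError):
            FiberTrace(
                "t", "GFP", 0, np.array([[0.0, 0.0], [0.1, 0.0]]),
                varicosity_positions=np.array([0.2]),
            )

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValidationError):
            FiberTrace("t", "YFP", 0, np.array([[0.0, 0.0], [0.1, 0.0]]))


class TestDatasetValidation:
    def test_trace_must_reference_known_section(self):
        with pytest.raises(ValidationError, match="t0"):
            Dataset(
                mouse_id="m",
                sections=[square_section(0)],
                traces=[
                    FiberTrace("t0", "GFP", 3, np.array([[0.0, -3.0], [0.1, -3.0]]))
                ],
                somata=[],
            )

    def test_ml_centers_must_increase(self):
        with pytest.raises(ValidationError):
            Dataset(
                mouse_id="m",
                sections=[square_section(0, ml=2.0), square_section(1, ml=1.9)],
                traces=[],
                somata=[],
            )


class TestRoundTrip:
    def test_two_vertex_trace_reads_back(self, tmp_path):
        ds = one_trace_dataset([[0.0, -3.0], [0.02, -3.0]], varic=[0.013])
        assert ds.total_length() == pytest.approx(0.02)
        write_dataset(ds, tmp_path / "d")
        back = read_dataset(tmp_path / "d")
        assert len(back.traces) == 1
        assert back.total_length() == pytest.approx(0.02, abs=1e-12)
        assert back.traces[0].varicosity_positions == pytest.approx(
            [0.013], abs=1e-12
        )
        assert back.mouse_id == ds.mouse_id

    def test_empty_trace_dataset_writes_no_swc(self, tmp_path):
        ds = one_trace_dataset([[0.0, -3.0], [0.02, -3.0]])
        ds.traces = []
        write_dataset(ds, tmp_path / "d")
        assert not (tmp_path / "d" / "traces").exists()
        back = read_dataset(tmp_path / "d")
        assert back.traces == []
        assert len(back.somata) == 2

    def test_one_trace_dataset_writes_one_swc(self, tmp_path):
        ds = one_trace_dataset([[0.0, -3.0], [0.02, -3.0]])
        write_dataset(ds, tmp_path / "d")
        assert len(list((tmp_path / "d" / "traces").glob("*.swc"))) == 1

    def test_synthetic_dataset_roundtrip_is_lossless(self, small_mouse, tmp_path):
        write_dataset(small_mouse, tmp_path / "d")
        back = read_dataset(tmp_path / "d")
        assert len(back.traces) == len(small_mouse.traces)
        assert back.total_length() == pytest.approx(
            small_mouse.total_length(), abs=1e-9
        )
        orig = {t.trace_id: t for t in small_mouse.traces}
        for t in back.traces:
            o = orig[t.trace_id]
            assert t.channel == o.channel and t.section_index == o.section_index
            assert t.varicose == o.varicose
            np.testing.assert_allclose(t.points, o.points, atol=1e-9)
            np.testing.assert_allclose(
                t.varicosity_positions, o.varicosity_positions, atol=1e-9
            )

    def test_write_is_deterministic(self, tmp_path):
        cfg = small_config(n_fibers={"GFP": 5, "RFP": 5})
        for sub in ("a", "b"):
            write_dataset(generate_dataset(cfg, seed=3), tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(-1.9, 1.9, allow_nan=False),
                st.floats(-5.9, -0.1, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
            unique=True,
        ),
        frac=st.lists(st.floats(0.0, 1.0), max_size=3),
    )
    def test_roundtrip_property(self, tmp_path_factory, pts, frac):
        trace = FiberTrace(
            "t0", "RFP", 0, np.asarray(pts, dtype=float),
            varicosity_positions=np.array([]),
        )
        length = trace.length()
        vpos = np.sort(np.asarray(frac) * length)
        ds = one_trace_dataset(pts, channel="RFP", varic=vpos)
        root = tmp_path_factory.mktemp("rt")
        write_dataset(ds, root)
        back = read_dataset(root)
        np.testing.assert_allclose(back.traces[0].points, trace.points, atol=1e-9)
        np.testing.assert_allclose(
            back.traces[0].varicosity_positions, vpos, atol=1e-9
        )


class TestReadErrors:
    def test_missing_manifest_names_file(self, tmp_path):
        with pytest.raises(FormatError, match="sections.csv"):
            read_dataset(tmp_path)

    def test_nonfinite_coordinate_reports_line(self, tmp_path):
        ds = one_trace_dataset([[0.0, -3.0], [0.02, -3.0]])
        write_dataset(ds, tmp_path / "d")
        swc = next((tmp_path / "d" / "traces").glob("*.swc"))
        text = swc.read_text().replace("0.02 ", "nan ", 1)
        swc.write_text(text)
        with pytest.raises(ValidationError, match=r":\d+"):
            read_dataset(tmp_path / "d")


class TestSuperimposeAdjacent:
    def make(self, n_sections=2):
        sections = [square_section(i, ml=1.30 + 0.02 * i) for i in range(n_sections)]
        traces = [
            FiberTrace(
                f"t{i}", "GFP" if i % 2 else "RFP", i % n_sections,
                np.array([[0.0, -3.0], [0.05 + 0.01 * i, -3.0]]),
            )
            for i in range(2 * n_sections)
        ]
        return Dataset(mouse_id="m", sections=sections, traces=traces, somata=[])

    def test_pair_merges_at_midpoint(self):
        ds = self.make(2)
        merged = superimpose_adjacent(ds, [(0, 1)])
        assert len(merged.sections) == 1
        assert merged.sections[0].ml_center == pytest.approx(1.31)

    def test_empty_pairing_is_identity(self):
        ds = self.make(2)
        out = superimpose_adjacent(ds, [])
        assert dataset_digest(out) == dataset_digest(ds)

    def test_twelve_sections_six_pairs_conserve_traces(self):
        ds = self.make(12)
        pairs = [(2 * i, 2 * i + 1) for i in range(6)]
        merged = superimpose_adjacent(ds, pairs)
        assert len(merged.sections) == 6
        assert len(merged.traces) == len(ds.traces)
        assert merged.total_length() == pytest.approx(ds.total_length())
        centers = [s.ml_center for s in sorted(merged.sections, key=lambda s: s.index)]
        assert all(b > a for a, b in zip(centers, centers[1:]))

    @pytest.mark.parametrize("pairing", [[(0, 0)], [(0, 2)]])
    def test_rejects_self_and_nonadjacent_pairs(self, pairing):
        ds = self.make(3)
        with pytest.raises(ValidationError):
            superimpose_adjacent(ds, pairing)


class TestToAtlasPoint:
    def test_lifts_plane_point_with_section_ml(self):
        sec = square_section(0, ml=1.9)
        p = to_atlas_point((-0.4, -3.0), sec)
        assert (p.rc, p.dv, p.ml) == (-0.4, -3.0, 1.9)

    def test_ml_is_only_difference_between_sections(self):
        a = to_atlas_point((-0.4, -3.0), square_section(0, ml=1.5))
        b = to_atlas_point((-0.4, -3.0), square_section(1, ml=2.5))
        assert (a.rc, a.dv) == (b.rc, b.dv) and a.ml != b.ml

    def test_synthetic_vertices_map_to_section_centers(self, small_mouse):
        centers = {s.ml_center for s in small_mouse.sections}
        by_index = {s.index: s for s in small_mouse.sections}
        for t in small_mouse.traces[:20]:
            sec = by_index[t.section_index]
            p = to_atlas_point(t.points[0], sec)
            assert p.ml in centers
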