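import numpy as np
import pytest
from hypothesis import given, strategies as st

from tssensemble import (
    GenomeLayout,
    PointPredictionSet,
    ScoreTrack,
    TrapezoidKernel,
    average_tracks,
    decimate_track,
    normalize_track,
    read_points,
    read_track,
    trapezoid_expand,
    write_track,
)


def _points(layout, recs):
    return PointPredictionSet.from_arrays(
        [r[0] for r in recs], [r[1] for r in recs], score=[r[2] for r in recs]
    )


class TestLayout:
    def test_rejects_duplicates_and_bad_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout([("chr1", 10), ("chr1", 20)])
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_cell_counts_round_up(self):
        lay = GenomeLayout({"c": 11})
        assert lay.n_cells("c", 5) == 3


class TestReadPoints:
    def test_empty_file(self, tmp_path, layout):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_points(p, layout)) == 0

    def test_bed6_line(self, tmp_path, layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1 999 1000 p1 0.8 +\n")
        r = read_points(p, layout).records.iloc[0]
        assert (r.chrom, r.pos, r.strand, r.score) == ("chr1", 999, "+", 0.8)

    def test_duplicates_retained(self, tmp_path, layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1 100 0.3\nchr1 100 0.7\n")
        pts = read_points(p, layout)
        assert len(pts) == 2 and set(pts.records["score"]) == {0.3, 0.7}

    def test_malformed_reports_line_number(self, tmp_path, layout):
        p = tmp_path / "a.bed"
        p.write_text("chr1 10 0.5\nchr1 20 notanumber\n")
        with pytest.raises(ValueError, match=":2"):
            read_points(p, layout)

    def test_unknown_chromosome_named(self, tmp_path, layout):
        p = tmp_path / "a.bed"
        p.write_text("chrZ 10 0.5\n")
        with pytest.raises(ValueError, match="chrZ"):
            read_points(p, layout)


class TestReadWriteTrack:
    def test_bedgraph_fill_and_default_zero(self, tmp_path, layout):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        t = read_track(p, layout)
        assert np.all(t.values["chr1"][:10] == 2.5)
        assert np.all(t.values["chr1"][10:] == 0.0)
        assert np.all(t.values["chr2"] == 0.0)

    @pytest.mark.parametrize(
        "line, msg",
        [
            ("chr1\t5\t3\t1.0\n", "end"),
            ("chr1\t0\t20000\t1.0\n", "beyond"),
            ("chr1\t0\t10\t1.0\nchr1\t5\t15\t2.0\n", "overlap"),
        ],
    )
    def test_bedgraph_errors(self, tmp_path, layout, line, msg):
        p = tmp_path / "t.bedGraph"
        p.write_text(line)
        with pytest.raises(ValueError, match=msg):
            read_track(p, layout)

    @pytest.mark.parametrize("step", [1, 5])
    def test_fixedstep_roundtrip_bit_exact(self, tmp_path, layout, step):
        rng = np.random.default_rng(0)
        t = ScoreTrack.zeros(layout, step=step, name="x")
        for c in layout.names:
            t.values[c][:] = rng.random(len(t.values[c]))
        p = tmp_path / "t.wig"
        write_track(t, p)
        back = read_track(p, layout)
        assert back.step == step
        for c in layout.names:
            assert np.array_equal(back.values[c], t.values[c])

    def test_bedgraph_roundtrip(self, tmp_path, layout):
        t = ScoreTrack.zeros(layout, name="x")
        t.values["chr1"][100:200] = 0.75
        p = tmp_path / "t.bedGraph"
        write_track(t, p, fmt="bedGraph")
        assert read_track(p, layout) == t


class TestTrapezoid:
    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            TrapezoidKernel(1000, 0)
        with pytest.raises(ValueError):
            TrapezoidKernel(200, 1000)

    def test_geometry_default_kernel(self, layout):
        pts = _points(layout, [("chr1", 5000, 1.0)])
        v = trapezoid_expand(pts, TrapezoidKernel(), layout).values["chr1"]
        assert v[5000] == 1.0
        assert v[4900] == 1.0 and v[5100] == 1.0  # plateau edges, full score
        assert v[4700] == pytest.approx(0.5) and v[5300] == pytest.approx(0.5)
        assert v[4500] == 0.0 and v[5500] == 0.0  # window edges

    def test_symmetric_support_window_minus_one(self, layout):
        pts = _points(layout, [("chr1", 5000, 0.7)])
        v = trapezoid_expand(pts, TrapezoidKernel(), layout).values["chr1"]
        assert np.count_nonzero(v) == 999  # strictly inside ±window/2
        d = np.arange(1, 500)
        assert np.allclose(v[5000 - d], v[5000 + d])

    def test_max_equals_max_input_score(self, layout):
        pts = _points(layout, [("chr1", 2000, 0.4), ("chr1", 7000, 0.9)])
        track = trapezoid_expand(pts, TrapezoidKernel(), layout)
        assert track.max() == 0.9
        # disjoint trapezoids: zero in between
        assert track.values["chr1"][4500] == 0.0

    def test_overlapping_points_combine_by_max(self, layout):
        pts = _points(layout, [("chr1", 5000, 1.0), ("chr1", 5050, 0.2)])
        v = trapezoid_expand(pts, TrapezoidKernel(), layout).values["chr1"]
        assert v[5050] == 1.0  # inside the stronger plateau

    def test_edge_truncation_silent(self, layout):
        pts = _points(layout, [("chr1", 10, 1.0)])
        v = trapezoid_expand(pts, TrapezoidKernel(), layout).values["chr1"]
        assert v[10] == 1.0 and len(v) == 10_000

    @given(
        pos=st.integers(2000, 8000),
        window=st.integers(2, 500).map(lambda x: 2 * x),
        frac=st.floats(0.1, 1.0),
    )
    def test_symmetry_property(self, pos, window, frac):
        plateau = max(2, int(window * frac) // 2 * 2)
        lay = GenomeLayout({"c": 10_000})
        pts = PointPredictionSet.from_arrays(["c"], [pos], score=[1.0])
        v = trapezoid_expand(pts, TrapezoidKernel(window, plateau), lay).values["c"]
        d = np.arange(1, window // 2 + 1)
        assert np.allclose(v[pos - d], v[pos + d])


class TestNormalize:
    def test_affine_and_clip(self, layout):
        t = ScoreTrack.zeros(layout)
        t.values["chr1"][:3] = [0.0, 5.0, 12.0]
        t.values["chr1"][3] = 10.0
        out = normalize_track(t, 0, 10)
        assert list(out.values["chr1"][:4]) == [0.0, 0.5, 1.0, 1.0]
        assert out.norm_bounds == (0.0, 10.0)

    def test_all_zero_identity(self, layout):
        t = ScoreTrack.zeros(layout)
        out = normalize_track(t)
        assert all(np.all(out.values[c] == 0) for c in layout.names)

    def test_idempotent_with_unit_bounds(self, layout):
        t = ScoreTrack.zeros(layout)
        t.values["chr1"][:] = np.linspace(0, 1, len(t.values["chr1"]))
        out = normalize_track(t, 0, 1)
        assert out == t

    def test_equal_bounds_error(self, layout):
        with pytest.raises(ValueError):
            normalize_track(ScoreTrack.zeros(layout), 3.0, 3.0)


class TestAverageDecimate:
    def test_average_self_identity(self, layout):
        t = ScoreTrack.zeros(layout)
        t.values["chr1"][:] = 0.3
        assert average_tracks([t, t]) == t

    def test_average_values(self, layout):
        a, b = ScoreTrack.zeros(layout), ScoreTrack.zeros(layout)
        for c in layout.names:
            a.values[c][:] = 0.2
            b.values[c][:] = 0.6
        out = average_tracks([a, b])
        assert all(np.allclose(out.values[c], 0.4) for c in layout.names)

    def test_average_errors(self, layout):
        with pytest.raises(ValueError):
            average_tracks([])
        other = ScoreTrack.zeros(GenomeLayout({"chrX": 100}))
        with pytest.raises(ValueError):
            average_tracks([ScoreTrack.zeros(layout), other])

    def test_decimate_max_pooling(self):
        lay = GenomeLayout({"c": 5})
        t = ScoreTrack(lay, 1, {"c": np.array([0.1, 0.9, 0.2, 0.3, 0.4])})
        out = decimate_track(t, 5)
        assert out.step == 5 and list(out.values["c"]) == [0.9]

    def test_decimate_identity_and_constant(self, layout):
        t = ScoreTrack.zeros(layout)
        t.values["chr1"][:] = 0.5
        assert decimate_track(t, 1) == t
        out = decimate_track(t, 8)
        assert np.all(out.values["chr1"] == 0.5)

    def test_decimate_non_multiple_error(self, layout):
        t = ScoreTrack.zeros(layout, step=2)
        with pytest.raises(ValueError):
            decimate_track(t, 5)
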