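"""FCS round trips, panel contracts, and the intensity transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomet.events import EventMatrix, arcsinh_transform, normalize_to_max
from cytomet.fcs import FCSFormatError, read_fcs, write_fcs
from cytomet.panel import MarkerPanel, PanelEntry


def _make_mini_panel():
    return MarkerPanel([
        PanelEntry("173Yb_PanCK", "PanCK", "173Yb", "phenotypic"),
        PanelEntry("89Y_CD45", "CD45", "89Y", "phenotypic"),
        PanelEntry("152Sm_EpCAM", "EpCAM", "152Sm", "phenotypic"),
        PanelEntry("198Pt_Cisplatin", "Cisplatin", "198Pt", "viability"),
        PanelEntry("191Ir_DNA1", "DNA1", "191Ir", "dna"),
    ])


@pytest.fixture
def mini_panel():
    return _make_mini_panel()


def _random_events(panel, n=50, seed=0):
    rng = np.random.default_rng(seed)
    return EventMatrix(rng.gamma(2.0, 20.0, (n, len(panel))), panel, "raw", "S1")


class TestFCSRoundTrip:
    def test_values_names_order_preserved(self, mini_panel, tmp_path):
        em = _random_events(mini_panel, n=200)
        back = read_fcs(write_fcs(em, tmp_path / "a.fcs"), mini_panel)
        # float32 round-trip tolerance
        np.testing.assert_allclose(back.values, em.values, rtol=1e-6)
        assert back.panel.channel_names == mini_panel.channel_names
        assert back.sample_id == "S1"

    def test_shape_contract(self, panel, tmp_path):
        em = _random_events(panel, n=1000)
        back = read_fcs(write_fcs(em, tmp_path / "b.fcs"), panel)
        assert back.values.shape == (1000, len(panel))

    def test_empty_matrix_roundtrip(self, mini_panel, tmp_path):
        em = EventMatrix(np.empty((0, len(mini_panel))), mini_panel, "raw")
        back = read_fcs(write_fcs(em, tmp_path / "c.fcs"), mini_panel)
        assert back.n_cells == 0

    def test_missing_channel_named_in_error(self, mini_panel, tmp_path):
        em = _random_events(mini_panel)
        path = write_fcs(em, tmp_path / "d.fcs")
        bigger = MarkerPanel(list(mini_panel.entries) + [
            PanelEntry("167Er_CD90", "CD90", "167Er", "phenotypic")])
        with pytest.raises(KeyError, match="CD90"):
            read_fcs(path, bigger)

    def test_transformed_matrix_rejected(self, mini_panel, tmp_path):
        em = arcsinh_transform(_random_events(mini_panel))
        with pytest.raises(ValueError, match="raw"):
            write_fcs(em, tmp_path / "e.fcs")

    def test_unparseable_file(self, mini_panel, tmp_path):
        bad = tmp_path / "f.fcs"
        bad.write_bytes(b"not an fcs file at all, definitely " * 4)
        with pytest.raises(FCSFormatError):
            read_fcs(bad, mini_panel)

    def test_unwritable_path(self, mini_panel):
        em = _random_events(mini_panel)
        with pytest.raises(OSError):
            write_fcs(em, "/nonexistent-dir/x.fcs")


class TestArcsinh:
    def test_closed_form(self, mini_panel):
        em = EventMatrix(np.full((1, 5), 5.0), mini_panel, "raw")
        out = arcsinh_transform(em, cofactor=5.0)
        assert out.values[0, 0] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)
        assert out.transform == "arcsinh"

    def test_zero_maps_to_zero_any_cofactor(self, mini_panel):
        em = EventMatrix(np.zeros((3, 5)), mini_panel, "raw")
        for cf in (0.5, 5.0, 150.0):
            assert np.all(arcsinh_transform(em, cf).values == 0)

    def test_invalid_cofactor(self, mini_panel):
        em = _random_events(mini_panel)
        for cf in (0.0, -1.0):
            with pytest.raises(ValueError):
                arcsinh_transform(em, cf)

    def test_double_transform_rejected(self, mini_panel):
        em = arcsinh_transform(_random_events(mini_panel))
        with pytest.raises(ValueError):
            arcsinh_transform(em)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=20, unique=True))
    def test_strictly_increasing(self, xs):
        mini_panel = _make_mini_panel()
        values = np.zeros((len(xs), 5))
        values[:, 0] = xs
        out = arcsinh_transform(EventMatrix(values, mini_panel, "raw"))
        order = np.argsort(xs)
        assert np.all(np.diff(out.values[order, 0]) > 0)

    def test_commutes_with_row_subsetting(self, mini_panel):
        em = _random_events(mini_panel, n=40, seed=2)
        rows = np.array([3, 7, 11, 30])
        a = arcsinh_transform(em).subset(rows).values
        b = arcsinh_transform(em.subset(rows)).values
        np.testing.assert_array_equal(a, b)


class TestNormalizeToMax:
    def test_simple_column(self, mini_panel):
        values = np.tile([[2.0, 1, 1, 1, 1], [4.0, 1, 1, 1, 1]], 1)
        em = EventMatrix(values, mini_panel, "arcsinh")
        out = normalize_to_max(em, ["PanCK"])
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.0])
        assert out.transform == "normalized01"
        # unlisted columns untouched
        np.testing.assert_array_equal(out.values[:, 1], values[:, 1])

    def test_all_zero_column_stays_zero(self, mini_panel):
        values = np.ones((4, 5))
        values[:, 0] = 0.0
        out = normalize_to_max(EventMatrix(values, mini_panel, "arcsinh"), ["PanCK"])
        assert np.all(out.values[:, 0] == 0)

    def test_max_maps_to_exactly_one_and_idempotent(self, mini_panel):
        rng = np.random.default_rng(1)
        em = EventMatrix(rng.random((30, 5)) * 7, mini_panel, "arcsinh")
        markers = ["PanCK", "CD45", "EpCAM"]
        out = normalize_to_max(em, markers)
        for m in markers:
            col = out.marker(m)
            assert col.max() == 1.0
            assert np.all((col >= 0) & (col <= 1))
        # idempotent on already-normalized columns (re-flag as arcsinh to re-run)
        again = normalize_to_max(
            EventMatrix(out.values, mini_panel, "arcsinh"), markers)
        np.testing.assert_array_equal(again.values, out.values)

    def test_unknown_marker_and_empty_matrix(self, mini_panel):
        em = EventMatrix(np.ones((2, 5)), mini_panel, "arcsinh")
        with pytest.raises(KeyError):
            normalize_to_max(em, ["NotAMarker"])
        empty = EventMatrix(np.empty((0, 5)), mini_panel, "arcsinh")
        with pytest.raises(ValueError):
            normalize_to_max(empty, ["PanCK"])

    def test_requires_arcsinh(self, mini_panel):
        em = EventMatrix(np.ones((2, 5)), mini_panel, "raw")
        with pytest.raises(ValueError):
            normalize_to_max(em, ["PanCK"])


class TestEventMatrix:
    def test_missing_values_rejected(self, mini_panel):
        values = np.ones((3, 5))
        values[1, 2] = np.nan
        with pytest.raises(ValueError):
            EventMatrix(values, mini_panel, "raw")

    def test_column_count_must_match_panel(self, mini_panel):
        with pytest.raises(ValueError):
            EventMatrix(np.ones((3, 4)), mini_panel, "raw")
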