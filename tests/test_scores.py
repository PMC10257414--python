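"""Scoring formulas: Ki-67+LNR index, MET score, H-score, hMET score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomet.events import EventMatrix
from cytomet.panel import (EPITHELIAL_MARKERS, MESENCHYMAL_MARKERS,
                           MarkerPanel, PanelEntry)
from cytomet.scores import (h_score, hmet_score, ki67_lnr_index,
                            met_score_cells, met_score_patient)


def _clinical(rows):
    return pd.DataFrame(rows, columns=["patient_id", "ki67_pct",
                                       "n_pos_nodes", "n_excised_nodes"])


class TestKi67LNRIndex:
    def test_upper_bound_attained(self):
        """Cohort-max Ki-67 with every excised node positive gives index 2."""
        tab = ki67_lnr_index(_clinical([("A", 60, 7, 7), ("B", 30, 1, 9)]))
        a = tab.set_index("patient_id").loc["A"]
        assert a["index"] == pytest.approx(2.0)

    def test_half_max_no_positive_nodes(self):
        tab = ki67_lnr_index(_clinical([("A", 60, 0, 5), ("B", 30, 0, 5)]))
        assert tab.set_index("patient_id").loc["B", "index"] == pytest.approx(0.5)

    def test_single_patient_self_normalizes(self):
        tab = ki67_lnr_index(_clinical([("A", 12.5, 2, 8)]))
        assert tab.loc[0, "norm_ki67"] == 1.0
        assert tab.loc[0, "index"] == pytest.approx(1.25)

    def test_bounds_always_respected(self):
        rng = np.random.default_rng(0)
        exc = rng.integers(1, 30, 50)
        tab = ki67_lnr_index(_clinical([
            (f"P{i}", rng.uniform(0.1, 100), rng.integers(0, e + 1), e)
            for i, e in enumerate(exc)
        ]))
        assert ((tab["index"] >= 0) & (tab["index"] <= 2)).all()

    def test_zero_excised_nodes_named(self):
        with pytest.raises(ValueError, match="B"):
            ki67_lnr_index(_clinical([("A", 60, 1, 5), ("B", 30, 0, 0)]))

    def test_all_zero_ki67(self):
        with pytest.raises(ValueError, match="Ki-67"):
            ki67_lnr_index(_clinical([("A", 0, 1, 5), ("B", 0, 0, 5)]))

    def test_invariances(self):
        """Patient order and common positive Ki-67 rescaling do not matter."""
        rows = [("A", 60, 7, 7), ("B", 30, 1, 9), ("C", 15, 0, 4)]
        base = ki67_lnr_index(_clinical(rows)).set_index("patient_id")
        shuffled = ki67_lnr_index(_clinical(rows[::-1])).set_index("patient_id")
        pd.testing.assert_frame_equal(base.sort_index(), shuffled.sort_index())
        scaled = ki67_lnr_index(_clinical(
            [(p, k * 1.5, a, b) for p, k, a, b in rows])).set_index("patient_id")
        pd.testing.assert_frame_equal(base, scaled)


def _make_met_panel():
    entries = [PanelEntry(f"ch{m}", m, "X", "phenotypic")
               for m in EPITHELIAL_MARKERS + MESENCHYMAL_MARKERS]
    return MarkerPanel(entries)


@pytest.fixture
def met_panel():
    return _make_met_panel()


def _met_events(met_panel, rows):
    return EventMatrix(np.asarray(rows, float), met_panel, "normalized01")


class TestMETScore:
    def test_fully_epithelial_is_plus_3(self, met_panel):
        scores = met_score_cells(_met_events(met_panel, [[1, 1, 1, 0, 0, 0]]))
        assert scores[0] == pytest.approx(3.0)

    def test_fully_mesenchymal_is_minus_3(self, met_panel):
        scores = met_score_cells(_met_events(met_panel, [[0, 0, 0, 1, 1, 1]]))
        assert scores[0] == pytest.approx(-3.0)

    def test_balanced_cell_is_zero(self, met_panel):
        scores = met_score_cells(_met_events(met_panel, [[0.4] * 6]))
        assert scores[0] == pytest.approx(0.0)

    def test_arithmetic(self, met_panel):
        scores = met_score_cells(
            _met_events(met_panel, [[0.8, 0.6, 0.4, 0.2, 0.1, 0.3]]))
        assert scores[0] == pytest.approx(1.2)

    def test_wrong_transform_rejected(self, met_panel):
        em = EventMatrix(np.zeros((1, 6)), met_panel, "arcsinh")
        with pytest.raises(ValueError, match="normalized01"):
            met_score_cells(em)

    def test_missing_marker_rejected(self):
        panel = MarkerPanel([PanelEntry("chEpCAM", "EpCAM", "X", "phenotypic")])
        em = EventMatrix(np.zeros((1, 1)), panel, "normalized01")
        with pytest.raises(KeyError, match="CD49f"):
            met_score_cells(em)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(
        st.tuples(*[st.floats(0, 1) for _ in range(6)]), min_size=1, max_size=8))
    def test_antisymmetry_and_bounds(self, rows):
        """Swapping epithelial and mesenchymal values negates the score."""
        met_panel = _make_met_panel()
        rows = np.asarray(rows, float)
        swapped = rows[:, [3, 4, 5, 0, 1, 2]]
        s1 = met_score_cells(_met_events(met_panel, rows))
        s2 = met_score_cells(_met_events(met_panel, swapped))
        np.testing.assert_allclose(s1, -s2, atol=1e-12)
        assert np.all((s1 >= -3) & (s1 <= 3))


class TestMETPatient:
    def test_mean_of_extremes(self):
        s = met_score_patient([3.0, -3.0], ["A", "A"])
        assert s["A"] == pytest.approx(0.0)

    def test_single_cell(self):
        s = met_score_patient([1.7], ["A"])
        assert s["A"] == pytest.approx(1.7)

    def test_mean_within_member_range(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(-3, 3, 100)
        pids = rng.choice(["A", "B", "C"], 100)
        s = met_score_patient(scores, pids)
        for pid in "ABC":
            member = scores[pids == pid]
            assert member.min() <= s[pid] <= member.max()

    def test_no_cells_warns(self):
        with pytest.warns(UserWarning, match="no cancer cells"):
            s = met_score_patient([], [])
        assert s.empty


class TestHScores:
    @pytest.mark.parametrize("pct,intensity,expected", [
        (100, 3, 300), (0, 2, 0), (50, 2, 100),
    ])
    def test_h_score(self, pct, intensity, expected):
        assert h_score(pct, intensity).h == pytest.approx(expected)

    @pytest.mark.parametrize("pct,intensity", [(101, 1), (-1, 1), (50, 3.5), (50, -0.1)])
    def test_out_of_range(self, pct, intensity):
        with pytest.raises(ValueError):
            h_score(pct, intensity)

    def test_hmet_bounds_and_symmetry(self):
        full = {"EpCAM": h_score(100, 3), "CD49f": h_score(100, 3),
                "Vimentin": h_score(0, 0), "aSMA": h_score(0, 0)}
        assert hmet_score(full) == pytest.approx(600.0)
        equal = {m: h_score(50, 2) for m in ("EpCAM", "CD49f", "Vimentin", "aSMA")}
        assert hmet_score(equal) == pytest.approx(0.0)

    def test_hmet_worked_example(self):
        ihc = {"EpCAM": h_score(100, 2), "CD49f": h_score(50, 2),
               "Vimentin": h_score(50, 1), "aSMA": h_score(25, 2)}
        assert hmet_score(ihc) == pytest.approx(200.0)

    def test_hmet_missing_marker_named(self):
        with pytest.raises(KeyError, match="aSMA"):
            hmet_score({"EpCAM": h_score(10, 1), "CD49f": h_score(10, 1),
                        "Vimentin": h_score(10, 1)})
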