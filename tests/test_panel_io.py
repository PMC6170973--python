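"""Panel reading, binarization, activity filters and demographics utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allergotype.panel_io import (
    ATTRITION,
    RESOLUTION,
    UNDETERMINED,
    BinaryPanel,
    PanelFormatError,
    QuantPanel,
    active_components,
    binarize_panel,
    build_activity_timeline,
    classify_dropout_cause,
    compare_groups,
    percent,
    read_panel,
    responder_subjects,
    write_panel,
)


def make_quant(values, subjects=None, components=None, age="5"):
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{i}" for i in range(values.shape[0])]
    components = components or [f"c{j}" for j in range(values.shape[1])]
    return QuantPanel(age, pd.DataFrame(values, index=subjects, columns=components))


def make_binary(values, subjects=None, components=None, age="5"):
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{i}" for i in range(values.shape[0])]
    components = components or [f"c{j}" for j in range(values.shape[1])]
    return BinaryPanel(age, pd.DataFrame(values, index=subjects, columns=components), 0.30)


class TestReadWrite:
    def test_round_trip_toy(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text("subject_id,Der p 1,Fel d 1\ns1,0.5,0\ns2,1.25,0.31\ns3,0,14\n")
        panel = read_panel(f, age_label="5")
        assert panel.data.shape == (3, 2)
        assert panel.component_ids == ["Der p 1", "Fel d 1"]
        assert panel.data.loc["s2", "Fel d 1"] == 0.31

    def test_tab_delimited_autodetected(self, tmp_path):
        f = tmp_path / "panel.tsv"
        f.write_text("subject_id\tc1\tc2\ns1\t0.1\t0.4\n")
        assert read_panel(f, "5").data.shape == (1, 2)

    def test_duplicate_component_named_in_error(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text("subject_id,c1,c1\ns1,0.5,0.2\n")
        with pytest.raises(PanelFormatError, match="c1"):
            read_panel(f, "5")

    def test_duplicate_subject_rejected(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text("subject_id,c1\ns1,0.5\ns1,0.2\n")
        with pytest.raises(PanelFormatError, match="s1"):
            read_panel(f, "5")

    def test_negative_isu_rejected(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text("subject_id,c1\ns1,-0.5\n")
        with pytest.raises(PanelFormatError, match="negative"):
            read_panel(f, "5")

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        f = tmp_path / "panel.csv"
        f.write_text("subject_id,c1,c2\ns1,0.5\ns2,0.1,0.2\n")
        with pytest.raises(PanelFormatError, match="line 2"):
            read_panel(f, "5")

    def test_partial_missing_row_rejected(self):
        with pytest.raises(PanelFormatError, match="whole-row"):
            make_quant([[0.5, np.nan], [0.1, 0.2]])

    @settings(max_examples=25, deadline=None)
    @given(
        rows=st.lists(
            st.lists(
                st.floats(min_value=0, max_value=20).map(lambda v: round(v, 3)),
                min_size=3, max_size=3,
            ),
            min_size=1, max_size=6,
        )
    )
    def test_write_read_round_trip_is_lossless(self, tmp_path_factory, rows):
        panel = make_quant(rows)
        path = tmp_path_factory.mktemp("rt") / "p.csv"
        write_panel(panel, path)
        back = read_panel(path, panel.age_label)
        pd.testing.assert_frame_equal(back.data, panel.data)
        # and the file itself is a fixed point of write(read(.))
        write_panel(back, path.with_suffix(".2.csv"))
        assert path.read_text() == path.with_suffix(".2.csv").read_text()


class TestBinarize:
    def test_threshold_boundary_inclusive(self):
        panel = make_quant([[0.30, 0.29, 0.31]])
        b = binarize_panel(panel, 0.30)
        assert b.data.iloc[0].tolist() == [1.0, 0.0, 1.0]

    def test_all_zero_panel_stays_zero(self):
        b = binarize_panel(make_quant(np.zeros((3, 4))), 0.30)
        assert (b.data.to_numpy() == 0).all()

    def test_missing_rows_preserved(self):
        panel = make_quant([[0.5, 0.4], [np.nan, np.nan]])
        b = binarize_panel(panel)
        assert b.data.iloc[1].isna().all()
        assert b.present_subjects() == ["s0"]

    @settings(max_examples=25, deadline=None)
    @given(st.floats(min_value=0.05, max_value=5.0), st.floats(min_value=0.05, max_value=5.0))
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(0)
        panel = make_quant(rng.uniform(0, 6, size=(5, 4)))
        b_lo = binarize_panel(panel, lo).data.to_numpy()
        b_hi = binarize_panel(panel, hi).data.to_numpy()
        assert (b_hi <= b_lo).all()  # raising the cutoff never creates a positive


class TestActivityFilters:
    def test_min_positive_rule(self):
        b = make_binary([[1, 1, 0], [1, 1, 0], [1, 0, 0]])
        assert active_components(b, min_positive=3) == ["c0"]
        assert active_components(b, min_positive=1) == ["c0", "c1"]

    def test_nested_in_min_positive(self):
        rng = np.random.default_rng(1)
        b = make_binary(rng.integers(0, 2, size=(10, 6)))
        for m in range(1, 6):
            assert set(active_components(b, m + 1)) <= set(active_components(b, m))

    def test_idempotent_on_restricted_panel(self):
        b = make_binary([[1, 1, 0], [1, 0, 0], [1, 0, 1]])
        act = active_components(b, 2)
        restricted = b.restrict(b.subject_ids, act)
        assert active_components(restricted, 2) == act

    def test_responders_and_nonsensitized(self):
        b = make_binary(
            [[1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 0], [0, 0, 0, 1]],
            subjects=["a", "b", "c", "d"],
        )
        # only c0, c2 active in this scenario; subject d is positive only to
        # the inactive c3 and must be excluded
        assert responder_subjects(b, ["c0", "c2"]) == ["a", "b"]

    def test_all_zero_panel_has_no_responders(self):
        b = make_binary(np.zeros((3, 2)))
        assert responder_subjects(b, ["c0", "c1"]) == []

    def test_empty_active_set_warns(self):
        b = make_binary([[1, 0]])
        with pytest.warns(UserWarning):
            assert responder_subjects(b, []) == []

    def test_responders_shrink_with_active_set(self):
        rng = np.random.default_rng(2)
        b = make_binary(rng.integers(0, 2, size=(12, 5)))
        full = set(responder_subjects(b, ["c0", "c1", "c2"]))
        sub = set(responder_subjects(b, ["c0", "c1"]))
        assert sub <= full


class TestActivityTimeline:
    @staticmethod
    def panels_from_columns(columns_by_age):
        """columns_by_age: {age: {component: column}}, all same subjects."""
        panels = []
        for age, cols in columns_by_age.items():
            frame = pd.DataFrame(cols, dtype=float)
            frame.index = [f"s{i}" for i in range(len(frame))]
            panels.append(BinaryPanel(age, frame, 0.30))
        return panels

    def test_dropout_and_reactivation(self):
        on, off = [1, 1, 1], [0, 0, 0]
        panels = self.panels_from_columns(
            {"3": {"x": on}, "5": {"x": on}, "8": {"x": off}, "11": {"x": on}}
        )
        tl = build_activity_timeline(panels, min_positive=3)
        assert tl.status.loc["x"].tolist() == ["active", "active", "inactive", "active"]
        assert tl.dropouts[["component", "age"]].values.tolist() == [["x", "8"]]
        assert tl.first_active_age["x"] == "3"

    def test_never_active(self):
        panels = self.panels_from_columns({"3": {"x": [1, 0, 0]}, "5": {"x": [0, 1, 0]}})
        tl = build_activity_timeline(panels, min_positive=3)
        assert (tl.status.loc["x"] == "never-active").all()
        assert tl.ever_active() == []

    def test_constant_activity_no_dropouts(self):
        panels = self.panels_from_columns({"3": {"x": [1, 1, 1]}, "5": {"x": [1, 1, 1]}})
        tl = build_activity_timeline(panels, min_positive=3)
        assert tl.dropouts.empty

    def test_single_panel_no_dropout_annotations(self):
        panels = self.panels_from_columns({"3": {"x": [1, 1, 1]}})
        assert build_activity_timeline(panels).dropouts.empty


class TestDropoutCause:
    @staticmethod
    def two_age_panels(prev_col, cur_col, cur_subjects):
        subjects = ["s0", "s1", "s2", "s3"]
        p1 = BinaryPanel("5", pd.DataFrame({"x": prev_col}, index=subjects, dtype=float), 0.3)
        p2 = BinaryPanel(
            "8", pd.DataFrame({"x": cur_col}, index=cur_subjects, dtype=float), 0.3
        )
        return [p1, p2]

    def run(self, panels):
        tl = build_activity_timeline(panels, min_positive=3)
        return classify_dropout_cause(tl, panels).dropouts

    def test_resolution(self):
        # all 3 previously positive subjects present and now negative
        panels = self.two_age_panels([1, 1, 1, 0], [0, 0, 0, 0], ["s0", "s1", "s2", "s3"])
        assert self.run(panels)["cause"].tolist() == [RESOLUTION]

    def test_attrition(self):
        # every previously positive subject missing at the drop-out age
        panels = self.two_age_panels([1, 1, 1, 0], [0.0], ["s3"])
        assert self.run(panels)["cause"].tolist() == [ATTRITION]

    def test_mixed_is_undetermined(self):
        panels = self.two_age_panels([1, 1, 1, 0], [0.0, 0.0], ["s0", "s3"])
        assert self.run(panels)["cause"].tolist() == [UNDETERMINED]


class TestDemographics:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(47, 225, 20.89), (588, 1184, 49.66), (188, 341, 55.13), (67, 150, 44.67), (0, 100, 0.0)],
    )
    def test_percent_printed_table_values(self, num, den, expected):
        assert percent(num, den) == expected

    def test_percent_round_half_up(self):
        assert percent(1, 8) == 12.5
        assert percent(1, 16) == 6.25
        assert percent(5, 2000) == 0.25  # exact .25 stays
        assert percent(1, 3200) == 0.03  # 0.03125 rounds down
        assert percent(9, 1600) == 0.56  # 0.5625 rounds up at the half

    def test_percent_complement_sums_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = int(rng.integers(1, 2000))
            n = int(rng.integers(0, d + 1))
            assert 99.99 <= percent(n, d) + percent(d - n, d) <= 100.01

    def test_percent_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    def test_identical_proportions_give_p_near_1(self):
        stat, p = compare_groups([[50, 50], [500, 500]])
        assert p > 0.9

    def test_maternal_asthma_contrast_significant(self):
        # included 47/225 vs excluded 125/954: group difference at the 1% level
        stat, p = compare_groups([[47, 225 - 47], [125, 954 - 125]])
        assert p < 0.01

    def test_doubling_counts_sharpens_evidence(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(10, 80, size=(2, 2))
            t[0, 0] += 30  # ensure some association and expected counts >= 5
            s1, p1 = compare_groups(t)
            s2, p2 = compare_groups(2 * t)
            assert s2 > s1
            assert p2 <= p1

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = compare_groups([[0, 0], [10, 20]])
        assert p == 1.0
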