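"""Simplified screening-table construction, lookup and classification."""

import numpy as np
import pytest

from growthscreen import (
    ChildRecord,
    CoverageError,
    GrowthReference,
    LmsRecord,
    OutOfRangeError,
    ScreeningTable,
    TableInvariantError,
    build_screening_table,
    classify_simplified,
    classify_who,
    export_table,
    import_table,
    locate_grid_cells,
)


def fig1_style_table():
    """Two-row, two-column table carrying the worked-example grid weights."""
    return ScreeningTable(
        sex="male",
        age_years=np.array([10.0, 10.5]),
        percentiles=(25, 50),
        heights=np.array([[144.4, 148.3], [144.8, 147.2]]),
        weights=np.array([[38.5, 40.6], [39.4, 40.8]]),
    )


class TestBuild:
    def test_trivial_grid_weight(self):
        # height 100 cm at every percentile and +1 SD BMI of 20 -> every cell 20.0 kg
        ages = range(60, 229)
        href = GrowthReference("height_for_age", [
            LmsRecord(s, a, 1.0, 100.0, 1e-9) for s in ("male", "female") for a in ages
        ])
        bref = GrowthReference("bmi_for_age", [
            LmsRecord(s, a, 1.0, 18.1818182, 0.1) for s in ("male", "female") for a in ages
        ])
        t = build_screening_table(bref, href, "male")
        assert np.allclose(t.heights, 100.0)
        assert np.allclose(t.weights, 20.0)

    def test_shape_and_monotonicity(self, tables):
        for t in tables.values():
            assert len(t.age_years) == 29  # 5.0..19.0 by 0.5
            assert len(t.percentiles) == 11
            assert np.all(np.diff(t.heights, axis=1) > 0)
            assert np.all(np.diff(t.weights, axis=1) > 0)

    def test_cells_match_definition(self, tables, bmi_ref, height_ref):
        # each cell is the +1 SD BMI cutoff times squared column height (m),
        # up to the 0.1 kg cell rounding
        from growthscreen import value_at_zscore

        t = tables["female"]
        for i in (0, 10, 28):
            cut = value_at_zscore(1.0, *bmi_ref.lms_at("female", int(t.age_years[i] * 12)))
            for j in (0, 5, 10):
                expected = cut * (t.heights[i, j] / 100.0) ** 2
                assert t.weights[i, j] == pytest.approx(expected, abs=0.051)

    def test_coverage_gap_names_months(self, bmi_ref, height_ref):
        from growthscreen import make_synthetic_reference

        short = make_synthetic_reference("height_for_age", age_range=(72, 228))
        with pytest.raises(CoverageError, match="60"):
            build_screening_table(bmi_ref, short, "male")

    def test_invariant_violation_rejected(self):
        with pytest.raises(TableInvariantError, match="not increasing"):
            ScreeningTable(
                sex="male",
                age_years=np.array([10.0]),
                percentiles=(25, 50),
                heights=np.array([[144.4, 148.3]]),
                weights=np.array([[40.6, 38.5]]),  # decreasing
            )


class TestLocate:
    def test_worked_example_bracketing(self, tables):
        # a 122-month boy at 146 cm falls between rows 10 / 10.5 and between
        # two height columns in each row: 4 matched cells
        lookup = locate_grid_cells(tables["male"], 122, 146.0)
        assert sorted({c[0] for c in lookup.cells}) == [10.0, 10.5]
        assert len(lookup.cells) == 4
        for _, _, h_lo in [(c[0], c[1], c[2]) for c in lookup.cells[::2]]:
            assert h_lo < 146.0
        assert lookup.threshold == min(lookup.grid_weights)
        assert not lookup.clamped

    def test_on_grid_single_cell(self, tables):
        t = tables["male"]
        lookup = locate_grid_cells(t, 120, float(t.heights[10, 4]))
        assert len(lookup.cells) == 1
        assert lookup.cells[0][0] == 10.0
        assert lookup.cells[0][1] == t.percentiles[4]

    def test_clamped_below_first_percentile(self, tables):
        t = tables["male"]
        low = float(t.heights[10, 0]) - 5.0
        lookup = locate_grid_cells(t, 120, low)
        assert lookup.clamped
        assert all(c[1] == t.percentiles[0] for c in lookup.cells)

    def test_age_outside_span(self, tables):
        with pytest.raises(OutOfRangeError):
            locate_grid_cells(tables["male"], 59, 140.0)
        with pytest.raises(OutOfRangeError):
            locate_grid_cells(tables["male"], 229, 140.0)


class TestClassifySimplified:
    def test_worked_example_healthy_then_unhealthy(self):
        table = fig1_style_table()
        boy = ChildRecord("fig1", "male", 122, 38.0, 146.0)
        status = classify_simplified(boy, table)
        assert status.label == "healthy"
        assert sorted(status.detail["grid_weights"]) == [38.5, 39.4, 40.6, 40.8]
        heavier = ChildRecord("fig1b", "male", 122, 38.7, 146.0)
        status2 = classify_simplified(heavier, table)
        # 38.7 kg reaches the lowest matched grid (38.5): screened overweight
        assert status2.label == "unhealthy"
        assert status2.detail["threshold"] == 38.5

    def test_weight_above_all_grids(self):
        table = fig1_style_table()
        heavy = ChildRecord("h", "male", 122, 41.8, 146.0)
        assert classify_simplified(heavy, table).label == "unhealthy"

    def test_tie_at_min_grid_is_unhealthy(self):
        # the table rule is >= ("placed within the grid"), unlike the strict
        # BMI-arm rule
        table = fig1_style_table()
        assert classify_simplified(
            ChildRecord("t", "male", 122, 38.5, 146.0), table
        ).label == "unhealthy"


class TestOnGridEquivalence:
    def test_simplified_matches_who_off_the_rounding_band(self, tables, bmi_ref):
        # for a child exactly on an age row and height column, the two arms
        # disagree only for weights inside the 0.1 kg grid rounding band
        t = tables["male"]
        for i in range(0, 29, 4):
            age = int(round(t.age_years[i] * 12))
            for j in range(0, 11, 3):
                h = float(t.heights[i, j])
                grid = float(t.weights[i, j])
                for w, expect in ((grid - 0.2, "healthy"), (grid + 0.2, "unhealthy")):
                    child = ChildRecord("g", "male", age, w, h)
                    assert classify_simplified(child, t).label == expect
                    assert classify_who(child, bmi_ref).label == expect


class TestRoundTrip:
    def test_export_import_identity(self, tables, tmp_path):
        path = tmp_path / "tables.csv"
        export_table(list(tables.values()), path)
        back = import_table(path)
        for sex, t in tables.items():
            assert np.array_equal(back[sex].age_years, t.age_years)
            assert back[sex].percentiles == t.percentiles
            assert np.allclose(back[sex].heights, t.heights)
            assert np.allclose(back[sex].weights, t.weights)

    def test_import_rejects_broken_monotonicity(self, tables, tmp_path):
        path = tmp_path / "tables.csv"
        export_table(tables["male"], path)
        text = path.read_text().splitlines()
        header = text[0].split(",")
        row = text[5].split(",")
        w_cols = [k for k, c in enumerate(header) if c.startswith("w")]
        row[w_cols[0]], row[w_cols[1]] = row[w_cols[1]], row[w_cols[0]]
        text[5] = ",".join(row)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(TableInvariantError, match="not increasing"):
            import_table(path)

    def test_exported_row_count(self, tables, tmp_path):
        path = tmp_path / "boys.csv"
        export_table(tables["male"], path)
        assert len(path.read_text().strip().splitlines()) == 30  # header + 29 rows
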