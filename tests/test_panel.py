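"""Panel data model, CSV round-trips, domain validation, alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfnowcast import panel as pio
from sfnowcast import weeks as wk
from sfnowcast.panel import (PanelFormatError, PanelGapError,
                             PanelValidationError, SourceKind, StatePanel,
                             ValueDomain, WeeklyRecord, align_panels,
                             read_panel_csv, validate_value, write_panel_csv)


def small_panel(state="AA", n=10, start=(2016, 1), population=1_000_000):
    weeks = wk.week_range(start, n)
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "google_trends": np.linspace(10, 100, n),
        "twitter": rng.integers(0, 50, n).astype(float),
        "phq9": np.full(n, 12.5),
    }, index=[wk.week_label(*w) for w in weeks])
    return StatePanel(state, weeks, df, rng.integers(0, 20, n), population)


class TestSourceKinds:
    def test_exactly_six_kinds_and_deaths_is_outcome(self):
        assert len(SourceKind) == 6
        assert SourceKind.DEATHS.is_outcome
        assert sum(s.is_outcome for s in SourceKind) == 1

    @pytest.mark.parametrize("source, good, bad", [
        (SourceKind.GOOGLE_TRENDS, 100.0, 101.0),
        (SourceKind.YOUTUBE_TRENDS, 0.0, -0.1),
        (SourceKind.TWITTER, 7, 7.5),
        (SourceKind.ED_VISITS, 0, -1),
        (SourceKind.PHQ9, 27.0, 27.5),
        (SourceKind.DEATHS, 3, -3),
    ])
    def test_value_domains(self, source, good, bad):
        assert validate_value(source, good) is None
        assert validate_value(source, bad) is not None

    @given(st.sampled_from(list(SourceKind)), st.floats(-50, 150))
    @settings(max_examples=200, deadline=None)
    def test_validation_matches_domain_definition(self, source, value):
        """Every record is accepted iff its value satisfies its domain."""
        err = validate_value(source, value)
        dom = source.domain
        if dom is ValueDomain.TREND_SCORE:
            ok = 0 <= value <= 100
        elif dom is ValueDomain.COUNT:
            ok = value >= 0 and abs(value - round(value)) <= 1e-9
        else:
            ok = 0 <= value <= 27
        assert (err is None) == ok


class TestCsvRoundTrip:
    def test_read_write_identity(self, tmp_path, informative_panel):
        path = tmp_path / "p.csv"
        write_panel_csv(informative_panel, path)
        back = read_panel_csv(path, "AA", informative_panel.population)
        assert back.weeks == informative_panel.weeks
        assert np.array_equal(back.deaths, informative_panel.deaths)
        assert list(back.sources.columns) == list(informative_panel.sources.columns)
        assert np.allclose(back.sources.to_numpy(), informative_panel.sources.to_numpy())

    def test_write_is_byte_stable(self, tmp_path):
        p = small_panel()
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_panel_csv(p, a)
        write_panel_csv(p, b)
        assert a.read_bytes() == b.read_bytes()

    def test_read_pivots_sources_to_columns(self, tmp_path):
        p = small_panel()
        path = tmp_path / "p.csv"
        write_panel_csv(p, path)
        back = read_panel_csv(path, "AA", p.population)
        assert back.n_weeks == 10
        assert len(back.sources.columns) == 3

    def test_empty_panel_refused(self, tmp_path):
        p = small_panel(n=1)
        p.weeks, p.deaths = [], np.zeros(0, dtype=int)
        p.sources = p.sources.iloc[:0]
        with pytest.raises(PanelValidationError):
            write_panel_csv(p, tmp_path / "x.csv")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("state,source,value\nAA,deaths,3\n")
        with pytest.raises(PanelFormatError, match="missing columns"):
            read_panel_csv(path, "AA", 1000)

    def test_out_of_domain_value_names_the_record(self, tmp_path, informative_panel):
        path = tmp_path / "p.csv"
        write_panel_csv(informative_panel, path)
        df = pd.read_csv(path)
        idx = df[df.source == "google_trends"].index[0]
        df.loc[idx, "value"] = 101.0
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="google_trends"):
            read_panel_csv(path, "AA", informative_panel.population)

    def test_missing_week_raises_gap_error_naming_it(self, tmp_path):
        p = small_panel(start=(2016, 1), n=10)
        path = tmp_path / "p.csv"
        write_panel_csv(p, path)
        df = pd.read_csv(path)
        df = df[~((df.iso_year == 2016) & (df.iso_week == 7))]
        df.to_csv(path, index=False)
        with pytest.raises(PanelGapError, match="2016-W07") as exc:
            read_panel_csv(path, "AA", p.population)
        assert (2016, 7) in exc.value.missing

    def test_round_trip_on_four_state_scenario(self, tmp_path, four_state_scenario):
        cfg, panels, _ = four_state_scenario
        path = tmp_path / "all.csv"
        pio.write_panels_csv(list(panels.values()), path)
        for state, p in panels.items():
            back = read_panel_csv(path, state, p.population)
            assert back.weeks == p.weeks
            assert np.array_equal(back.deaths, p.deaths)
            assert np.allclose(back.sources.to_numpy(), p.sources.to_numpy())


class TestAlignment:
    def test_trims_to_week_intersection(self):
        a = small_panel(n=20, start=(2016, 1))
        b = small_panel(state="BB", n=10, start=(2016, 6))
        out = align_panels([a, b], policy="strict")
        assert out[0].weeks == out[1].weeks == wk.week_range((2016, 6), 10)

    def test_one_week_gap_interpolated_as_neighbor_mean(self):
        p = small_panel(n=10)
        keep = [i for i in range(10) if i != 4]
        gappy = StatePanel(p.state, [p.weeks[i] for i in keep], p.sources.iloc[keep],
                           p.deaths[keep], p.population)
        out = align_panels([gappy], policy="interpolate")[0]
        assert out.n_weeks == 10
        expected = (p.sources.iloc[3]["google_trends"] + p.sources.iloc[5]["google_trends"]) / 2
        assert out.sources.iloc[4]["google_trends"] == pytest.approx(expected)
        # counts are re-rounded to integers
        assert float(out.sources.iloc[4]["twitter"]).is_integer()

    def test_three_week_gap_rejected_under_interpolate(self):
        p = small_panel(n=12)
        keep = [i for i in range(12) if i not in (4, 5, 6)]
        gappy = StatePanel(p.state, [p.weeks[i] for i in keep], p.sources.iloc[keep],
                           p.deaths[keep], p.population)
        with pytest.raises(PanelGapError):
            align_panels([gappy], policy="interpolate")

    def test_strict_policy_rejects_any_gap(self):
        p = small_panel(n=10)
        keep = [i for i in range(10) if i != 4]
        gappy = StatePanel(p.state, [p.weeks[i] for i in keep], p.sources.iloc[keep],
                           p.deaths[keep], p.population)
        with pytest.raises(PanelGapError):
            align_panels([gappy], policy="strict")

    def test_empty_intersection_is_error(self):
        a = small_panel(n=5, start=(2016, 1))
        b = small_panel(state="BB", n=5, start=(2017, 1))
        with pytest.raises(PanelValidationError):
            align_panels([a, b])


class TestWeeklyRecord:
    def test_validates_week_and_domain(self):
        WeeklyRecord("AA", SourceKind.DEATHS, 2016, 52, 3).validate()
        with pytest.raises(ValueError):
            WeeklyRecord("AA", SourceKind.DEATHS, 2016, 53, 3).validate()  # 2016 has 52 weeks
        with pytest.raises(PanelValidationError):
            WeeklyRecord("AA", SourceKind.GOOGLE_TRENDS, 2016, 1, 150.0).validate()

    def test_duplicate_record_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "state,source,iso_year,iso_week,value\n"
            "AA,deaths,2016,1,3\nAA,deaths,2016,1,4\n")
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_panel_csv(path, "AA", 1000)
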