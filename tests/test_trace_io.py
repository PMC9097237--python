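"""Balance-log parsing, raw-flow tables and report serialization."""

import logging

import numpy as np
import pandas as pd
import pytest

from efmkit import (
    BalanceLogDialect,
    EmptyTraceError,
    FlowTrace,
    FormatError,
    LeafRecord,
    REPORT_COLUMNS,
    ReportRecord,
    StateError,
    TraceDataError,
    ValidationError,
    read_balance_log,
    read_report,
    write_raw_flow_table,
    write_report,
)

DIALECT_TW = BalanceLogDialect(time_col="t", weight_col="w")


def _leaf(**kw):
    defaults = dict(
        species="Oryza sativa",
        leaf_area_m2=2.5e-3,
        psi_initial_MPa=-0.05,
        psi_final_MPa=-0.31,
        T_leaf_C=27.0,
        PARa_umol_m2_s=1000.0,
        T_air_C=27.0,
        airflow_m_s=1.0,
    )
    defaults.update(kw)
    return LeafRecord(**defaults)


class TestReadBalanceLog:
    def test_three_row_csv(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("t,w\n0,100.000\n3,99.998\n6,99.996\n")
        trace = read_balance_log(p, DIALECT_TW)
        assert trace.n == 3
        assert trace.sampling_interval_s == 3.0
        np.testing.assert_allclose(trace.weight_g, [100.0, 99.998, 99.996])

    def test_duplicate_timestamp_collapsed_by_mean(self, tmp_path, caplog):
        p = tmp_path / "log.csv"
        p.write_text("t,w\n0,100.0\n3,99.0\n3,97.0\n6,96.0\n")
        with caplog.at_level(logging.WARNING, logger="efmkit.io"):
            trace = read_balance_log(p, DIALECT_TW)
        assert trace.n == 3
        assert trace.weight_g[1] == pytest.approx(98.0)
        assert any("duplicate" in rec.message for rec in caplog.records)

    def test_unparseable_rows_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "log.csv"
        p.write_text("t,w\n0,100.0\n3,oops\n6,99.6\n9,99.4\n")
        with caplog.at_level(logging.WARNING, logger="efmkit.io"):
            trace = read_balance_log(p, DIALECT_TW)
        assert trace.n == 3
        assert any("unparseable" in rec.message for rec in caplog.records)

    def test_missing_columns_is_format_error(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("a,b\n0,1\n3,2\n")
        with pytest.raises(FormatError):
            read_balance_log(p, DIALECT_TW)

    def test_single_valid_row_is_empty_trace_error(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("t,w\n0,100.0\nx,y\n")
        with pytest.raises(EmptyTraceError):
            read_balance_log(p, DIALECT_TW)

    def test_wallclock_timestamps_become_elapsed_seconds(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text(
            "t,w\n2024-05-01 08:00:00,100.0\n2024-05-01 08:00:03,99.9\n"
            "2024-05-01 08:00:06,99.8\n"
        )
        trace = read_balance_log(p, DIALECT_TW)
        np.testing.assert_allclose(trace.time_s, [0.0, 3.0, 6.0])

    def test_flow_only_log(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("time_s,flow_mmol_m2_s\n0,8.1\n3,8.2\n6,8.3\n")
        trace = read_balance_log(p)
        assert trace.weight_g is None
        np.testing.assert_allclose(trace.flow, [8.1, 8.2, 8.3])


class TestRawFlowTable:
    def _trace(self, n=50):
        rng = np.random.default_rng(7)
        t = np.arange(n) * 3.0
        return FlowTrace(time_s=t, flow=8.75 + rng.normal(0, 0.1, n))

    def test_row_count(self, tmp_path):
        trace = self._trace()
        path = tmp_path / "raw.csv"
        write_raw_flow_table(trace, "leaf1", path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == trace.n + 1

    def test_roundtrip_reconstructs_series(self, tmp_path):
        trace = self._trace()
        path = tmp_path / "raw.csv"
        write_raw_flow_table(trace, "leaf1", path)
        back = read_balance_log(path)
        np.testing.assert_allclose(back.time_s, trace.time_s, rtol=1e-8)
        np.testing.assert_allclose(back.flow, trace.flow, rtol=1e-8)
        assert back.weight_g is None

    def test_empty_leaf_id_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_raw_flow_table(self._trace(), "", tmp_path / "raw.csv")

    def test_flow_not_computed_is_state_error(self, tmp_path):
        trace = FlowTrace(time_s=[0, 3, 6], weight_g=[100, 99.9, 99.8])
        with pytest.raises(StateError):
            write_raw_flow_table(trace, "leaf1", tmp_path / "raw.csv")


class TestReport:
    def _steady_record(self):
        return ReportRecord(
            leaf_id="L1",
            leaf=_leaf(),
            curve_class="D",
            last_segment_duration_s=1500.0,
            slope_p_value=0.4,
            E_mmol_m2_s=8.75,
            K_leaf_raw=28.2,
            K_leaf_25C=27.1,
            viscosity_factor=0.96,
            flow_trace_uri="L1_rawflow.csv",
        )

    def test_steady_row_carries_kleaf(self, tmp_path):
        path = tmp_path / "report.csv"
        write_report([self._steady_record()], path)
        df = read_report(path)
        assert len(df) == 1
        assert df.loc[0, "K_leaf_25C_mmol_m2_s_MPa"] == pytest.approx(27.1)
        assert df.loc[0, "curve_class"] == "D"

    def test_nonsteady_row_has_na_kleaf(self, tmp_path):
        rec = ReportRecord(
            leaf_id="L2",
            leaf=_leaf(),
            curve_class="C",
            last_segment_duration_s=600.0,
            slope_p_value=1e-9,
        )
        path = tmp_path / "report.csv"
        write_report([rec], path)
        raw = path.read_text().splitlines()
        row = raw[1].split(",")
        cols = raw[0].split(",")
        assert row[cols.index("K_leaf_mmol_m2_s_MPa")] == "NA"
        assert row[cols.index("E_mmol_m2_s")] == "NA"
        assert row[cols.index("curve_class")] == "C"

    def test_nonsteady_record_with_kleaf_is_invalid(self):
        rec = self._steady_record()
        rec.curve_class = "B"
        with pytest.raises(ValidationError, match="K_leaf_raw|E_mmol_m2_s"):
            rec.validate()

    def test_zero_records_gives_header_only(self, tmp_path):
        path = tmp_path / "report.csv"
        write_report([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == REPORT_COLUMNS

    def test_header_covers_required_metadata(self):
        required = {
            "species", "leaf_area_m2", "psi_initial_MPa", "psi_final_MPa",
            "T_leaf_C", "PARa_umol_m2_s", "T_air_C", "airflow_m_s",
            "E_mmol_m2_s", "K_leaf_mmol_m2_s_MPa", "K_leaf_25C_mmol_m2_s_MPa",
            "curve_class",
        }
        assert required <= set(REPORT_COLUMNS)

    def test_footer_comments_survive_roundtrip(self, tmp_path):
        path = tmp_path / "report.csv"
        write_report([self._steady_record()], path, footer={"slope_alpha": 0.001})
        assert "# slope_alpha = 0.001" in path.read_text()
        df = read_report(path)  # comments must not corrupt parsing
        assert len(df) == 1
        assert df.loc[0, "E_mmol_m2_s"] == pytest.approx(8.75)


class TestLeafRecordInvariants:
    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValidationError, match="leaf_area_m2"):
            _leaf(leaf_area_m2=0.0)

    def test_positive_water_potential_rejected(self):
        with pytest.raises(ValidationError, match="psi_final_MPa"):
            _leaf(psi_final_MPa=0.2)


class TestFlowTraceInvariants:
    def test_non_monotone_time_rejected(self):
        with pytest.raises(TraceDataError):
            FlowTrace(time_s=[0, 3, 3], flow=[1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(TraceDataError):
            FlowTrace(time_s=[0, 3, 6], flow=[1, 2])

    def test_trailing_window_point_count(self):
        t = np.arange(0, 1803, 3.0)
        trace = FlowTrace(time_s=t, flow=np.zeros(t.size))
        a, b = trace.trailing_window(900.0)
        assert b - a + 1 == 300
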