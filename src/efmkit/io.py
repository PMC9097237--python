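"""Readers and writers for balance logs, raw-flow tables and report tables.

All external representations are delimited UTF-8 text with '.' as the
decimal separator: a configurable-column balance log (input), a long-format
raw-flow table (one row per sample, so published K_leaf values remain
re-analyzable), and the tidy one-row-per-leaf report table with
unit-annotated headers.  Lines starting with ``#`` are treated as comments
on read, which lets report files carry a footer echoing every threshold
used to produce them.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyTraceError, FormatError, StateError, ValidationError
from .records import NA_TOKEN, REPORT_COLUMNS, ReportRecord, record_to_row
from .trace import FLOW_PER_AREA, FlowTrace

log = logging.getLogger(__name__)

__all__ = [
    "BalanceLogDialect",
    "read_balance_log",
    "write_raw_flow_table",
    "write_report",
    "read_report",
]


@dataclass
class BalanceLogDialect:
    """Column mapping of a balance log file.

    ``time_col`` may hold elapsed seconds or wall-clock timestamps
    (anything :func:`pandas.to_datetime` parses); timestamps are converted
    to seconds since the first sample.  At least one of ``weight_col`` /
    ``flow_col`` must be present in the file.
    """

    time_col: str = "time_s"
    weight_col: str = "weight_g"
    flow_col: str = "flow_mmol_m2_s"
    delimiter: str = ","
    flow_units: str = FLOW_PER_AREA


def _parse_time(raw: pd.Series) -> pd.Series:
    """Elapsed seconds from a numeric or wall-clock time column."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().sum() >= 2:
        return numeric
    try:
        stamps = pd.to_datetime(raw, errors="coerce", format="mixed")
    except (ValueError, TypeError):
        stamps = pd.Series(pd.NaT, index=raw.index)
    if stamps.notna().sum() >= 2:
        origin = stamps.dropna().iloc[0]
        return (stamps - origin).dt.total_seconds()
    # too few parseable values either way; downstream row-dropping will
    # raise EmptyTraceError with an accurate message
    return numeric


def read_balance_log(
    path: str | os.PathLike, dialect: BalanceLogDialect | None = None
) -> FlowTrace:
    """Parse a delimited balance log into a :class:`FlowTrace`.

    Rows with unparseable numerics are dropped (and counted in a warning);
    duplicate timestamps are collapsed by averaging.  Requires at least two
    valid rows after cleaning.
    """
    dialect = dialect or BalanceLogDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, comment="#", skip_blank_lines=True)
    if dialect.time_col not in df.columns:
        raise FormatError(f"missing required time column {dialect.time_col!r}")
    has_weight = dialect.weight_col in df.columns
    has_flow = dialect.flow_col in df.columns
    if not (has_weight or has_flow):
        raise FormatError(
            f"need a weight column {dialect.weight_col!r} or a flow column "
            f"{dialect.flow_col!r}"
        )
    out = pd.DataFrame({"t": _parse_time(df[dialect.time_col])})
    if has_weight:
        out["w"] = pd.to_numeric(df[dialect.weight_col], errors="coerce")
    if has_flow:
        out["f"] = pd.to_numeric(df[dialect.flow_col], errors="coerce")

    n_raw = len(out)
    out = out.dropna()
    if n_raw - len(out):
        log.warning("%s: dropped %d unparseable row(s)", path, n_raw - len(out))
    n_valid = len(out)
    out = out.groupby("t", as_index=False, sort=True).mean()
    if n_valid - len(out):
        log.warning(
            "%s: collapsed %d duplicate timestamp(s) by mean", path, n_valid - len(out)
        )
    if len(out) < 2:
        raise EmptyTraceError(f"{path}: fewer than 2 valid samples")

    t = out["t"].to_numpy()
    interval = float(np.median(np.diff(t)))
    return FlowTrace(
        time_s=t,
        weight_g=out["w"].to_numpy() if has_weight else None,
        flow=out["f"].to_numpy() if has_flow else None,
        flow_units=dialect.flow_units,
        sampling_interval_s=interval if interval > 0 else 3.0,
    )


def write_raw_flow_table(
    trace: FlowTrace, leaf_id: str, path: str | os.PathLike, sig_digits: int = 9
) -> None:
    """Write the long-format raw-flow table (leaf_id, time_s, flow).

    Values are serialized with ``sig_digits`` significant digits (default 9)
    so a read-back reconstructs the series beyond the 6-significant-digit
    guarantee of the format.
    """
    if trace.flow is None:
        raise StateError("write_raw_flow_table requires computed flow")
    if not leaf_id:
        raise ValidationError("leaf_id must be non-empty")
    df = pd.DataFrame(
        {
            "leaf_id": leaf_id,
            "time_s": trace.time_s,
            "flow_mmol_m2_s": trace.flow,
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{sig_digits}g")


def write_report(
    records: list[ReportRecord],
    path: str | os.PathLike,
    footer: dict | None = None,
) -> None:
    """Write the tidy report table: one validated row per leaf.

    Missing optional values are serialized as the literal ``NA`` token.
    ``footer`` entries are appended as ``# key = value`` comment lines so
    every threshold that produced the report travels with it.
    """
    rows = [record_to_row(r) for r in records]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, index=False, na_rep=NA_TOKEN, float_format="%.9g")
        if footer:
            for key, value in footer.items():
                fh.write(f"# {key} = {value}\n")


def read_report(path: str | os.PathLike) -> pd.DataFrame:
    """Read a report table back (footer comments skipped, NA decoded)."""
    return pd.read_csv(path, comment="#", na_values=[NA_TOKEN], keep_default_na=True)
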