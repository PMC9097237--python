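"""Per-leaf metadata and report records.

A :class:`LeafRecord` carries everything about the leaf and its measurement
environment that a K_leaf value cannot be interpreted without: leaf area,
initial/final water potential, leaf temperature, light, air temperature,
airflow, and the sampling/storage/degassing provenance flags.  A
:class:`ReportRecord` extends it with the pipeline outputs (E, K_leaf raw
and 25 °C-standardized, curve class, steadiness diagnostics) and a pointer
to the archived raw flow trace — the standardized, self-describing row
format this toolkit recommends for publishing EFM measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .exceptions import ValidationError

#: serialized missing-value token (unambiguous across spreadsheet dialects)
NA_TOKEN = "NA"


@dataclass
class LeafRecord:
    """Leaf + environment metadata for one EFM measurement.

    Water potentials are in MPa and must be ≤ 0; ``psi_final_MPa`` must be
    strictly negative for a valid K_leaf.  ``height_offset_cm`` is the
    signed height of the reservoir water surface relative to the leaf
    (negative = meniscus below the leaf).
    """

    species: str
    leaf_area_m2: float
    psi_final_MPa: float | None = None
    psi_initial_MPa: float | None = None
    T_leaf_C: float | None = None
    PARa_umol_m2_s: float | None = None
    T_air_C: float | None = None
    airflow_m_s: float | None = None
    sampling_time: str | None = None
    storage: str | None = None
    degassed: bool | None = None
    height_offset_cm: float | None = None

    def __post_init__(self) -> None:
        if self.leaf_area_m2 is None or self.leaf_area_m2 <= 0:
            raise ValidationError("leaf_area_m2 must be > 0")
        for name in ("psi_initial_MPa", "psi_final_MPa"):
            v = getattr(self, name)
            if v is not None and v > 0:
                raise ValidationError(f"{name} must be <= 0 (water potential)")


@dataclass
class ReportRecord:
    """One tidy report row: leaf metadata plus pipeline outputs.

    Invariant: a leaf classified non-steady (class A, B or C) carries no
    flow or conductance values — publishing a K_leaf from a non-steady
    trace is exactly the practice the report format exists to prevent.
    """

    leaf_id: str
    leaf: LeafRecord
    curve_class: str | None = None
    last_segment_duration_s: float | None = None
    slope_p_value: float | None = None
    E_mmol_m2_s: float | None = None
    K_leaf_raw: float | None = None
    K_leaf_25C: float | None = None
    viscosity_factor: float | None = None
    flow_trace_uri: str | None = None
    notes: str | None = field(default=None, compare=False)

    def validate(self) -> None:
        if not self.leaf_id:
            raise ValidationError("leaf_id must be non-empty")
        if self.curve_class is not None and self.curve_class not in "ABCD":
            raise ValidationError(f"curve_class must be A/B/C/D, got {self.curve_class!r}")
        if self.curve_class in ("A", "B", "C"):
            for name in ("E_mmol_m2_s", "K_leaf_raw", "K_leaf_25C"):
                if getattr(self, name) is not None:
                    raise ValidationError(
                        f"{name} must be absent for non-steady class {self.curve_class}"
                    )
        if self.curve_class == "D":
            if self.E_mmol_m2_s is None:
                raise ValidationError("E_mmol_m2_s required for a steady (class D) record")


#: fixed column order of the serialized report; every numeric column name
#: carries its unit so a report file is self-describing
REPORT_COLUMNS: list[str] = [
    "leaf_id",
    "species",
    "leaf_area_m2",
    "psi_initial_MPa",
    "psi_final_MPa",
    "T_leaf_C",
    "PARa_umol_m2_s",
    "T_air_C",
    "airflow_m_s",
    "sampling_time",
    "storage",
    "degassed",
    "height_offset_cm",
    "E_mmol_m2_s",
    "K_leaf_mmol_m2_s_MPa",
    "K_leaf_25C_mmol_m2_s_MPa",
    "viscosity_factor",
    "curve_class",
    "last_segment_duration_s",
    "slope_p_value",
    "flow_trace_uri",
    "notes",
]


def record_to_row(rec: ReportRecord) -> dict:
    """Flatten a validated ReportRecord into a report-table row dict."""
    rec.validate()
    leaf = rec.leaf
    return {
        "leaf_id": rec.leaf_id,
        "species": leaf.species,
        "leaf_area_m2": leaf.leaf_area_m2,
        "psi_initial_MPa": leaf.psi_initial_MPa,
        "psi_final_MPa": leaf.psi_final_MPa,
        "T_leaf_C": leaf.T_leaf_C,
        "PARa_umol_m2_s": leaf.PARa_umol_m2_s,
        "T_air_C": leaf.T_air_C,
        "airflow_m_s": leaf.airflow_m_s,
        "sampling_time": leaf.sampling_time,
        "storage": leaf.storage,
        "degassed": leaf.degassed,
        "height_offset_cm": leaf.height_offset_cm,
        "E_mmol_m2_s": rec.E_mmol_m2_s,
        "K_leaf_mmol_m2_s_MPa": rec.K_leaf_raw,
        "K_leaf_25C_mmol_m2_s_MPa": rec.K_leaf_25C,
        "viscosity_factor": rec.viscosity_factor,
        "curve_class": rec.curve_class,
        "last_segment_duration_s": rec.last_segment_duration_s,
        "slope_p_value": rec.slope_p_value,
        "flow_trace_uri": rec.flow_trace_uri,
        "notes": rec.notes,
    }


def leaf_record_fields() -> list[str]:
    """Names of the LeafRecord metadata fields (for CSV readers)."""
    return [f.name for f in fields(LeafRecord)]
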