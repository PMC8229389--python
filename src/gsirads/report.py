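"""Standard per-patient report rendering (text + CSV).

The report lists every extracted feature exactly once, in fixed section
order: volumes, laterality, focality, resectability, cortical overlap,
subcortical overlap.  Undefined values are serialized as the explicit
sentinel string ``"undefined"``, never omitted, so reports for empty
masks keep the full schema.  Formatting: volumes 2 decimals (mL),
indices 3 decimals, percentages 2 decimals.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass

from .features import FeatureReport

UNDEFINED = "undefined"


def _fmt(value, kind: str) -> str:
    if value is None:
        return UNDEFINED
    if isinstance(value, float) and math.isnan(value):
        return UNDEFINED
    if kind == "volume":
        return f"{value:.2f}"
    if kind == "index":
        return f"{value:.3f}"
    if kind == "percent":
        return f"{value:.2f}"
    if kind == "bool":
        return "yes" if value else "no"
    if kind == "int":
        return str(int(value))
    return str(value)


@dataclass
class RenderedReport:
    """Text report plus its long-format CSV rows (feature, value, unit)."""

    patient_id: str
    text: str
    rows: list[dict[str, str]]

    def csv_text(self) -> str:
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=["feature", "value", "unit"])
        writer.writeheader()
        writer.writerows(self.rows)
        return buf.getvalue()


def render_report(report: FeatureReport, patient_id: str, version: str = "") -> RenderedReport:
    """Serialize a :class:`FeatureReport` as a fixed-layout text document
    and matching CSV rows.  Text and CSV always carry identical values."""
    rows: list[dict[str, str]] = []
    lines: list[str] = []

    def emit(feature: str, value, kind: str, unit: str, label: str) -> None:
        s = _fmt(value, kind)
        rows.append({"feature": feature, "value": s, "unit": unit})
        suffix = f" {unit}" if unit and s != UNDEFINED else ""
        lines.append(f"  {label}: {s}{suffix}")

    lines.append(f"Standard tumor feature report — patient {patient_id}")
    if version:
        lines.append(f"(generator version {version})")
    lines.append("")

    lines.append("Volumes")
    emit("native_volume_ml", report.native_volume_ml, "volume", "mL", "native tumor volume")
    emit(
        "normalized_volume_ml",
        report.normalized_volume_ml,
        "volume",
        "mL",
        "normalized tumor volume",
    )
    emit("left_volume_ml", report.left_volume_ml, "volume", "mL", "left hemisphere volume")
    emit("right_volume_ml", report.right_volume_ml, "volume", "mL", "right hemisphere volume")
    lines.append("")

    lines.append("Laterality")
    emit("laterality", report.laterality, "str", "", "laterality")
    emit("laterality_index", report.laterality_index, "index", "", "laterality index")
    emit(
        "contralateral_infiltration",
        report.contralateral_infiltration,
        "bool",
        "",
        "contralateral infiltration",
    )
    lines.append("")

    lines.append("Focality")
    emit("multifocal", report.multifocal, "bool", "", "multifocal")
    emit("n_foci", report.n_foci, "int", "", "number of foci")
    lines.append("")

    lines.append("Resectability")
    emit(
        "expected_resectable_volume_ml",
        report.expected_resectable_volume_ml,
        "volume",
        "mL",
        "expected resectable volume",
    )
    emit(
        "expected_residual_volume_ml",
        report.expected_residual_volume_ml,
        "volume",
        "mL",
        "expected residual tumor volume",
    )
    emit(
        "resectability_index",
        report.resectability_index,
        "index",
        "",
        "expected resectability index",
    )
    lines.append("")

    lines.append("Cortical overlap (% of tumor volume)")
    for name in sorted(report.cortical_overlap or {}):
        emit(
            f"cortical_overlap.{name}",
            report.cortical_overlap[name],  # type: ignore[index]
            "percent",
            "%",
            name,
        )
    if report.cortical_overlap is None:
        emit("cortical_overlap", None, "percent", "%", "all parcels")
    lines.append("")

    lines.append("Subcortical overlap (% of tumor volume)")
    for name in sorted(report.subcortical_overlap or {}):
        emit(
            f"subcortical_overlap.{name}",
            report.subcortical_overlap[name],  # type: ignore[index]
            "percent",
            "%",
            name,
        )
    if report.subcortical_overlap is None:
        emit("subcortical_overlap", None, "percent", "%", "all tracts")
    lines.append("")

    return RenderedReport(patient_id=patient_id, text="\n".join(lines), rows=rows)
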