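"""Replicate aggregation, percent-of-reference normalisation and report bundles.

Monolayer parameters measured at several temperatures are commonly rescaled
to the value at a reference temperature (here 20 C = 100%) so that the
low- and high-temperature responses of different film compositions can be
compared on one axis.  This module provides the mean +/- SE summary used for
replicate measurements, the percent normalisation, and a small deterministic
report bundle (one JSON document plus per-section CSV tables).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, KeyingError, ParameterError, ValidationError

__all__ = [
    "FEATURE_PARAMETERS",
    "replicate_summary",
    "feature_table",
    "percent_of_reference",
    "build_report",
    "emit_report",
    "parse_report",
]

FEATURE_PARAMETERS = ("A_lim", "pi_coll", "pi_plateau", "cs_inv_max")
_FEATURE_COLUMNS = ["system", "temperature_C", "parameter", "value", "se", "n"]
_SECTION_ORDER = ("features", "percents", "excess", "order", "zeta")


def replicate_summary(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, standard error and count of replicate values.

    SE is the sample standard deviation over sqrt(n); by convention 0 when
    n = 1.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("empty replicate list")
    n = int(arr.size)
    mean = float(arr.mean())
    if n == 1 or np.ptp(arr) == 0.0:  # identical replicates: exactly zero scatter
        return mean, 0.0, n
    return mean, float(np.std(arr, ddof=1) / math.sqrt(n)), n


def feature_table(
    rows: Sequence[tuple[str, float, str, float, float, int]]
) -> pd.DataFrame:
    """Build a long-format feature table from (system, T, parameter, value, se, n) rows.

    Keys (system, temperature, parameter) must be unique and n >= 1.
    """
    frame = pd.DataFrame(list(rows), columns=_FEATURE_COLUMNS)
    if frame.empty:
        raise ValidationError("feature table must have at least one row")
    if (frame["n"] < 1).any():
        raise ValidationError("replicate counts must be >= 1")
    keys = frame[["system", "temperature_C", "parameter"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate key (system={dup.system!r}, T={dup.temperature_C}, "
            f"parameter={dup.parameter!r})"
        )
    return frame


def percent_of_reference(
    table: pd.DataFrame, reference_temperature: float = 20.0
) -> pd.DataFrame:
    """Rescale each (system, parameter) series to its reference-temperature value.

    percent = 100 * value(T) / value(T_ref); reference rows are exactly 100.
    Accepts either a raw feature table (column ``value``) or an already
    normalised table (column ``percent``), which makes the operation
    idempotent.  Negative inputs are refused rather than silently normalised,
    and a missing or zero reference raises a descriptive error.
    """
    value_col = "value" if "value" in table.columns else "percent"
    if value_col not in table.columns:
        raise ValidationError("table has neither a 'value' nor a 'percent' column")
    frame = table.copy()
    if (frame[value_col] < 0).any():
        raise ValidationError("negative parameter values are not supported")
    out_rows = []
    for (system, parameter), group in frame.groupby(["system", "parameter"], sort=False):
        is_ref = np.isclose(group["temperature_C"].to_numpy(), reference_temperature)
        if not is_ref.any():
            raise KeyingError(
                f"no reference row at T = {reference_temperature} C for "
                f"system {system!r}, parameter {parameter!r}"
            )
        ref_value = float(group.loc[is_ref, value_col].iloc[0])
        if ref_value == 0.0:
            raise DomainError(
                f"zero reference value for system {system!r}, parameter {parameter!r}"
            )
        for (_, row), ref in zip(group.iterrows(), is_ref):
            out_rows.append(
                {
                    "system": system,
                    "temperature_C": row["temperature_C"],
                    "parameter": parameter,
                    "percent": 100.0 if ref else 100.0 * row[value_col] / ref_value,
                }
            )
    return pd.DataFrame(out_rows)


def _to_records(section) -> list[dict]:
    if isinstance(section, pd.DataFrame):
        records = section.to_dict(orient="records")
    elif isinstance(section, list):
        records = [r if isinstance(r, dict) else _as_dict(r) for r in section]
    elif isinstance(section, dict):
        records = [section]
    else:
        records = [_as_dict(section)]
    return [_jsonable(r) for r in records]


def _as_dict(obj) -> dict:
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses

        return dataclasses.asdict(obj)
    raise ParameterError(f"cannot serialise section entry of type {type(obj).__name__}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def build_report(
    features=None,
    percents=None,
    excess=None,
    order=None,
    zeta=None,
    format: str = "json",
) -> dict:
    """Assemble analysis sections into one machine-readable report.

    Sections may be DataFrames, lists of dataclasses, or dicts; at least one
    must be present.  Section and key ordering is deterministic.
    """
    if format not in ("json", "json+csv"):
        raise ParameterError(f"unknown report format {format!r}")
    sections = {
        "features": features,
        "percents": percents,
        "excess": excess,
        "order": order,
        "zeta": zeta,
    }
    present = {k: v for k, v in sections.items() if v is not None}
    if not present:
        raise ValidationError("report needs at least one section")
    report = {"format": format, "sections": {}}
    for name in _SECTION_ORDER:
        if name in present:
            report["sections"][name] = _to_records(present[name])
    return report


def emit_report(report: dict, out_dir) -> Path:
    """Write ``report.json`` plus one CSV per section; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for name, records in report["sections"].items():
        if records:
            pd.DataFrame(records).to_csv(out / f"{name}.csv", index=False)
    return json_path


def parse_report(path) -> dict:
    return json.loads(Path(path).read_text())
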