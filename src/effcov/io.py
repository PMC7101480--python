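"""Delimited-text I/O for stratum tables and results.

Dialect is fixed: comma separator, "." decimal point, UTF-8, header row
required, empty field (not "NA") for inapplicable columns.  Floats are
written with ``repr`` so round trips preserve them bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .estimands import AggregationSpec, StratumSummary
from .interval import IntervalEstimate

__all__ = [
    "STRATUM_COLUMNS",
    "RESULT_COLUMNS",
    "read_stratum_table",
    "write_stratum_table",
    "write_results",
    "read_results",
]

STRATUM_COLUMNS = [
    "region_id", "facility_type", "x_successes", "n_x", "readiness_kind",
    "y_successes", "n_y", "y_mean", "y_var", "region_weight",
]

RESULT_COLUMNS = [
    "level", "region_id", "facility_type", "method",
    "point", "variance", "lower", "upper", "status",
]

_LEVEL_ORDER = {"stratum": 0, "region": 1, "national": 2}


class StratumTableError(ValueError):
    """A stratum table failed validation; the message names the line."""


def _req_int(row: dict, col: str, line: int) -> int:
    raw = (row.get(col) or "").strip()
    if not raw:
        raise StratumTableError(f"line {line}: missing required column {col!r}")
    try:
        return int(raw)
    except ValueError:
        raise StratumTableError(
            f"line {line}: column {col!r} must be an integer, got {raw!r}"
        ) from None


def _req_float(row: dict, col: str, line: int) -> float:
    raw = (row.get(col) or "").strip()
    if not raw:
        raise StratumTableError(f"line {line}: missing required column {col!r}")
    try:
        return float(raw)
    except ValueError:
        raise StratumTableError(
            f"line {line}: column {col!r} must be a number, got {raw!r}"
        ) from None


def read_stratum_table(path: str | Path) -> AggregationSpec:
    """Parse and validate a stratum-summary table into an AggregationSpec.

    Binary rows use y_successes/n_y and leave y_mean/y_var empty; continuous
    rows the reverse.  Region weights may repeat across a region's rows and
    need not be normalized.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise StratumTableError(f"{path}: empty file (no header)")
        missing = set(STRATUM_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise StratumTableError(
                f"{path}: missing columns {sorted(missing)}"
            )
        strata: list[StratumSummary] = []
        weights: dict[str, float] = {}
        for line, row in enumerate(reader, start=2):
            region = (row["region_id"] or "").strip()
            ftype = (row["facility_type"] or "").strip()
            if not region or not ftype:
                raise StratumTableError(
                    f"line {line}: region_id and facility_type are required"
                )
            kind = (row["readiness_kind"] or "").strip()
            kwargs = dict(
                region_id=region,
                facility_type=ftype,
                x_successes=_req_int(row, "x_successes", line),
                n_x=_req_int(row, "n_x", line),
                readiness_kind=kind,
                n_y=_req_int(row, "n_y", line),
            )
            if kind == "binary":
                kwargs["y_successes"] = _req_int(row, "y_successes", line)
            elif kind == "continuous":
                kwargs["y_mean"] = _req_float(row, "y_mean", line)
                kwargs["y_var"] = _req_float(row, "y_var", line)
            else:
                raise StratumTableError(
                    f"line {line}: unknown readiness_kind {kind!r} "
                    "(expected 'binary' or 'continuous')"
                )
            try:
                stratum = StratumSummary(**kwargs)
            except ValueError as exc:
                raise StratumTableError(f"line {line}: {exc}") from None
            w = _req_float(row, "region_weight", line)
            prev = weights.get(region)
            if prev is not None and abs(prev - w) > 1e-12:
                raise StratumTableError(
                    f"line {line}: region {region!r} has conflicting weights "
                    f"{prev!r} and {w!r}"
                )
            weights[region] = w
            strata.append(stratum)
    if not strata:
        raise StratumTableError(f"{path}: no data rows")
    try:
        return AggregationSpec(region_weights=weights, strata=strata)
    except ValueError as exc:
        raise StratumTableError(f"{path}: {exc}") from None


def write_stratum_table(spec: AggregationSpec, path: str | Path) -> None:
    """Write an AggregationSpec back to the delimited stratum-table schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STRATUM_COLUMNS)
        for s in spec.strata:
            binary = s.readiness_kind == "binary"
            writer.writerow(
                [
                    s.region_id,
                    s.facility_type,
                    s.x_successes,
                    s.n_x,
                    s.readiness_kind,
                    s.y_successes if binary else "",
                    s.n_y,
                    "" if binary else repr(s.y_mean),
                    "" if binary else repr(s.y_var),
                    repr(spec.region_weights[s.region_id]),
                ]
            )


def write_results(estimates: list[IntervalEstimate], path: str | Path) -> None:
    """Write interval estimates as a delimited table, full float precision.

    Rows are ordered deterministically by (level, region, facility_type,
    method); status is serialized as its literal string.
    """
    if not estimates:
        raise ValueError("no estimates to write")
    path = Path(path)
    ordered = sorted(
        estimates,
        key=lambda e: (
            _LEVEL_ORDER.get(e.level, 99),
            e.region_id or "",
            e.facility_type or "",
            e.method,
        ),
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for e in ordered:
            writer.writerow(
                [
                    e.level,
                    e.region_id or "",
                    e.facility_type or "",
                    e.method,
                    repr(e.point),
                    repr(e.variance),
                    repr(e.lower),
                    repr(e.upper),
                    e.status.value,
                ]
            )


def read_results(path: str | Path) -> pd.DataFrame:
    """Results table as a DataFrame (floats parsed at full precision)."""
    return pd.read_csv(
        path, keep_default_na=False, na_values=["nan"],
        float_precision="round_trip",
    )
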