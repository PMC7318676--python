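"""File formats: constants tables (CSV), reaction configs (YAML), results.

All text formats are plain UTF-8; CSV is comma-separated with dot decimals
and a required header. Floats in result files are written with 6 significant
digits so that repeated writes are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core import PhosphorolysisEntry, TransglycosylationSystem, YieldPrediction
from .errors import DomainError, ParseError

__all__ = [
    "read_constants_table",
    "read_reaction_config",
    "write_results",
    "CONSTANTS_COLUMNS",
]

logger = logging.getLogger("transglyc")

CONSTANTS_COLUMNS = ("species_id", "K", "temperature_C", "pH", "source")

_CONFIG_REQUIRED = ("K1", "K2", "N1_0_mM", "B2_0_mM", "P_0_mM")
_CONFIG_OPTIONAL = ("B1_0_mM", "N2_0_mM", "P1P_0_mM")


def read_constants_table(path: str | PathLike) -> list[PhosphorolysisEntry]:
    """Read a CSV table of apparent phosphorolysis constants.

    Expected header: ``species_id,K,temperature_C,pH,source``. Row numbers
    in error messages count the header as row 1. Duplicate
    (species_id, temperature_C, pH) combinations are rejected: the apparent
    constant is unique per species and condition.
    """
    try:
        frame = pd.read_csv(path, dtype={"species_id": str, "source": str})
    except Exception as exc:
        raise ParseError(f"cannot read constants table {path}: {exc}") from exc
    missing = [c for c in CONSTANTS_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"constants table {path} missing columns: {missing}")

    entries: list[PhosphorolysisEntry] = []
    for idx, row in frame.iterrows():
        rowno = idx + 2  # header is row 1
        try:
            entries.append(
                PhosphorolysisEntry(
                    species_id=str(row["species_id"]),
                    K=float(row["K"]),
                    temperature_C=float(row["temperature_C"]),
                    pH=float(row["pH"]),
                    source="" if pd.isna(row["source"]) else str(row["source"]),
                )
            )
        except (DomainError, ValueError) as exc:
            raise ParseError(f"constants table {path}, row {rowno}: {exc}") from exc

    keys = frame[["species_id", "temperature_C", "pH"]]
    dup_mask = keys.duplicated(keep=False)
    if dup_mask.any():
        dups = sorted(
            set(map(tuple, keys[dup_mask].itertuples(index=False, name=None)))
        )
        raise ParseError(
            f"constants table {path} has duplicate (species_id, temperature_C, pH) "
            f"entries: {dups}"
        )
    return entries


def read_reaction_config(path: str | PathLike) -> TransglycosylationSystem:
    """Read a YAML reaction configuration into a system.

    Required keys: ``K1``, ``K2``, ``N1_0_mM``, ``B2_0_mM``, ``P_0_mM``.
    Optional (default 0): ``B1_0_mM``, ``N2_0_mM``, ``P1P_0_mM``. Unknown
    keys are logged as warnings, not rejected, so configs may carry
    free-form annotations (enzyme, buffer, ...).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"config {path} must be a key-value mapping")
    for key in _CONFIG_REQUIRED:
        if key not in raw:
            raise ParseError(f"config {path}: missing {key}")
    known = set(_CONFIG_REQUIRED) | set(_CONFIG_OPTIONAL)
    for key in sorted(set(raw) - known):
        logger.warning("config %s: ignoring unknown key %r", path, key)
    try:
        return TransglycosylationSystem(
            K1=float(raw["K1"]),
            K2=float(raw["K2"]),
            N1_0=float(raw["N1_0_mM"]),
            B2_0=float(raw["B2_0_mM"]),
            P_0=float(raw["P_0_mM"]),
            B1_0=float(raw.get("B1_0_mM", 0.0)),
            N2_0=float(raw.get("N2_0_mM", 0.0)),
            P1P_0=float(raw.get("P1P_0_mM", 0.0)),
        )
    except (DomainError, ValueError) as exc:
        raise ParseError(f"config {path}: {exc}") from exc


def _fmt(value: float) -> str:
    if isinstance(value, float) and math.isnan(value):
        return ""
    return f"{value:.6g}"


def _prediction_rows(predictions: Iterable[YieldPrediction]) -> tuple[list[str], list[dict]]:
    """Flatten predictions into records; inputs first, ideal, then per-equiv yields."""
    preds = list(predictions)
    equiv_cols: list[float] = []
    for p in preds:
        for eq, _ in p.yields_at_phosphate:
            if eq not in equiv_cols:
                equiv_cols.append(eq)
    columns = ["K1", "K2", "N1_0_mM", "B2_0_mM", "ideal_yield"] + [
        f"yield_at_{_fmt(eq)}equiv" for eq in equiv_cols
    ]
    rows = []
    for p in preds:
        s = p.settings
        row = {
            "K1": s.K1,
            "K2": s.K2,
            "N1_0_mM": s.N1_0,
            "B2_0_mM": s.B2_0,
            "ideal_yield": p.ideal_yield,
        }
        for eq, y in p.yields_at_phosphate:
            row[f"yield_at_{_fmt(eq)}equiv"] = y
        rows.append(row)
    return columns, rows


def write_results(
    records: Sequence[YieldPrediction] | pd.DataFrame,
    path: str | PathLike,
    format: str = "csv",
) -> None:
    """Write predictions (or any long-format table) to CSV or JSON.

    Column order is deterministic — reaction inputs first, then the ideal
    yield, then one column per phosphate loading — and floats carry 6
    significant digits, so writing the same records twice produces
    byte-identical files. The JSON output mirrors the CSV fields as a list
    of objects.
    """
    fmt = format.lower()
    if fmt not in ("csv", "json"):
        raise DomainError(f"format must be 'csv' or 'json', got {format!r}")

    if isinstance(records, pd.DataFrame):
        columns = list(records.columns)
        rows = records.to_dict(orient="records")
    else:
        columns, rows = _prediction_rows(records)

    if fmt == "csv":
        lines = [",".join(columns)]
        for row in rows:
            lines.append(
                ",".join(
                    _fmt(v) if isinstance(v, float) else str(v)
                    for v in (row.get(c, math.nan) for c in columns)
                )
            )
        text = "\n".join(lines) + "\n"
    else:
        payload = [
            {
                c: (float(_fmt(v)) if isinstance(v, float) and not math.isnan(v)
                    else None if isinstance(v, float) else v)
                for c, v in ((c, row.get(c, math.nan)) for c in columns)
            }
            for row in rows
        ]
        text = json.dumps(payload, indent=2, sort_keys=False) + "\n"
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
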