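"""Reading and writing quotient tables and results.

Quotients are stored internally as absolute dimensionless fractions
everywhere; the conventional x1e-3 display convention enters only through
the explicit ``scale`` argument at the I/O boundary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .reibergram import ClassificationResult, PatientRecord

__all__ = ["ValidationError", "read_quotient_table", "write_classification", "write_fit_results"]

_QUOTIENT_COLS = ("q_alb", "q_igg", "q_iga", "q_igm")


class ValidationError(ValueError):
    """Collected row-level validation failures of an input table."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def read_quotient_table(
    path: str | Path, scale: float = 1.0, sep: Optional[str] = None
) -> list[PatientRecord]:
    """Read a CSV/TSV of patient quotients into validated records.

    Expected header: ``id,q_alb[,q_igg,q_iga,q_igm]``.  The delimiter is
    sniffed unless ``sep`` is given.  Quotient columns are multiplied by
    ``scale`` (use 1e-3 for tables in the conventional x1e-3 display
    units).  All row-level problems are collected and raised together.
    """
    if scale not in (1, 1.0, 1e-3):
        raise ValueError("scale must be 1 or 1e-3")
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    errors: list[str] = []
    if "id" not in df.columns or "q_alb" not in df.columns:
        raise ValidationError([f"{path}: required columns 'id' and 'q_alb' missing"])
    dupes = df["id"].astype(str)[df["id"].astype(str).duplicated()].unique()
    if len(dupes):
        errors.append(f"duplicate ids: {', '.join(map(str, dupes))}")
    records: list[PatientRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        row_ok = True
        for col in _QUOTIENT_COLS:
            raw = getattr(row, col, None)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                vals[col] = None
                continue
            try:
                vals[col] = float(raw) * scale
            except (TypeError, ValueError):
                errors.append(f"row {row_no}: malformed numeric {col}={raw!r}")
                row_ok = False
        if vals.get("q_alb") is None:
            errors.append(f"row {row_no}: missing q_alb")
            row_ok = False
        if not row_ok:
            continue
        try:
            records.append(
                PatientRecord(
                    id=str(row.id),
                    q_alb=vals["q_alb"],
                    q_igg=vals["q_igg"],
                    q_iga=vals["q_iga"],
                    q_igm=vals["q_igm"],
                )
            )
        except ValueError as exc:
            errors.append(f"row {row_no}: {exc}")
    if errors:
        raise ValidationError(errors)
    return records


def write_classification(
    results: Sequence[ClassificationResult], path: str | Path
) -> pd.DataFrame:
    """Write classification results as CSV with a deterministic column order.

    An empty result list still produces a header-only file.
    """
    cols = [
        "id", "analyte", "band", "observed_q", "limit_q_upper",
        "limit_q_lower", "mean_q", "ratio_to_mean", "out_of_calibrated_range",
    ]
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "analyte": r.analyte,
                "band": r.band.value,
                "observed_q": r.observed_q,
                "limit_q_upper": r.limit_q_upper,
                "limit_q_lower": r.limit_q_lower,
                "mean_q": r.mean_q,
                "ratio_to_mean": r.ratio_to_mean,
                "out_of_calibrated_range": r.out_of_calibrated_range,
            }
            for r in results
        ],
        columns=cols,
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def write_fit_results(results, path: str | Path) -> None:
    """Write one or more fit results as JSON (with diagnostics)."""
    if not isinstance(results, (list, tuple)):
        results = [results]
    payload = [r.to_dict() for r in results]
    Path(path).write_text(json.dumps(payload, indent=2))
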