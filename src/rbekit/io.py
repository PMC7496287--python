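"""Reading and writing of clonogenic-assay tables and tidy result tables.

The survival-table CSV schema is rectangular and lower_snake_case:
``cell_line, radiation, let_d, depth_mm, dose, cells_seeded, colonies,
session, well``.  X-ray records carry ``radiation=xray_200kV`` with
``let_d = 0`` rather than a missing value.  Strict mode additionally
enforces the study's dose grid {0, 0.5, 1, 2, 4, 6} Gy.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Radiation, SurvivalRecord, ValidationError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "cell_line",
    "radiation",
    "let_d",
    "dose",
    "cells_seeded",
    "colonies",
    "session",
)
OPTIONAL_COLUMNS = ("depth_mm", "well")

STRICT_DOSE_GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)


class SchemaError(ValidationError):
    """Raised when a table lacks required columns."""


def read_survival_table(
    path: str | Path, strict: bool = False
) -> list[SurvivalRecord]:
    """Read and validate a survival CSV into SurvivalRecord objects.

    Every malformed row is reported with its file line number; the read
    fails after collecting all offending rows rather than at the first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            radiation = Radiation(str(row.radiation))
            dose = float(row.dose)
            if strict and dose not in STRICT_DOSE_GRID:
                raise ValidationError(
                    f"dose {dose} Gy outside the strict dose grid"
                )
            depth = getattr(row, "depth_mm", None)
            depth = None if depth is None or pd.isna(depth) else float(depth)
            records.append(
                SurvivalRecord(
                    cell_line=str(row.cell_line),
                    radiation=radiation,
                    let_d=float(row.let_d),
                    depth_mm=depth,
                    dose=dose,
                    cells_seeded=int(row.cells_seeded),
                    colonies=int(row.colonies),
                    session=str(row.session),
                    well=str(getattr(row, "well", "")),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )
    log.info("read %d survival records from %s", len(records), path)
    return records


def write_survival_table(
    records: Iterable[SurvivalRecord], path: str | Path
) -> Path:
    """Write SurvivalRecord objects to the canonical CSV schema."""
    from .lq import records_to_frame

    path = Path(path)
    frame = records_to_frame(records)
    cols = [*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS]
    frame[cols].to_csv(path, index=False)
    return path


def write_results(
    results: pd.DataFrame, path: str | Path, format: str | None = None
) -> Path:
    """Write a tidy result table as CSV or JSON (re-readable round trip).

    JSON preserves numeric values to full double precision; CSV uses the
    '.' decimal separator and 12 significant digits.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "csv").lower()
    if fmt == "csv":
        results.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        payload = results.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1, default=_json_default))
    else:
        raise ValidationError(f"unknown result format {fmt!r}")
    log.info("wrote %d result rows to %s", len(results), path)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


LQ_TABLE_COLUMNS = ("cell_line", "radiation", "let_d", "alpha", "beta")


def read_lq_table(path: str | Path) -> pd.DataFrame:
    """Read a parameters-only LQ table (printed-table style CSV).

    Required columns: ``cell_line, radiation, let_d, alpha, beta``;
    optional: ``alpha_over_beta`` (published rounded ratio), standard
    errors and covariance.  Used by the parameters-only pipeline entry
    point, which reproduces model predictions without raw colony counts.
    """
    df = pd.read_csv(path)
    missing = [c for c in LQ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bad = df[(df["alpha"] < 0) | (df["beta"] < 0)]
    if len(bad):
        raise ValidationError(f"{path}: negative LQ parameters in rows {bad.index.tolist()}")
    return df


def study_lq_frame() -> pd.DataFrame:
    """The built-in published LQ parameter table as a tidy frame.

    One x-ray row and six proton rows per cell line, with the published
    rounded (α/β)_x carried in ``alpha_over_beta`` for the x-ray rows.
    """
    from . import study

    rows = []
    for cell in study.CELL_LINES:
        xq = study.XRAY_LQ[cell]
        rows.append(
            dict(
                cell_line=cell,
                radiation=Radiation.XRAY_200KV.value,
                let_d=0.0,
                alpha=xq.alpha,
                beta=xq.beta,
                se_alpha=xq.se_alpha,
                se_beta=xq.se_beta,
                alpha_over_beta=study.ALPHA_BETA_X[cell],
            )
        )
        for let, (a, b) in sorted(study.PROTON_LQ[cell].items()):
            rows.append(
                dict(
                    cell_line=cell,
                    radiation=Radiation.PROTON.value,
                    let_d=let,
                    alpha=a,
                    beta=b,
                    se_alpha=np.nan,
                    se_beta=np.nan,
                    alpha_over_beta=a / b,
                )
            )
    return pd.DataFrame(rows)
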