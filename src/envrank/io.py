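"""CSV reading/writing of feature tables.

The on-disk layout is fixed: a comma-separated UTF-8 file with a header
row, an ISO-8601 ``date`` column first, then numeric feature columns, then
integer target columns.  Ambiguity is refused rather than sniffed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = ["read_feature_table", "write_feature_table"]


def read_feature_table(
    path: str | Path,
    date_column: str = "date",
    target_columns: list[str] | None = None,
) -> FeatureTable:
    """Load and validate a feature table from CSV.

    Columns not named in ``target_columns`` (default: the standard admission
    columns ``CVD``/``RD`` when present) are features.  Missing values,
    non-daily or duplicated dates and non-numeric features are rejected with
    the offending cell or column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    frame = pd.read_csv(path)
    if date_column not in frame.columns:
        raise ValueError(f"date column {date_column!r} not found in {path.name}")
    if target_columns is None:
        target_columns = [c for c in ("CVD", "RD") if c in frame.columns]
    missing = [c for c in target_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"target columns not found: {missing}")
    if not target_columns:
        raise ValueError("no target columns given and none of CVD/RD present")

    na = frame.isna()
    if na.to_numpy().any():
        cells = [
            (int(i), str(c))
            for c in frame.columns
            for i in frame.index[na[c]][:3]
        ]
        raise ValueError(f"missing values at (row, column): {cells[:10]}")

    try:
        dates = pd.to_datetime(frame[date_column], format="%Y-%m-%d")
    except ValueError as exc:
        raise ValueError(f"dates must be ISO-8601 (YYYY-MM-DD): {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"duplicated date {dup.date()}")

    feature_cols = [c for c in frame.columns if c != date_column and c not in target_columns]
    features = frame[feature_cols]
    for col in feature_cols:
        if not pd.api.types.is_numeric_dtype(features[col]):
            raise ValueError(f"feature column {col!r} is not numeric")
    targets = frame[target_columns]
    return FeatureTable(pd.DatetimeIndex(dates), features.copy(), targets.copy())


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write the standard CSV layout (date, features, targets)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.to_frame()
    for col in table.targets.columns:
        vals = table.targets[col].to_numpy()
        if np.allclose(vals, np.round(vals)):
            out[col] = np.round(vals).astype(int)
    out.to_csv(path, index=False)
    return path
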