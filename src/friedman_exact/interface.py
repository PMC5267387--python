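"""Reading delimited rank/score tables and serializing results.

The canonical in-memory orientation is blocks as rows and groups as
columns; files laid out the other way round are accepted via the
``orientation`` option.  Validation failures carry row/column diagnostics
and raise :class:`~friedman_exact.errors.ValidationError`.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .comparisons import ComparisonTable, RankMatrix, rank_transform
from .errors import ValidationError

__all__ = ["read_table", "comparison_to_tsv", "comparison_to_json"]


def read_table(
    path,
    delimiter: str | None = None,
    orientation: str = "blocks-rows",
    kind: str = "ranks",
    direction: str = "ascending",
    allow_missing: bool = False,
):
    """Read a delimited two-way layout into a RankMatrix (or raw DataFrame).

    Parameters
    ----------
    path : file path
        Delimited text; first row group labels, first column block labels
        (after optional transposition).
    delimiter : explicit field delimiter; sniffed from the extension when
        None (',' for .csv, tab otherwise).
    orientation : {"blocks-rows", "groups-rows"}
        Which axis the file's rows represent; the result always has blocks
        as rows.
    kind : {"ranks", "raw"}
        "ranks" validates rank rows as-is; "raw" rank-transforms the scores
        within each block (direction as in
        :func:`~friedman_exact.comparisons.rank_transform`).
    allow_missing : bool
        When True, missing cells are tolerated and a raw DataFrame with
        NaNs is returned (incomplete-design workflows); otherwise a missing
        cell is a validation error naming the cell.
    """
    path = Path(path)
    if orientation not in ("blocks-rows", "groups-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if kind not in ("ranks", "raw"):
        raise ValidationError(f"unknown data kind {kind!r}")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except Exception as err:
        raise ValidationError(f"cannot parse {path}: {err}") from err
    if orientation == "groups-rows":
        df = df.T
    if df.index.duplicated().any():
        raise ValidationError(
            f"duplicate block labels in {path}: "
            f"{sorted(set(df.index[df.index.duplicated()]))}"
        )
    if df.columns.duplicated().any():
        raise ValidationError(
            f"duplicate group labels in {path}: "
            f"{sorted(set(df.columns[df.columns.duplicated()]))}"
        )
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"non-numeric cell in {path}: {err}") from err
    nan = np.argwhere(values.isna().to_numpy())
    if len(nan) and not allow_missing:
        i, j = nan[0]
        raise ValidationError(
            f"missing cell at block {values.index[i]!r}, group "
            f"{values.columns[j]!r} in {path}; pass allow_missing=True for "
            "incomplete-design workflows"
        )
    if len(nan):
        return values
    if kind == "raw":
        return rank_transform(values, direction=direction)
    matrix = RankMatrix(
        ranks=values,
        has_ties=any(len(np.unique(row)) < len(row) for row in values.to_numpy()),
    )
    matrix.validate()
    return matrix


def _rational(p) -> str:
    if isinstance(p, Fraction):
        return f"{p.numerator}/{p.denominator}"
    return repr(float(p))


def comparison_to_tsv(result: ComparisonTable, digits: int = 4) -> str:
    """Human-readable TSV rendering with rounded p-values."""
    return result.to_frame(digits=digits).to_csv(sep="\t", index=False)


def comparison_to_json(result: ComparisonTable, digits: int = 4) -> str:
    """Machine-readable JSON; exact rationals kept as numerator/denominator."""
    rows = []
    for rec in result.table.to_dict(orient="records"):
        row = {}
        for key, value in rec.items():
            if key.startswith("p_"):
                row[key] = {
                    "value": round(float(value), digits),
                    "exact": _rational(value),
                }
            elif key == "significant":
                row[key] = bool(value)
            else:
                row[key] = value
        rows.append(row)
    payload = {
        "mode": result.mode,
        "alpha": result.alpha,
        "k": result.k,
        "n": result.n,
        "m_comparisons": result.m_comparisons,
        "control": result.control,
        "comparisons": rows,
    }
    return json.dumps(payload, indent=2)
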