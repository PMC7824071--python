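"""CSV ingestion and serialization of ratings tables.

Two layouts are supported: wide (one row per subject, one column per rater)
and long (``subject, rater, value`` columns).  Input must form a complete
subject x rater grid; missing cells are rejected with a listing of the
offending subjects rather than imputed or pairwise-deleted, because every
downstream statistic assumes the complete grid.  Lines starting with ``#``
are treated as metadata comments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RatingsMatrix

__all__ = ["TableLayout", "read_ratings", "write_ratings"]


@dataclass(frozen=True)
class TableLayout:
    """Column mapping for a ratings CSV."""

    layout: str = "wide"
    subject_col: str = "subject"
    rater_col: str = "rater"
    value_col: str = "value"

    def __post_init__(self) -> None:
        if self.layout not in ("wide", "long"):
            raise ValueError(f"layout must be 'wide' or 'long', got {self.layout!r}")
        if not self.subject_col or (
            self.layout == "long" and not (self.rater_col and self.value_col)
        ):
            raise ValueError("long layout requires subject, rater and value column names")


def _coerce_numeric(series: pd.Series, what: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric value {series.iloc[row]!r} in {what}, data row {row + 1}"
        )
    return numeric


def read_ratings(path, layout: TableLayout | str = "wide") -> RatingsMatrix:
    """Read a ratings CSV in wide or long layout into a :class:`RatingsMatrix`.

    Subject and rater order is normalised to first appearance in the file.
    Duplicate ``(subject, rater)`` pairs and incomplete subjects are
    rejected.
    """
    if isinstance(layout, str):
        layout = TableLayout(layout=layout)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    if layout.layout == "wide":
        return _from_wide(df, layout)
    return _from_long(df, layout)


def _from_wide(df: pd.DataFrame, layout: TableLayout) -> RatingsMatrix:
    subject_col = layout.subject_col if layout.subject_col in df.columns else df.columns[0]
    rater_cols = [c for c in df.columns if c != subject_col]
    if len(rater_cols) < 2:
        raise ValueError(f"wide input needs at least 2 rater columns, found {len(rater_cols)}")
    subjects = df[subject_col].astype(str)
    if subjects.duplicated().any():
        dupes = sorted(set(subjects[subjects.duplicated()]))
        raise ValueError(f"duplicated subjects in wide input: {dupes}")
    values = np.column_stack(
        [_coerce_numeric(df[c], f"column {c!r}") for c in rater_cols]
    )
    missing = np.isnan(values).any(axis=1)
    if missing.any():
        raise ValueError(
            "incomplete subjects (missing ratings): "
            f"{subjects[missing].tolist()}"
        )
    return RatingsMatrix(values, subject_ids=tuple(subjects), rater_ids=tuple(rater_cols))


def _from_long(df: pd.DataFrame, layout: TableLayout) -> RatingsMatrix:
    for col in (layout.subject_col, layout.rater_col, layout.value_col):
        if col not in df.columns:
            raise ValueError(f"long input is missing required column {col!r}")
    df = df.assign(
        **{
            layout.subject_col: df[layout.subject_col].astype(str),
            layout.rater_col: df[layout.rater_col].astype(str),
            layout.value_col: _coerce_numeric(df[layout.value_col],
                                              f"column {layout.value_col!r}"),
        }
    )
    dup = df.duplicated([layout.subject_col, layout.rater_col])
    if dup.any():
        pairs = df.loc[dup, [layout.subject_col, layout.rater_col]].values.tolist()
        raise ValueError(f"duplicated (subject, rater) pairs in long input: {pairs[:5]}")
    subjects = list(pd.unique(df[layout.subject_col]))
    raters = list(pd.unique(df[layout.rater_col]))
    wide = (
        df.pivot(index=layout.subject_col, columns=layout.rater_col, values=layout.value_col)
        .reindex(index=subjects, columns=raters)
    )
    missing = wide.isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"incomplete subjects (missing ratings): {wide.index[missing].tolist()}"
        )
    return RatingsMatrix(wide.to_numpy(), subject_ids=tuple(subjects), rater_ids=tuple(raters))


def write_ratings(
    ratings: RatingsMatrix,
    path,
    layout: TableLayout | str = "wide",
    metadata: str | None = None,
) -> None:
    """Write a ratings table as CSV; ``metadata`` becomes a ``#`` comment line."""
    if isinstance(layout, str):
        layout = TableLayout(layout=layout)
    df = ratings.to_frame().reset_index()
    df.columns = [layout.subject_col] + list(ratings.rater_ids)
    if layout.layout == "long":
        df = df.melt(id_vars=layout.subject_col, var_name=layout.rater_col,
                     value_name=layout.value_col)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if metadata:
            fh.write(f"# {metadata}\n")
        df.to_csv(fh, index=False)
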