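"""Questionnaire I/O, scoring, and depression-group classification.

Two instruments are built in:

* GSES — 10-item General Self-Efficacy Scale, items coded 1-4, total 10-40.
* PHQ-9 — 9-item depression questionnaire, items coded 0-3, total 0-27.
  Totals >= 10 denote clinically significant depressive symptoms, with
  severity bands 10-14 (moderate), 15-19 (moderate-severe), >= 20 (severe).

Input tables are delimited text with one row per participant, lowercase
item columns s1..s10 / d1..d9 (matched case-insensitively) and optional
age / gender / education covariates.  Validation is complete-case: any row
with a missing or out-of-range item response is dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDataError, ParameterError, SchemaError

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "gender", "education")
SEVERITY_ORDER = ["control", "moderate", "moderate-severe", "severe"]


@dataclass(frozen=True)
class ScaleDefinition:
    """An instrument: ordered item ids and their shared category range."""

    name: str
    item_ids: tuple[str, ...]
    item_range: tuple[int, int]

    @property
    def score_range(self) -> tuple[int, int]:
        p = len(self.item_ids)
        return (p * self.item_range[0], p * self.item_range[1])


GSES = ScaleDefinition("GSES", tuple(f"S{i}" for i in range(1, 11)), (1, 4))
PHQ9 = ScaleDefinition("PHQ9", tuple(f"D{i}" for i in range(1, 10)), (0, 3))
DEFAULT_SCHEMA = (GSES, PHQ9)


@dataclass
class ItemResponseMatrix:
    """Validated participants x items ordinal responses."""

    values: pd.DataFrame
    category_ranges: dict[str, tuple[int, int]]
    covariates: pd.DataFrame | None = None
    n_dropped: int = 0

    def __post_init__(self):
        ids = list(self.values.columns)
        if len(set(ids)) != len(ids):
            raise SchemaError("item ids must be unique")
        for item, (lo, hi) in self.category_ranges.items():
            col = self.values[item]
            if col.isna().any() or (col < lo).any() or (col > hi).any():
                raise SchemaError(f"item {item} has values outside [{lo}, {hi}]")

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return len(self.values)

    def values_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, item_ids) -> "ItemResponseMatrix":
        missing = [i for i in item_ids if i not in self.values.columns]
        if missing:
            raise SchemaError(f"items absent from matrix: {', '.join(missing)}")
        return ItemResponseMatrix(
            self.values[list(item_ids)].copy(),
            {i: self.category_ranges[i] for i in item_ids},
            covariates=self.covariates,
            n_dropped=self.n_dropped,
        )

    def rows(self, mask) -> "ItemResponseMatrix":
        cov = self.covariates
        return ItemResponseMatrix(
            self.values.loc[mask].reset_index(drop=True),
            dict(self.category_ranges),
            covariates=None if cov is None else cov.loc[mask].reset_index(drop=True),
            n_dropped=self.n_dropped,
        )


@dataclass
class GroupedSample:
    """Per-participant group labels, severity bands and scale totals."""

    group: pd.Series  # {"depressed", "control"}
    severity: pd.Series  # SEVERITY_ORDER categories
    phq9_total: pd.Series
    gses_total: pd.Series
    cutoff: int = 10

    def counts(self) -> dict:
        g = self.group.value_counts()
        s = self.severity.value_counts()
        return {
            "n": int(len(self.group)),
            "depressed": int(g.get("depressed", 0)),
            "control": int(g.get("control", 0)),
            "moderate": int(s.get("moderate", 0)),
            "moderate-severe": int(s.get("moderate-severe", 0)),
            "severe": int(s.get("severe", 0)),
        }


def _from_frame(
    frame: pd.DataFrame,
    schema=DEFAULT_SCHEMA,
    covariates=DEFAULT_COVARIATES,
) -> ItemResponseMatrix:
    colmap = {str(c).strip().lower(): c for c in frame.columns}
    wanted, ranges = [], {}
    for scale in schema:
        for item in scale.item_ids:
            key = item.lower()
            if key not in colmap:
                raise SchemaError(f"required column {item!r} missing")
            wanted.append(colmap[key])
            ranges[item] = scale.item_range
    items = frame[wanted].copy()
    items.columns = [i for scale in schema for i in scale.item_ids]
    items = items.apply(pd.to_numeric, errors="coerce")

    ok = pd.Series(True, index=items.index)
    for item, (lo, hi) in ranges.items():
        col = items[item]
        ok &= col.notna() & (col >= lo) & (col <= hi) & (col == col.round())
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d row(s) with missing/out-of-range item responses", n_dropped)
    items = items.loc[ok].astype(np.int64).reset_index(drop=True)
    if items.empty:
        raise EmptyDataError("no rows survived validation")

    cov = None
    cov_cols = [c for c in covariates if c.lower() in colmap]
    if cov_cols:
        cov = frame.loc[ok, [colmap[c.lower()] for c in cov_cols]].reset_index(drop=True)
        cov.columns = cov_cols
    return ItemResponseMatrix(items, ranges, covariates=cov, n_dropped=n_dropped)


def read_item_table(
    path,
    schema=DEFAULT_SCHEMA,
    covariates=DEFAULT_COVARIATES,
    delimiter: str | None = None,
) -> ItemResponseMatrix:
    """Read and validate a delimited item-response table.

    The delimiter is sniffed when not given.  Rows failing validation are
    dropped (complete-case) and counted in ``n_dropped``.
    """
    frame = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    return _from_frame(frame, schema=schema, covariates=covariates)


def from_frame(frame: pd.DataFrame, schema=DEFAULT_SCHEMA,
               covariates=DEFAULT_COVARIATES) -> ItemResponseMatrix:
    """Validate an in-memory table the same way ``read_item_table`` does."""
    return _from_frame(frame, schema=schema, covariates=covariates)


def write_item_table(matrix: ItemResponseMatrix, path) -> None:
    """Write items (+ covariates) as CSV in the package's input dialect."""
    out = matrix.values.copy()
    out.columns = [c.lower() for c in out.columns]
    if matrix.covariates is not None:
        for c in matrix.covariates.columns:
            out[c] = matrix.covariates[c].to_numpy()
    out.to_csv(path, index=False)


def score_scale(matrix: ItemResponseMatrix, scale: ScaleDefinition) -> pd.Series:
    """Total score = arithmetic sum of the scale's item codes."""
    missing = [i for i in scale.item_ids if i not in matrix.values.columns]
    if missing:
        raise SchemaError(f"scale {scale.name}: items missing: {', '.join(missing)}")
    total = matrix.values[list(scale.item_ids)].sum(axis=1)
    total.name = f"{scale.name.lower()}_total"
    return total


def classify_depression(totals: pd.Series, cutoff: int = 10) -> tuple[pd.Series, pd.Series]:
    """Group and severity labels from PHQ-9 totals.

    depressed iff total >= cutoff; severity bands 10-14 / 15-19 / >= 20
    (below cutoff -> 'control').
    """
    if not (0 <= cutoff <= 27):
        raise ParameterError("cutoff must lie in [0, 27]")
    totals = pd.Series(totals)
    if ((totals < 0) | (totals > 27)).any():
        raise ParameterError("PHQ-9 totals must lie in [0, 27]")
    group = pd.Series(np.where(totals >= cutoff, "depressed", "control"),
                      index=totals.index, name="group")
    severity = pd.Series(
        np.select(
            [totals >= 20, totals >= 15, totals >= cutoff],
            ["severe", "moderate-severe", "moderate"],
            default="control",
        ),
        index=totals.index, name="severity",
    )
    severity = severity.astype(pd.CategoricalDtype(SEVERITY_ORDER))
    return group, severity


def score_sample(matrix: ItemResponseMatrix, cutoff: int = 10) -> tuple[pd.DataFrame, GroupedSample]:
    """Scored table (items + covariates + totals + group labels)."""
    phq = score_scale(matrix, PHQ9)
    gses = score_scale(matrix, GSES)
    group, severity = classify_depression(phq, cutoff=cutoff)
    scored = matrix.values.copy()
    if matrix.covariates is not None:
        for c in matrix.covariates.columns:
            scored[c] = matrix.covariates[c].to_numpy()
    scored["phq9_total"] = phq
    scored["gses_total"] = gses
    scored["group"] = group
    scored["severity"] = severity
    return scored, GroupedSample(group, severity, phq, gses, cutoff=cutoff)
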