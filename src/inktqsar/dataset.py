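"""Ingestion and harmonisation of per-study cytokine measurements.

Raw responses come from heterogeneous studies (different units, doses,
incubation times).  Comparability is obtained by expressing every analogue
response as a ratio to the reference compound (α-GalCer) measured in the
same study at the same condition — units cancel, and the reference maps to
1.0 by construction.  Within a study, when several doses/times were used,
only the condition at which the reference response is maximal is retained.
Replicated (compound, test-system, marker) results from different studies
are then averaged on the ratio scale into one value per cell.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import (MARKERS, TEST_SYSTEMS, VocabularyError,
                    make_test_system, normalize_marker)

__all__ = [
    "RESPONSE_COLUMNS",
    "LITERATURE_ASSAY_COUNTS",
    "ResponseTableError",
    "RelativeResponseMatrix",
    "read_response_table",
    "select_reference_condition",
    "normalize_to_reference",
    "aggregate_replicates",
    "summarize_frequencies",
]

RESPONSE_COLUMNS = ("compound_id", "study_id", "species", "setting", "presentation",
                    "marker", "dose", "dose_unit", "time", "time_unit", "value")

#: Published per-assay result counts for the curated literature dataset of
#: α-GalCer analogues (851 aggregated results over 333 compounds): how often
#: each (test-model, marker) combination was used.  Packaged so frequency
#: summaries can be exercised and compared against the published shares.
LITERATURE_ASSAY_COUNTS: dict[tuple[str, str], int] = {
    ("mice/in-vivo", "IL-2"): 3,
    ("mice/in-vivo", "IFN-γ"): 120,
    ("mice/in-vivo", "IL-4"): 113,
    ("mice/in-vivo", "IL-13"): 1,
    ("mice/in-vitro/cell-cell", "IL-2"): 87,
    ("mice/in-vitro/cell-cell", "IFN-γ"): 77,
    ("mice/in-vitro/cell-cell", "IL-4"): 67,
    ("mice/in-vitro/cell-cell", "IL-13"): 13,
    ("mice/in-vitro/cell-plate", "IL-2"): 66,
    ("mice/in-vitro/cell-plate", "IFN-γ"): 1,
    ("mice/in-vitro/cell-plate", "IL-4"): 1,
    ("mice/in-vitro/cell-plate", "IL-13"): 1,
    ("human/in-vitro/cell-cell", "IL-2"): 19,
    ("human/in-vitro/cell-cell", "IFN-γ"): 121,
    ("human/in-vitro/cell-cell", "IL-4"): 96,
    ("human/in-vitro/cell-cell", "IL-13"): 56,
    ("human/in-vitro/cell-plate", "IL-2"): 5,
    ("human/in-vitro/cell-plate", "IFN-γ"): 2,
    ("human/in-vitro/cell-plate", "IL-4"): 1,
    ("human/in-vitro/cell-plate", "IL-13"): 1,
}


class ResponseTableError(ValueError):
    """Raised when response-table rows fail validation; lists line numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"invalid response rows — {lines}{more}")


@dataclass
class RelativeResponseMatrix:
    """Compound × (test-system, marker) mean normalized responses.

    ``values`` holds the across-study mean ratio to the reference (NaN where
    a cell was never measured); ``n_sources`` the replicate count behind
    each mean.  The reference compound is 1.0 in every measured cell.
    """

    values: pd.DataFrame
    n_sources: pd.DataFrame
    reference_id: str

    def cell(self, test_system: str, marker: str) -> pd.Series:
        return self.values[(test_system, marker)]

    def to_csv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{s}|{m}" for s, m in flat.columns]
        flat.to_csv(path, float_format="%.10g")


def read_response_table(source, dialect: dict | None = None) -> pd.DataFrame:
    """Read and validate a per-study response CSV.

    Expected header (order-free): ``compound_id, study_id, species, setting,
    presentation, marker, dose, dose_unit, time, time_unit, value``.  Marker
    and test-system vocabularies are normalised case-insensitively
    (``il4`` → ``IL-4``).  Rows with unknown vocabulary terms or non-numeric
    values are rejected collectively with their line numbers.
    """
    dialect = dialect or {}
    if isinstance(source, (str, Path)):
        raw = pd.read_csv(source, dtype=str, keep_default_na=False, **dialect)
    elif isinstance(source, io.IOBase):
        raw = pd.read_csv(source, dtype=str, keep_default_na=False, **dialect)
    else:  # already a frame (e.g. straight from the generator)
        raw = pd.DataFrame(source).copy()
        raw["marker"] = [normalize_marker(m) for m in raw["marker"]]
        raw["test_system"] = [make_test_system(sp, st, pr) for sp, st, pr in
                              zip(raw["species"], raw["setting"], raw["presentation"])]
        return raw[list(RESPONSE_COLUMNS[:5]) + ["test_system"]
                   + list(RESPONSE_COLUMNS[5:])].astype(
                       {"dose": float, "time": float, "value": float})

    missing = [c for c in RESPONSE_COLUMNS if c not in raw.columns]
    if missing:
        raise ResponseTableError([(1, f"missing columns {missing}")])

    problems: list[tuple[int, str]] = []
    markers, systems, doses, times, values = [], [], [], [], []
    for pos, row in enumerate(raw.itertuples(index=False)):
        line = pos + 2  # header is line 1
        ok = True
        try:
            markers.append(normalize_marker(row.marker))
        except VocabularyError as exc:
            problems.append((line, str(exc)))
            markers.append(None)
            ok = False
        try:
            systems.append(make_test_system(row.species, row.setting, row.presentation))
        except VocabularyError as exc:
            problems.append((line, str(exc)))
            systems.append(None)
            ok = False
        for col, store in (("dose", doses), ("time", times), ("value", values)):
            cell = getattr(row, col)
            try:
                store.append(float(cell))
            except (TypeError, ValueError):
                problems.append((line, f"non-numeric {col} {cell!r}"))
                store.append(np.nan)
                ok = False
        if ok and values[-1] < 0:
            problems.append((line, f"negative value {values[-1]}"))
    if problems:
        raise ResponseTableError(problems)

    out = raw.copy()
    out["marker"] = markers
    out["test_system"] = systems
    out["dose"] = doses
    out["time"] = times
    out["value"] = values
    cols = ["compound_id", "study_id", "species", "setting", "presentation",
            "test_system", "marker", "dose", "dose_unit", "time", "time_unit", "value"]
    return out[cols]


def select_reference_condition(records: pd.DataFrame, cell: tuple[str, str],
                               study: str, reference_id: str) -> tuple[float, float]:
    """Dose/time at which the reference response is maximal in one study/cell.

    Ties break to the lowest dose, then the earliest time.  Raises
    ``KeyError`` if the reference was not measured in that study/cell.
    """
    system, marker = cell
    ref = records[(records["compound_id"] == reference_id)
                  & (records["test_system"] == system)
                  & (records["marker"] == marker)
                  & (records["study_id"] == study)]
    if ref.empty:
        raise KeyError(f"reference {reference_id!r} absent from study {study!r}, "
                       f"cell {cell!r}")
    ordered = ref.sort_values(["value", "dose", "time"],
                              ascending=[False, True, True], kind="mergesort")
    best = ordered.iloc[0]
    return float(best["dose"]), float(best["time"])


def normalize_to_reference(records: pd.DataFrame, reference_id: str) -> pd.DataFrame:
    """Per-study normalized responses (ratio to the reference compound).

    For every (study, test-system, marker): pick the reference-maximal
    condition, divide each analogue's raw value at that condition by the
    reference's, and discard records at other conditions.  Studies without
    the reference in a cell are skipped with a warning, as are cells where
    the reference response is zero (ratio undefined).

    Returns a long frame: compound_id, study_id, test_system, marker,
    dose, time, normalized.
    """
    if (records["compound_id"] == reference_id).sum() == 0:
        raise ValueError(f"reference compound {reference_id!r} not in records")
    keys = ["study_id", "test_system", "marker"]
    ref = records[records["compound_id"] == reference_id]
    # reference-maximal condition per study-cell; ties -> lowest dose, earliest time
    ref = ref.sort_values(["value", "dose", "time"],
                          ascending=[False, True, True], kind="mergesort")
    selected = ref.drop_duplicates(keys, keep="first")[
        keys + ["dose", "time", "value"]].rename(columns={"value": "ref_raw"})

    n_cells_total = records.drop_duplicates(keys).shape[0]
    skipped_no_ref = n_cells_total - selected.shape[0]
    zero_ref = selected["ref_raw"] == 0
    skipped_zero_ref = int(zero_ref.sum())
    selected = selected[~zero_ref]

    merged = records.merge(selected, on=keys + ["dose", "time"], how="inner")
    merged["normalized"] = merged["value"] / merged["ref_raw"]
    if skipped_no_ref:
        warnings.warn(f"{skipped_no_ref} study-cells skipped: reference not measured",
                      stacklevel=2)
    if skipped_zero_ref:
        warnings.warn(f"{skipped_zero_ref} study-cells dropped: reference response 0",
                      stacklevel=2)
    out = merged[["compound_id", "study_id", "test_system", "marker", "dose",
                  "time", "normalized"]]
    return out.sort_values(["test_system", "marker", "compound_id", "study_id"],
                           kind="mergesort").reset_index(drop=True)


def aggregate_replicates(normalized: pd.DataFrame,
                         reference_id: str) -> RelativeResponseMatrix:
    """Average per-study normalized values into one result per cell.

    Unweighted arithmetic mean on the ratio scale across studies; the
    replicate count per cell is kept alongside.  Aggregation is invariant
    to study order.
    """
    if normalized.empty:
        raise ValueError("no normalized values to aggregate")
    grouped = normalized.groupby(["compound_id", "test_system", "marker"],
                                 sort=True)["normalized"]
    means = grouped.mean().unstack(["test_system", "marker"])
    counts = grouped.size().unstack(["test_system", "marker"]).reindex_like(means)
    counts = counts.fillna(0).astype(int)
    # stable, vocabulary-ordered columns
    order = [(s, m) for s in TEST_SYSTEMS for m in MARKERS if (s, m) in means.columns]
    means = means[order]
    counts = counts[order]
    means.columns = pd.MultiIndex.from_tuples(means.columns,
                                              names=["test_system", "marker"])
    counts.columns = means.columns
    return RelativeResponseMatrix(values=means, n_sources=counts,
                                  reference_id=reference_id)


def summarize_frequencies(data) -> pd.DataFrame:
    """Dataset-composition table: results per (test-model, marker).

    ``data`` may be a :class:`RelativeResponseMatrix` (counts one aggregated
    result per non-missing cell), a long normalized frame (counts unique
    (compound, cell) combinations) or a mapping/frame of precomputed counts.
    Returns a frame with columns test_system, marker, count, percent
    (two decimals, summing to 100 within rounding) plus per-test-model
    subtotal shares in ``.attrs["test_model_percent"]``.
    """
    if isinstance(data, RelativeResponseMatrix):
        counts = {col: int(data.values[col].notna().sum()) for col in data.values.columns}
    elif isinstance(data, dict):
        counts = {k: int(v) for k, v in data.items()}
    elif isinstance(data, pd.DataFrame) and {"test_system", "marker", "count"} <= set(
            data.columns):
        counts = {(s, m): int(c) for s, m, c in
                  zip(data["test_system"], data["marker"], data["count"])}
    elif isinstance(data, pd.DataFrame) and {"test_system", "marker",
                                             "compound_id"} <= set(data.columns):
        uniq = data.drop_duplicates(["compound_id", "test_system", "marker"])
        counts = {k: int(v) for k, v in
                  uniq.groupby(["test_system", "marker"]).size().items()}
    else:
        raise TypeError("unsupported input for summarize_frequencies")
    if not counts or sum(counts.values()) == 0:
        raise ValueError("no results to summarize")

    total = sum(counts.values())
    rows = [(s, m, counts.get((s, m), 0), round(100.0 * counts.get((s, m), 0) / total, 2))
            for s in TEST_SYSTEMS for m in MARKERS if (s, m) in counts]
    table = pd.DataFrame(rows, columns=["test_system", "marker", "count", "percent"])
    by_model = table.groupby("test_system", sort=False)["count"].sum()
    table.attrs["grand_total"] = total
    table.attrs["test_model_percent"] = {
        s: round(100.0 * c / total, 2) for s, c in by_model.items()}
    return table
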