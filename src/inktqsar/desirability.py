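"""Derringer desirability scoring of Th1/Th2 cytokine profiles.

Each normalized cytokine response y is linearly mapped to a dimensionless
desirability d on [0.1, 0.9] between two anchors (Y_lo, Y_hi):

    larger-better   d = 0.1 + 0.8 (y − Y_lo) / (Y_hi − Y_lo)
    smaller-better  d = 0.9 − 0.8 (y − Y_lo) / (Y_hi − Y_lo)

clipped to the range.  Component d-values are combined into an overall
desirability D by the geometric mean, so a profile that is excellent on one
cytokine but poor on the other lands low (e.g. d = 0.1 and 0.9 give
D = 0.3): only consistently desirable — i.e. polarized — profiles score
high.  Four axes are scored per compound: Th1 and Th2, each in vivo
(mice/in-vivo cell) and in vitro (human and mice cell-cell responses
pooled).  A Th1 axis wants IFN-γ high and IL-4 low; Th2 is the mirror.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import RelativeResponseMatrix
from .vocab import IN_VITRO_CC_SYSTEMS, MICE_IN_VIVO

__all__ = ["DesirabilityConfig", "DesirabilityTable", "d_transform",
           "overall_desirability", "desirability_profiles", "AXES"]

AXES = ("Th1-in-vivo", "Th2-in-vivo", "Th1-in-vitro", "Th2-in-vitro")

#: (marker, direction) components per axis; direction is the desired trend.
_AXIS_COMPONENTS = {
    "Th1": (("IFN-γ", "larger"), ("IL-4", "smaller")),
    "Th2": (("IFN-γ", "smaller"), ("IL-4", "larger")),
}


@dataclass
class DesirabilityConfig:
    """Anchors and axis composition for desirability scoring.

    ``anchors`` maps (group, marker) — group being ``"in-vivo"`` or
    ``"in-vitro"`` — to (Y_lo, Y_hi) on the normalized-response scale.
    Missing anchors default to Y_lo = 0 and Y_hi = the maximum response
    observed in that group/marker (the "maximally found response" rule);
    responses beyond Y_hi clip to 0.9 rather than erroring, so compounds
    exceeding the historical maximum stay scoreable.  ``include_il13``
    optionally adds IL-13 (larger-better) to the Th2 axes.
    """

    d_min: float = 0.1
    d_max: float = 0.9
    anchors: dict = field(default_factory=dict)
    include_il13: bool = False

    def validate(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")
        for key, (lo, hi) in self.anchors.items():
            if not hi > lo:
                raise ValueError(f"degenerate anchors for {key}: Y_hi must exceed Y_lo")


@dataclass
class DesirabilityTable:
    """Per-compound component d-values and overall D per axis (long form)."""

    table: pd.DataFrame  # columns: compound_id, axis, per-marker d columns, D

    def d_matrix(self) -> pd.DataFrame:
        """Compound × axis matrix of overall D-values (NaN where unscored)."""
        return self.table.pivot(index="compound_id", columns="axis", values="D")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def d_transform(y, anchor: tuple[float, float], direction: str = "larger",
                d_min: float = 0.1, d_max: float = 0.9):
    """Linear Derringer transform of a normalized response to [d_min, d_max]."""
    lo, hi = anchor
    if not hi > lo:
        raise ValueError(f"degenerate anchors ({lo}, {hi})")
    if direction not in ("larger", "smaller"):
        raise ValueError(f"direction must be 'larger' or 'smaller', got {direction!r}")
    frac = (np.asarray(y, dtype=float) - lo) / (hi - lo)
    if direction == "smaller":
        frac = 1.0 - frac
    d = d_min + (d_max - d_min) * frac
    out = np.clip(d, d_min, d_max)
    return float(out) if np.isscalar(y) else out


def overall_desirability(d_values) -> float:
    """Geometric mean of component desirabilities."""
    d = np.asarray(list(d_values), dtype=float)
    if d.size == 0:
        raise ValueError("no component d-values")
    if np.any(d <= 0):
        raise ValueError("d-values must be positive for the geometric mean")
    return float(np.exp(np.mean(np.log(d))))


def default_anchors(matrix: RelativeResponseMatrix) -> dict:
    """Y_lo = 0, Y_hi = maximum observed normalized response per
    (group, marker), with in-vitro pooled over the two cell-cell systems."""
    anchors = {}
    for marker in ("IFN-γ", "IL-4", "IL-13"):
        col = (MICE_IN_VIVO, marker)
        if col in matrix.values.columns:
            hi = float(matrix.values[col].max())
            if np.isfinite(hi) and hi > 0:
                anchors[("in-vivo", marker)] = (0.0, hi)
        pooled = _pooled_in_vitro(matrix, marker)
        if pooled is not None:
            hi = float(pooled.max())
            if np.isfinite(hi) and hi > 0:
                anchors[("in-vitro", marker)] = (0.0, hi)
    return anchors


def _pooled_in_vitro(matrix: RelativeResponseMatrix, marker: str):
    cols = [(s, marker) for s in IN_VITRO_CC_SYSTEMS if (s, marker) in
            matrix.values.columns]
    if not cols:
        return None
    return matrix.values[cols].mean(axis=1)  # mean of available systems


def desirability_profiles(matrix: RelativeResponseMatrix,
                          config: DesirabilityConfig | None = None) -> DesirabilityTable:
    """Score every compound on the four Th1/Th2 desirability axes.

    In-vivo axes read the mice/in-vivo responses; in-vitro axes use the
    mean of the human and mice cell-cell responses (whichever are present
    per compound).  An axis D is missing wherever any required component
    response is missing.  Axes with no scoreable compound are omitted with
    a warning.
    """
    config = config or DesirabilityConfig()
    config.validate()
    anchors = dict(default_anchors(matrix))
    anchors.update(config.anchors)

    responses = {}  # (group, marker) -> Series over compounds
    for marker in ("IFN-γ", "IL-4", "IL-13"):
        col = (MICE_IN_VIVO, marker)
        if col in matrix.values.columns:
            responses[("in-vivo", marker)] = matrix.values[col]
        pooled = _pooled_in_vitro(matrix, marker)
        if pooled is not None:
            responses[("in-vitro", marker)] = pooled

    rows = []
    for axis in AXES:
        th, group = axis.split("-", 1)
        components = list(_AXIS_COMPONENTS[th])
        if config.include_il13 and th == "Th2":
            components.append(("IL-13", "larger"))
        needed = [(group, m) for m, _ in components]
        if any(key not in responses or key not in anchors for key in needed):
            warnings.warn(f"axis {axis}: required responses/anchors unavailable; omitted",
                          stacklevel=2)
            continue
        d_cols = {}
        for (marker, direction) in components:
            y = responses[(group, marker)]
            d_cols[marker] = pd.Series(
                d_transform(y.to_numpy(), anchors[(group, marker)], direction,
                            config.d_min, config.d_max),
                index=y.index).where(y.notna())
        d_frame = pd.DataFrame(d_cols)
        complete = d_frame.dropna()
        if complete.empty:
            warnings.warn(f"axis {axis}: no compound has a complete profile; omitted",
                          stacklevel=2)
            continue
        D = np.exp(np.log(complete).mean(axis=1))
        for cid in d_frame.index:
            row = {"compound_id": cid, "axis": axis,
                   "D": float(D[cid]) if cid in D.index else np.nan}
            for marker in d_cols:
                row[f"d_{marker}"] = float(d_frame.loc[cid, marker])
            rows.append(row)
    table = pd.DataFrame(rows)
    return DesirabilityTable(table=table)
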