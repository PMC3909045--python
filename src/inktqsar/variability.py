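"""Precision and discriminating power of the immunological test-models.

Three complementary views of assay quality:

* **intra-variability** — for each compound measured by more than one study
  in the same (test-system, marker) cell, the relative standard deviation
  (RSD, %) of its normalized responses; low values mean different research
  groups agree.
* **inter-variability** — the spread *between* compounds within a cell,
  corrected for the intrinsic intra-variability: a test-model that returns
  the same value for every compound cannot discriminate.  Corrected RSD =
  100·√max(0, s²_between − mean s²_intra) / grand mean, where s²_between is
  the variance of per-compound means and s²_intra the per-compound sample
  variances averaged over replicated compounds.
* **cross-model agreement** — Spearman rank correlation of per-compound
  means between two test-models, on compounds measured in both.

Group differences in intra-RSD across test-models are assessed with the
Kruskal–Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import MARKERS, TEST_SYSTEMS

__all__ = ["intra_rsd", "inter_rsd_corrected", "kruskal_wallis",
           "spearman_correlation", "VariabilityReport", "variability_report"]


def intra_rsd(replicates_by_compound: dict) -> pd.Series:
    """Per-compound RSD (%) across replicate normalized values.

    Compounds with fewer than two replicates are excluded; compounds whose
    replicate mean is zero are excluded with a warning (RSD undefined).
    Uses the sample (n−1) standard deviation.
    """
    out = {}
    zero_mean = []
    for cid, vals in replicates_by_compound.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 2:
            continue
        m = v.mean()
        if m == 0:
            zero_mean.append(cid)
            continue
        out[cid] = 100.0 * v.std(ddof=1) / m
    if zero_mean:
        warnings.warn(f"excluded {len(zero_mean)} compound(s) with zero mean "
                      f"from RSD: {zero_mean[:5]}", stacklevel=2)
    return pd.Series(out, dtype=float, name="intra_rsd")


def inter_rsd_corrected(replicates_by_compound: dict) -> float:
    """Discriminating power (%) of a cell: between-compound RSD corrected
    for intra-variability.

    Floors at 0 when the intra component exceeds the between-compound
    variance.  Requires ≥3 compounds and a nonzero grand mean.
    """
    means, intra_vars = [], []
    for vals in replicates_by_compound.values():
        v = np.asarray(list(vals), dtype=float)
        if v.size == 0:
            continue
        means.append(v.mean())
        if v.size >= 2:
            intra_vars.append(v.var(ddof=1))
    if len(means) < 3:
        raise ValueError("need at least 3 compounds for inter-variability")
    grand = float(np.mean(means))
    if grand == 0:
        raise ValueError("grand mean is zero; RSD undefined")
    s2_between = float(np.var(means, ddof=1))
    s2_intra = float(np.mean(intra_vars)) if intra_vars else 0.0
    return 100.0 * np.sqrt(max(0.0, s2_between - s2_intra)) / grand


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-square p (df = k−1).

    Degenerate input (every value identical across all groups) returns
    (H=0, p=1) rather than erroring.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman ρ (Pearson on mid-ranks) with two-sided t-approximation p.

    Pairs with a missing member are dropped; fewer than three complete
    pairs is an error; zero rank variance yields (nan, nan).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class VariabilityReport:
    """Per-cell variability summary plus cross-model correlations."""

    cells: pd.DataFrame                 # test_system, marker, n_compounds_replicated,
                                        # median_intra_rsd, inter_rsd_corrected
    intra_values: dict = field(repr=False)  # (system, marker) -> Series of RSDs
    group_tests: pd.DataFrame = None    # marker, H, p over test-systems
    cross_model: pd.DataFrame = None    # marker, system_a, system_b, n, rho, p

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False, float_format="%.6g")


def variability_report(normalized: pd.DataFrame,
                       reference_id: str | None = None,
                       min_pairs: int = 3) -> VariabilityReport:
    """Full variability analysis from long per-study normalized values.

    The reference compound (identically 1 by construction) is excluded.
    Cross-model Spearman correlations compare per-compound mean responses
    between test-systems sharing a marker, complete-case.
    """
    df = normalized
    if reference_id is not None:
        df = df[df["compound_id"] != reference_id]
    if df.empty:
        raise ValueError("no normalized values")

    intra_values: dict = {}
    cell_rows = []
    for (system, marker), grp in df.groupby(["test_system", "marker"], sort=True):
        reps = {cid: sub["normalized"].to_numpy()
                for cid, sub in grp.groupby("compound_id")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rsd = intra_rsd(reps)
        intra_values[(system, marker)] = rsd
        try:
            inter = inter_rsd_corrected(reps)
        except ValueError:
            inter = np.nan
        cell_rows.append((system, marker, int(rsd.size),
                          float(rsd.median()) if rsd.size else np.nan, inter))
    cells = pd.DataFrame(cell_rows, columns=[
        "test_system", "marker", "n_compounds_replicated",
        "median_intra_rsd", "inter_rsd_corrected"])

    test_rows = []
    for marker in MARKERS:
        groups = [intra_values[(s, marker)].to_numpy()
                  for s in TEST_SYSTEMS
                  if (s, marker) in intra_values and intra_values[(s, marker)].size > 0]
        if len(groups) >= 2:
            h, p = kruskal_wallis(groups)
            test_rows.append((marker, len(groups), h, p))
    group_tests = pd.DataFrame(test_rows, columns=["marker", "n_groups", "H", "p"])

    means = df.groupby(["compound_id", "test_system", "marker"])["normalized"].mean()
    cross_rows = []
    for marker in MARKERS:
        for i, sa in enumerate(TEST_SYSTEMS):
            for sb in TEST_SYSTEMS[i + 1:]:
                try:
                    a = means.xs((sa, marker), level=["test_system", "marker"])
                    b = means.xs((sb, marker), level=["test_system", "marker"])
                except KeyError:
                    continue
                common = a.index.intersection(b.index)
                if common.size < min_pairs:
                    continue
                try:
                    rho, p = spearman_correlation(a[common], b[common])
                except ValueError:
                    continue
                cross_rows.append((marker, sa, sb, int(common.size), rho, p))
    cross_model = pd.DataFrame(cross_rows, columns=[
        "marker", "system_a", "system_b", "n", "rho", "p"])
    return VariabilityReport(cells=cells, intra_values=intra_values,
                             group_tests=group_tests, cross_model=cross_model)
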