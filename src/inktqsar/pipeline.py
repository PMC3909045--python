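"""End-to-end orchestration: ingest → desirability → models → evaluation.

Runs the whole analysis from a single config: normalize per-study cytokine
responses to the reference compound, aggregate replicates, score the four
Th1/Th2 desirability axes, summarise the chemical space (PCA + UPGMA) and
test-model variability, fit stepwise-MLR and PLS structure–immune models
per axis with seven-fold Q², and evaluate each model's ability to separate
strong from weak polarizers by ROC/AUC at the reference-D cutoff.  All
artifacts are plain CSV/JSON/Newick files; identical config + inputs give
identical artifacts.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold

from . import __version__
from .chemspace import hca_average_linkage, pca_scores, prune_constant_descriptors
from .dataset import (aggregate_replicates, normalize_to_reference,
                      read_response_table, summarize_frequencies)
from .desirability import DesirabilityConfig, desirability_profiles
from .evaluation import classify_strength, roc_auc
from .qsar import choose_pls_components, kfold_q2, pls_fit, stepwise_mlr_fit
from .variability import variability_report

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("inktqsar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    responses: object                 # path or DataFrame of raw records
    descriptors: object               # path or DataFrame (compounds × descriptors)
    out_dir: object = "pipeline_out"
    reference_id: str = "CPD-001"
    seed: int = 0
    include_il13: bool = False
    pca_components: int = 2
    hca_metric: str = "euclidean"
    p_enter: float = 0.05
    p_remove: float = 0.10
    adjust: str = "bonferroni"
    k_folds: int = 7
    max_components: int = 10
    min_gain: float = 0.01
    use_cv_predictions: bool = False
    min_model_rows: int = 10
    anchors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key in ("desirability", "chemspace",
                                                 "model", "evaluation"):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        for name in ("responses", "descriptors"):
            val = getattr(self, name)
            if isinstance(val, (str, Path)) and not Path(val).exists():
                raise FileNotFoundError(f"{name} file not found: {val}")


def _load_descriptors(source) -> pd.DataFrame:
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, index_col=0)
    return pd.DataFrame(source)


def _cv_predictions(X, y, fit, k, seed) -> pd.Series:
    pred = pd.Series(index=y.index, dtype=float)
    for tr, te in KFold(n_splits=k, shuffle=True, random_state=int(seed)).split(X):
        model = fit(X.iloc[tr], y.iloc[tr])
        pred.iloc[te] = np.asarray(model.predict(X.iloc[te]), dtype=float).ravel()
    return pred


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as
    ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"version": __version__, "seed": int(config.seed), "stages": {},
                    "axes": {}}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                log.error("stage %s failed: %s", name, exc)
                log.removeHandler(handler)
                raise PipelineError(name, exc) from exc
            return result
        return deco

    @stage("ingest")
    def records():
        rec = read_response_table(config.responses)
        log.info("ingest: %d raw records", len(rec))
        report["stages"]["ingest"] = {"n_records": int(len(rec))}
        return rec

    @stage("normalize")
    def norm_result():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normalized = normalize_to_reference(records, config.reference_id)
            agg = aggregate_replicates(normalized, config.reference_id)
        agg.to_csv(out / "relative_responses.csv")
        freq = summarize_frequencies(agg)
        freq.to_csv(out / "frequencies.csv", index=False)
        report["stages"]["normalize"] = {
            "n_normalized": int(len(normalized)),
            "n_cells": int(agg.values.notna().sum().sum()),
            "grand_total": int(freq.attrs["grand_total"])}
        return agg, normalized

    matrix, normalized = norm_result

    @stage("desirability")
    def dtable():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dt = desirability_profiles(
                matrix, DesirabilityConfig(anchors=dict(config.anchors),
                                           include_il13=config.include_il13))
        dt.to_csv(out / "desirability.csv")
        dmat = dt.d_matrix()
        report["stages"]["desirability"] = {
            "axes": list(dmat.columns),
            "n_scored": {a: int(dmat[a].notna().sum()) for a in dmat.columns}}
        return dt

    @stage("chemspace")
    def chem():
        desc = _load_descriptors(config.descriptors)
        pruned, removed = prune_constant_descriptors(desc)
        k = min(config.pca_components, pruned.shape[0] - 1, pruned.shape[1])
        pca = pca_scores(pruned, n_components=k)
        pca.scores.to_csv(out / "pca_scores.csv", float_format="%.10g")
        pca.loadings.to_csv(out / "pca_loadings.csv", float_format="%.10g")
        dendro = hca_average_linkage(pruned, metric=config.hca_metric)
        (out / "dendrogram.nwk").write_text(dendro.to_newick(), encoding="utf-8")
        dendro.merge_table().to_csv(out / "hca_merges.csv", index=False,
                                    float_format="%.10g")
        report["stages"]["chemspace"] = {
            "n_descriptors": int(desc.shape[1]), "n_removed_constant": len(removed),
            "explained_variance_fraction":
                [float(v) for v in pca.explained_variance_fraction]}
        return pruned

    @stage("variability")
    def variability():
        try:
            rep = variability_report(normalized, reference_id=config.reference_id)
        except ValueError as exc:
            log.info("variability skipped: %s", exc)
            return None
        rep.to_csv(out / "variability_cells.csv")
        rep.group_tests.to_csv(out / "variability_tests.csv", index=False,
                               float_format="%.6g")
        rep.cross_model.to_csv(out / "cross_model_correlations.csv", index=False,
                               float_format="%.6g")
        report["stages"]["variability"] = {
            "n_cells": int(len(rep.cells)),
            "n_cross_model_pairs": int(len(rep.cross_model))}
        return rep

    @stage("models")
    def models():
        dmat = dtable.d_matrix()
        fitted = {}
        for axis in dmat.columns:
            y = dmat[axis].dropna()
            Xax = chem.reindex(y.index).dropna()
            y = y.loc[Xax.index]
            axis_report: dict = {"n_compounds": int(len(y))}
            report["axes"][axis] = axis_report
            if len(y) < config.min_model_rows or y.std(ddof=0) == 0:
                axis_report["skipped"] = "too few complete rows or constant D"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mlr = stepwise_mlr_fit(Xax, y, p_enter=config.p_enter,
                                       p_remove=config.p_remove,
                                       adjust=config.adjust)
                mlr.q2, _ = kfold_q2(
                    Xax, y,
                    lambda Xt, yt: stepwise_mlr_fit(
                        Xt, yt, p_enter=config.p_enter, p_remove=config.p_remove,
                        adjust=config.adjust),
                    k=min(config.k_folds, len(y)), seed=config.seed)
                n_comp, _ = choose_pls_components(
                    Xax, y, max_components=config.max_components,
                    k=min(config.k_folds, len(y)), seed=config.seed,
                    min_gain=config.min_gain)
                pls = pls_fit(Xax, y, n_components=n_comp)
                pls.q2, _ = kfold_q2(Xax, y,
                                     lambda Xt, yt: pls_fit(Xt, yt, n_comp),
                                     k=min(config.k_folds, len(y)),
                                     seed=config.seed)
            slug = axis.lower().replace("/", "-")
            (out / f"model_{slug}_mlr.json").write_text(mlr.to_json(), encoding="utf-8")
            (out / f"model_{slug}_pls.json").write_text(pls.to_json(), encoding="utf-8")
            axis_report.update({
                "mlr": {"n_selected": len(mlr.selected), "r2": mlr.r2, "q2": mlr.q2},
                "pls": {"n_components": pls.n_components, "r2": pls.r2,
                        "q2": pls.q2}})
            fitted[axis] = (Xax, y, mlr, pls)
            log.info("axis %s: MLR R2=%.3f Q2=%.3f | PLS(%d) R2=%.3f Q2=%.3f",
                     axis, mlr.r2, mlr.q2, pls.n_components, pls.r2, pls.q2)
        return fitted

    @stage("evaluation")
    def evaluation():
        dmat = dtable.d_matrix()
        for axis, (Xax, y, mlr, pls) in models.items():
            if config.reference_id not in dmat.index or pd.isna(
                    dmat.loc[config.reference_id, axis]):
                report["axes"][axis]["roc"] = "reference D unavailable"
                continue
            ref_D = float(dmat.loc[config.reference_id, axis])
            labels = classify_strength(y.drop(config.reference_id, errors="ignore"),
                                       ref_D)
            if labels.nunique() < 2:
                report["axes"][axis]["roc"] = "single-class labels"
                continue
            rocs = {}
            for name, model in (("mlr", mlr), ("pls", pls)):
                if config.use_cv_predictions:
                    fit = ((lambda Xt, yt: pls_fit(Xt, yt, pls.n_components))
                           if name == "pls" else
                           (lambda Xt, yt: stepwise_mlr_fit(
                               Xt, yt, p_enter=config.p_enter,
                               p_remove=config.p_remove, adjust=config.adjust)))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        scores = _cv_predictions(Xax, y, fit,
                                                 min(config.k_folds, len(y)),
                                                 config.seed)
                else:
                    scores = model.predict(Xax)
                scores = scores.loc[labels.index]
                roc = roc_auc(scores, labels)
                slug = axis.lower().replace("/", "-")
                roc.to_frame().to_csv(out / f"roc_{slug}_{name}.csv", index=False,
                                      float_format="%.10g")
                rocs[name] = {"auc": roc.auc, "n_strong": roc.n_pos,
                              "n_weak": roc.n_neg}
            report["axes"][axis]["roc"] = rocs
            report["axes"][axis]["reference_D"] = ref_D
        return None

    (out / "report.json").write_text(
        json.dumps(report, ensure_ascii=False, indent=1, sort_keys=True),
        encoding="utf-8")
    log.info("pipeline complete: %s", out)
    log.removeHandler(handler)
    handler.close()
    return report
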