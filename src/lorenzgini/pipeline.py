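"""End-to-end marker discovery as a model / results pair.

:class:`MarkerSelectionModel` wraps a labelled expression matrix and a
configuration; :meth:`MarkerSelectionModel.fit` runs the full procedure —
per-gene EM discretization, Lorenz-Gini ranking, wrapper subset search
with the Bayesian-net classifier, final model fit and the repeated k-fold
evaluation — and returns a :class:`MarkerSelectionResults` carrying the
selected markers, the fitted network, the ranking, the CV report and a
reproducibility manifest.  All stage seeds derive from one master seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import bayesnet, discretize, evaluation, ranking, search
from .data import (ExpressionMatrix, RankingTable, read_expression_matrix,
                   serialize_model, write_ranking_table)

__all__ = ["PipelineConfig", "MarkerSelectionModel", "MarkerSelectionResults",
           "run", "stage_seeds"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the package defaults."""

    # discretization
    k_candidates: tuple = discretize.DEFAULT_K_CANDIDATES
    disc_tol: float = discretize.DEFAULT_TOL
    disc_max_iter: int = discretize.DEFAULT_MAX_ITER
    # ranking
    top_k: int = ranking.DEFAULT_TOP_K
    # subset search
    search_pool: int | None = None  # candidates fed to the wrapper; None=top_k
    strategies: tuple = ("greedy", "best-first")
    directions: tuple = ("forward",)
    stale_limit: int = search.DEFAULT_STALE_LIMIT
    goodness_k: int = 5
    goodness_repeats: int = 3
    # classifier
    max_parents: int = 1
    smoothing: float = bayesnet.DEFAULT_SMOOTHING
    # final evaluation
    eval_k_values: tuple = (5, 6, 7, 8, 9)
    eval_repeats: int = 50
    stratified: bool = True
    # reproducibility
    seed: int = 1

    def validate(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        for s in self.strategies:
            if s not in ("greedy", "best-first"):
                raise ValueError(f"unknown strategy {s!r}")
        for d in self.directions:
            if d not in ("forward", "backward"):
                raise ValueError(f"unknown direction {d!r}")


def stage_seeds(master_seed: int) -> dict:
    """Derive one independent 31-bit seed per pipeline stage from the
    master seed (stable spawn order: discretize, goodness, evaluation)."""
    state = np.random.SeedSequence(master_seed).generate_state(3)
    names = ("discretize", "goodness", "evaluation")
    return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


class MarkerSelectionModel:
    """Lorenz-Gini marker selection on a labelled expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Continuous genes x samples data with per-sample class labels.
    config : PipelineConfig, optional
        Defaults are used when omitted; keyword overrides are applied on
        top of the given (or default) config.
    """

    def __init__(self, matrix: ExpressionMatrix,
                 config: PipelineConfig | None = None, **overrides):
        self.matrix = matrix
        cfg = config or PipelineConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        cfg.validate()
        self.config = cfg

    @classmethod
    def from_files(cls, matrix_path: str, labels_path: str,
                   config: PipelineConfig | None = None, **overrides):
        return cls(read_expression_matrix(matrix_path, labels_path),
                   config, **overrides)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels,
                       config: PipelineConfig | None = None, **overrides):
        return cls(ExpressionMatrix.from_dataframe(df, labels),
                   config, **overrides)

    def fit(self, seed: int | None = None) -> "MarkerSelectionResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        seeds = stage_seeds(cfg.seed)

        disc = discretize.discretize_matrix(
            self.matrix, cfg.k_candidates, seed=seeds["discretize"],
            max_iter=cfg.disc_max_iter, tol=cfg.disc_tol)

        rank_table = ranking.rank_genes(disc, top_k=cfg.top_k)
        pool_size = cfg.search_pool or cfg.top_k
        pool = rank_table.gene_ids[:pool_size]

        clf_cfg = evaluation.ClassifierConfig(
            max_parents=cfg.max_parents, smoothing=cfg.smoothing, order=pool)
        evaluator = search.GoodnessEvaluator(
            disc, k=cfg.goodness_k, repeats=cfg.goodness_repeats,
            seed=seeds["goodness"], classifier_config=clf_cfg,
            stratified=cfg.stratified)
        log = search.SearchLog()

        candidates = []
        for strategy in cfg.strategies:
            for direction in cfg.directions:
                if strategy == "greedy":
                    sub = search.greedy_search(pool, direction,
                                               goodness=evaluator, log=log)
                else:
                    sub = search.best_first_search(
                        pool, direction, goodness=evaluator,
                        stale_limit=cfg.stale_limit, log=log)
                candidates.append((strategy, direction, sub, evaluator(sub)))

        pidx = {g: i for i, g in enumerate(pool)}
        best = min(candidates,
                   key=lambda c: search._subset_key(frozenset(c[2]), c[3],
                                                    pidx))
        markers = best[2]

        marker_order = [g for g in pool if g in markers]
        model = bayesnet.learn_structure(
            disc.restrict(marker_order), order=marker_order,
            max_parents=cfg.max_parents, smoothing=cfg.smoothing)

        report = evaluation.cross_validate(
            disc, markers, k_values=cfg.eval_k_values,
            n_seeds=cfg.eval_repeats,
            classifier_config=evaluation.ClassifierConfig(
                max_parents=cfg.max_parents, smoothing=cfg.smoothing,
                order=marker_order),
            stratified=cfg.stratified, base_seed=seeds["evaluation"])

        return MarkerSelectionResults(
            markers=markers, model=model, ranking=rank_table,
            cv_report=report, config=cfg, seeds=seeds,
            searches=[{"strategy": s, "direction": d,
                       "subset": list(sub), "goodness": g}
                      for s, d, sub, g in candidates],
            search_log=log, n_goodness_evaluations=evaluator.n_evaluations)


@dataclass
class MarkerSelectionResults:
    """Everything the selection produced, with reporting helpers."""

    markers: list
    model: bayesnet.BayesNetModel
    ranking: RankingTable
    cv_report: evaluation.CVReport
    config: PipelineConfig
    seeds: dict
    searches: list
    search_log: search.SearchLog
    n_goodness_evaluations: int = 0

    def summary(self) -> str:
        cfg = self.config
        rep = self.cv_report
        lines = [
            "Lorenz-Gini marker selection",
            "=" * 60,
            f"genes ranked:          {len(self.ranking)} (top_k={cfg.top_k})",
            f"selected markers:      {len(self.markers)}",
            f"  {', '.join(self.markers)}",
            f"search strategies:     {', '.join(cfg.strategies)} "
            f"({', '.join(cfg.directions)})",
            f"goodness evaluations:  {self.n_goodness_evaluations}",
            "",
            f"cross-validation:      k = "
            f"{','.join(map(str, cfg.eval_k_values))}, "
            f"{cfg.eval_repeats} seeds each",
            f"mean accuracy:         {rep.mean:.4f}  (sd {rep.std:.4f})",
            "per-k mean accuracy:",
        ]
        for k, a in rep.per_k().items():
            lines.append(f"  k={k}: {a:.4f}")
        lines.append("")
        lines.append("pooled confusion matrix (true rows x predicted cols):")
        lines.append(" " * 16 + " ".join(f"{c:>12s}" for c in rep.class_set))
        for i, c in enumerate(rep.class_set):
            row = " ".join(f"{int(v):>12d}" for v in rep.confusion[i])
            lines.append(f"{c:>14s}  {row}")
        return "\n".join(lines)

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "stage_seeds": self.seeds,
            "markers": list(self.markers),
            "searches": self.searches,
            "n_goodness_evaluations": self.n_goodness_evaluations,
        }

    def save_artifacts(self, out_dir: str) -> None:
        """Write ranking, markers, model, CV report, search log and the
        run manifest under ``out_dir``."""
        os.makedirs(out_dir, exist_ok=True)
        write_ranking_table(self.ranking, os.path.join(out_dir,
                                                       "ranking.tsv"))
        with open(os.path.join(out_dir, "markers.txt"), "w") as fh:
            fh.write("\n".join(self.markers) + "\n")
        serialize_model(self.model, os.path.join(out_dir, "model.json"))
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(self.cv_report.to_dict(), fh, indent=1)
        with open(os.path.join(out_dir, "search_log.tsv"), "w") as fh:
            fh.write("subset\tgoodness\n")
            for sub, g in self.search_log.records:
                fh.write(f"{','.join(sub)}\t{g:.17g}\n")
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def run(matrix: ExpressionMatrix, config: PipelineConfig | None = None,
        out_dir: str | None = None):
    """Functional entry point: returns (markers, model, CVReport,
    RankingTable); writes artifacts when ``out_dir`` is given."""
    res = MarkerSelectionModel(matrix, config).fit()
    if out_dir is not None:
        res.save_artifacts(out_dir)
    return res.markers, res.model, res.cv_report, res.ranking
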