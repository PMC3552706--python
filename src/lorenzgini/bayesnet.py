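"""Discrete Bayesian-network classifier over a class node and marker genes.

The class node is always a root and a parent of every gene node; gene-gene
edges are learned greedily under an AIC score (negated log-likelihood plus
the number of free parameters — lower is better).  Classification is the
usual product query: posterior over classes proportional to the class
prior times each gene's conditional probability given its parents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import DiscretizedMatrix

__all__ = [
    "BayesNetModel",
    "fit_cpts",
    "log_likelihood",
    "aic_score",
    "n_free_parameters",
    "learn_structure",
    "joint_probability",
    "predict",
    "predict_codes",
]

FORMAT_VERSION = "lorenzgini-bn-1"
DEFAULT_SMOOTHING = 0.5


def _check_acyclic(gene_ids: Sequence[str], parents: Mapping[str, Sequence[str]]):
    state: dict = {}

    def visit(g):
        if state.get(g) == 1:
            raise ValueError(f"cycle through gene {g!r}")
        if state.get(g) == 2:
            return
        state[g] = 1
        for p in parents.get(g, ()):  # gene parents only
            visit(p)
        state[g] = 2

    for g in gene_ids:
        visit(g)


@dataclass
class BayesNetModel:
    """Fitted network: structure, smoothed CPTs, class priors.

    ``cpts[g]`` has shape (n_classes, *parent_arities, arity_g); the class
    is the leading parent axis of every gene's table.  ``boundaries`` keeps
    the discretization cut points so the model can classify continuous
    expression vectors directly.
    """

    class_set: list
    gene_ids: list
    arities: list
    parents: dict  # gene -> list of gene parents (class parent implicit)
    class_priors: np.ndarray
    cpts: dict  # gene -> ndarray
    smoothing: float = DEFAULT_SMOOTHING
    aic: float | None = None
    boundaries: dict | None = None  # gene -> ascending cut points

    def __post_init__(self):
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if abs(self.class_priors.sum() - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        _check_acyclic(self.gene_ids, self.parents)
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        for g in self.gene_ids:
            cpt = np.asarray(self.cpts[g], dtype=float)
            expect = (len(self.class_set),
                      *(self.arities[gi[p]] for p in self.parents.get(g, ())),
                      self.arities[gi[g]])
            if cpt.shape != expect:
                raise ValueError(
                    f"CPT for {g!r} has shape {cpt.shape}, expected {expect}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {g!r} do not sum to 1")
            self.cpts[g] = cpt

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def gene_index(self, gene: str) -> int:
        return self.gene_ids.index(gene)

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "class_set": list(self.class_set),
            "gene_ids": list(self.gene_ids),
            "arities": [int(a) for a in self.arities],
            "parents": {g: list(p) for g, p in self.parents.items()},
            "class_priors": self.class_priors.tolist(),
            "cpts": {g: self.cpts[g].tolist() for g in self.gene_ids},
            "smoothing": self.smoothing,
            "aic": self.aic,
            "boundaries": (None if self.boundaries is None else
                           {g: list(map(float, b))
                            for g, b in self.boundaries.items()}),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "BayesNetModel":
        from .data import DataFormatError

        try:
            if payload["format_version"] != FORMAT_VERSION:
                raise DataFormatError(
                    f"unsupported model format {payload['format_version']!r}")
            return cls(
                class_set=list(payload["class_set"]),
                gene_ids=list(payload["gene_ids"]),
                arities=[int(a) for a in payload["arities"]],
                parents={g: list(p) for g, p in payload["parents"].items()},
                class_priors=np.asarray(payload["class_priors"], dtype=float),
                cpts={g: np.asarray(c, dtype=float)
                      for g, c in payload["cpts"].items()},
                smoothing=float(payload["smoothing"]),
                aic=payload.get("aic"),
                boundaries=(None if payload.get("boundaries") is None else
                            {g: np.asarray(b, dtype=float)
                             for g, b in payload["boundaries"].items()}),
            )
        except (KeyError, TypeError, ValueError) as e:
            if isinstance(e, DataFormatError):
                raise
            raise DataFormatError(f"malformed model payload: {e}") from e


def _cpt_from_counts(counts: np.ndarray, smoothing: float) -> np.ndarray:
    arity = counts.shape[-1]
    totals = counts.sum(axis=-1, keepdims=True)
    if smoothing > 0:
        return (counts + smoothing) / (totals + smoothing * arity)
    cpt = np.empty_like(counts, dtype=float)
    empty = (totals == 0)
    safe = np.where(empty, 1.0, totals)
    cpt = counts / safe
    # rows with no observations get a uniform placeholder so they remain
    # valid distributions; they never occur in the training data
    cpt = np.where(empty, 1.0 / arity, cpt)
    return cpt


def fit_cpts(
    structure: Mapping[str, Sequence[str]],
    data: DiscretizedMatrix,
    smoothing: float = DEFAULT_SMOOTHING,
) -> BayesNetModel:
    """Estimate all conditional probability tables for a given structure.

    P(value | parent combo) = (count + smoothing) / (total + smoothing*arity);
    the class prior is estimated the same way from the label counts.
    """
    gi = {g: i for i, g in enumerate(data.gene_ids)}
    for g, pars in structure.items():
        if g not in gi:
            raise ValueError(f"node {g!r} absent from data")
        for p in pars:
            if p not in gi:
                raise ValueError(f"parent node {p!r} absent from data")
    genes = list(data.gene_ids)
    parents = {g: list(structure.get(g, ())) for g in genes}
    _check_acyclic(genes, parents)
    arities = list(data.ranges_per_gene)
    lab = data.label_codes()
    n_classes = len(data.class_set)

    cpts = {}
    for g in genes:
        pars = parents[g]
        shape = (n_classes, *(arities[gi[p]] for p in pars), arities[gi[g]])
        counts = np.zeros(shape, dtype=float)
        idx = (lab, *(data.codes[gi[p]] for p in pars), data.codes[gi[g]])
        np.add.at(counts, idx, 1.0)
        cpts[g] = _cpt_from_counts(counts, smoothing)

    class_counts = np.bincount(lab, minlength=n_classes).astype(float)
    priors = ((class_counts + smoothing)
              / (class_counts.sum() + smoothing * n_classes))
    bounds = None
    if data.boundaries_per_gene is not None:
        bounds = {g: np.asarray(data.boundaries_per_gene[gi[g]], dtype=float)
                  for g in genes}
    return BayesNetModel(list(data.class_set), genes, arities, parents,
                         priors, cpts, smoothing, boundaries=bounds)


def n_free_parameters(model: BayesNetModel) -> int:
    """Standard free-parameter count: (arity-1) x product of parent
    arities per node, class node included."""
    gi = {g: i for i, g in enumerate(model.gene_ids)}
    total = model.n_classes - 1
    for g in model.gene_ids:
        prod = model.n_classes
        for p in model.parents.get(g, ()):
            prod *= model.arities[gi[p]]
        total += (model.arities[gi[g]] - 1) * prod
    return total


def log_likelihood(model: BayesNetModel, data: DiscretizedMatrix) -> float:
    """Sum over samples of the log joint probability; -inf (not an error)
    if an unsmoothed model meets an unseen event."""
    gi = {g: i for i, g in enumerate(data.gene_ids)}
    lab = data.label_codes()
    with np.errstate(divide="ignore"):
        total = np.log(model.class_priors)[lab].astype(float)
        for g in model.gene_ids:
            pars = model.parents.get(g, ())
            idx = (lab, *(data.codes[gi[p]] for p in pars), data.codes[gi[g]])
            total = total + np.log(model.cpts[g][idx])
    return float(total.sum())


def aic_score(model: BayesNetModel, data: DiscretizedMatrix) -> float:
    """Negated log-likelihood plus the number of free parameters (lower is
    better)."""
    return -log_likelihood(model, data) + n_free_parameters(model)


def _family_aic(
    g_codes: np.ndarray,
    g_arity: int,
    parent_codes: list,
    parent_arities: list,
    lab: np.ndarray,
    n_classes: int,
    smoothing: float,
) -> float:
    """One gene family's additive AIC contribution (-LL_g + params_g)."""
    shape = (n_classes, *parent_arities, g_arity)
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, (lab, *parent_codes, g_codes), 1.0)
    cpt = _cpt_from_counts(counts, smoothing)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(cpt), 0.0).sum()
    params = (g_arity - 1) * n_classes * math.prod(parent_arities)
    return float(-ll + params)


def learn_structure(
    data: DiscretizedMatrix,
    order: Sequence[str] | None = None,
    max_parents: int = 1,
    smoothing: float = DEFAULT_SMOOTHING,
) -> BayesNetModel:
    """Greedy AIC edge-addition search over a fixed gene ordering.

    The class node is a parent of every gene (classifier backbone).  Genes
    are processed in ``order``; for each, candidate parents are the
    earlier-ordered genes, added one at a time and kept only on a strict
    AIC improvement, up to ``max_parents`` gene-parents.  ``max_parents=0``
    returns the naive structure.  The AIC decomposes over families, so only
    the affected family is rescored per candidate.
    """
    genes = list(order) if order is not None else list(data.gene_ids)
    if set(genes) != set(data.gene_ids):
        data = data.restrict(genes)
    gi = {g: i for i, g in enumerate(data.gene_ids)}
    lab = data.label_codes()
    n_classes = len(data.class_set)
    arities = data.ranges_per_gene

    parents: dict = {g: [] for g in genes}
    for pos, g in enumerate(genes):
        g_codes = data.codes[gi[g]]
        g_arity = arities[gi[g]]
        current = _family_aic(g_codes, g_arity, [], [], lab, n_classes,
                              smoothing)
        candidates = genes[:pos]
        while len(parents[g]) < max_parents:
            best_gain = 0.0
            best_cand = None
            best_score = None
            for cand in candidates:
                if cand in parents[g]:
                    continue
                pars = parents[g] + [cand]
                score = _family_aic(
                    g_codes, g_arity,
                    [data.codes[gi[p]] for p in pars],
                    [arities[gi[p]] for p in pars],
                    lab, n_classes, smoothing)
                gain = current - score
                if gain > best_gain + 1e-12:
                    best_gain, best_cand, best_score = gain, cand, score
            if best_cand is None:
                break
            parents[g].append(best_cand)
            current = best_score
    model = fit_cpts(parents, data, smoothing)
    model.aic = aic_score(model, data)
    return model


def _instance_codes(model: BayesNetModel, instance) -> np.ndarray:
    if isinstance(instance, Mapping):
        vals = [instance[g] for g in model.gene_ids]
    else:
        vals = list(instance)
        if len(vals) != len(model.gene_ids):
            raise ValueError(
                f"instance has {len(vals)} values for "
                f"{len(model.gene_ids)} genes")
    codes = np.asarray(vals, dtype=np.intp)
    for i, g in enumerate(model.gene_ids):
        if not (0 <= codes[i] < model.arities[i]):
            raise ValueError(
                f"value {codes[i]} out of range [0, {model.arities[i]}) "
                f"for gene {g!r}")
    return codes


def joint_probability(model: BayesNetModel, instance, class_label) -> float:
    """Joint probability of one fully observed instance and a class:
    class prior times the product of each gene's CPT entry."""
    codes = _instance_codes(model, instance)
    j = model.class_set.index(class_label)
    gi = {g: i for i, g in enumerate(model.gene_ids)}
    p = float(model.class_priors[j])
    for g in model.gene_ids:
        pars = model.parents.get(g, ())
        idx = (j, *(codes[gi[q]] for q in pars), codes[gi[g]])
        p *= float(model.cpts[g][idx])
    return p


def predict(model: BayesNetModel, instance) -> tuple:
    """MAP class for one instance plus the full normalized posterior.

    Ties go to the earlier class in class_set order; an all-zero joint
    (possible only with smoothing 0) raises.
    """
    joints = np.array([joint_probability(model, instance, c)
                       for c in model.class_set])
    total = joints.sum()
    if total == 0.0:
        raise ValueError("all class joints are zero; cannot normalize "
                         "(fit with smoothing > 0)")
    post = joints / total
    return model.class_set[int(np.argmax(post))], post


def predict_codes(model: BayesNetModel, codes: np.ndarray) -> list:
    """Classify each column of a (genes x samples) code matrix aligned to
    ``model.gene_ids``."""
    codes = np.asarray(codes)
    return [predict(model, codes[:, s])[0] for s in range(codes.shape[1])]
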