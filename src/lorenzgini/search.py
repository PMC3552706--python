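"""Wrapper feature-subset selection over the pre-ranked candidate genes.

Subsets are scored by the cross-validated accuracy of the Bayesian-net
classifier ("goodness"); the search walks the subset lattice either
greedily (hill climbing by single-gene addition or removal) or best-first
(a backtracking variant that keeps an open list of frontier subsets and
stops after a fixed number of consecutive non-improving expansions —
default five).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Sequence

from . import evaluation
from .data import DiscretizedMatrix

__all__ = [
    "GoodnessEvaluator",
    "SearchLog",
    "greedy_search",
    "best_first_search",
    "select_markers",
    "DEFAULT_STALE_LIMIT",
]

DEFAULT_STALE_LIMIT = 5


class GoodnessEvaluator:
    """Cached CV-accuracy goodness of a gene subset.

    Uses a single fixed CV configuration (default 5-fold, 3 repeats, fixed
    internal seed) so goodness is a deterministic, repeatable function of
    the subset; results are cached by subset, so re-scoring is free.
    """

    def __init__(
        self,
        disc: DiscretizedMatrix,
        k: int = 5,
        repeats: int = 3,
        seed: int = 20130123,
        classifier_config: evaluation.ClassifierConfig | None = None,
        stratified: bool = True,
    ):
        self.disc = disc
        self.k = k
        self.repeats = repeats
        self.seed = seed
        self.classifier_config = classifier_config
        self.stratified = stratified
        self.cache: dict = {}
        self.n_evaluations = 0

    def __call__(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if not key:
            raise ValueError("cannot score an empty subset")
        if key in self.cache:
            return self.cache[key]
        report = evaluation.cross_validate(
            self.disc, sorted(key), k_values=(self.k,), n_seeds=self.repeats,
            classifier_config=self.classifier_config,
            stratified=self.stratified, base_seed=self.seed)
        self.n_evaluations += 1
        self.cache[key] = report.mean
        return report.mean


@dataclass
class SearchLog:
    """Every subset a search scored, with its goodness, for audit."""

    records: list = field(default_factory=list)  # (subset tuple, goodness)

    def add(self, subset, goodness):
        self.records.append((tuple(sorted(subset)), float(goodness)))


def _subset_key(subset: frozenset, goodness: float, pool_index: dict):
    """Total order: higher goodness, then smaller subset, then earlier
    ranking positions (cost-effective small marker sets win ties)."""
    return (-goodness, len(subset),
            tuple(sorted(pool_index[g] for g in subset)))


def _resolve_goodness(goodness, disc, eval_config):
    if goodness is not None:
        return goodness
    if disc is None:
        raise ValueError("provide either a goodness callable or disc")
    return GoodnessEvaluator(disc, **(eval_config or {}))


def greedy_search(
    pool: Sequence[str],
    direction: str = "forward",
    goodness: Callable | None = None,
    disc: DiscretizedMatrix | None = None,
    eval_config: dict | None = None,
    log: SearchLog | None = None,
) -> list:
    """Hill-climbing subset search.

    Forward starts from the empty set and adds the best single gene while
    it strictly improves goodness; backward starts from the full pool and
    removes.  Ties among equally good children go to the gene earlier in
    the ranking order of ``pool``.  Returns the final subset in pool order.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("pool must be non-empty")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    good = _resolve_goodness(goodness, disc, eval_config)
    pidx = {g: i for i, g in enumerate(pool)}

    if direction == "forward":
        current: frozenset = frozenset()
        current_good = float("-inf")
    else:
        current = frozenset(pool)
        current_good = good(current)
        if log is not None:
            log.add(current, current_good)

    while True:
        children = []
        if direction == "forward":
            for g in pool:
                if g not in current:
                    children.append(current | {g})
        else:
            if len(current) > 1:
                for g in sorted(current, key=pidx.get):
                    children.append(current - {g})
        if not children:
            break
        best_child, best_good = None, float("-inf")
        for child in children:
            cg = good(child)
            if log is not None:
                log.add(child, cg)
            if cg > best_good or (
                cg == best_good
                and _subset_key(child, cg, pidx)
                < _subset_key(best_child, best_good, pidx)
            ):
                best_child, best_good = child, cg
        if best_good > current_good:
            current, current_good = best_child, best_good
        else:
            break
    return sorted(current, key=pidx.get)


def best_first_search(
    pool: Sequence[str],
    direction: str = "forward",
    goodness: Callable | None = None,
    disc: DiscretizedMatrix | None = None,
    eval_config: dict | None = None,
    stale_limit: int | None = DEFAULT_STALE_LIMIT,
    log: SearchLog | None = None,
) -> list:
    """Best-first subset search with backtracking.

    Keeps an open list of scored-but-unexpanded subsets and always expands
    the best one (children are single-gene additions — forward — or
    removals — backward).  The search stops when ``stale_limit``
    consecutive expansions fail to improve the global best, or when the
    open list is exhausted; ``stale_limit=None`` removes the cap, in which
    case the whole reachable lattice is explored.  Returns the best subset
    found.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("pool must be non-empty")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if stale_limit is not None and stale_limit < 1:
        raise ValueError("stale_limit must be >= 1 (or None)")
    good = _resolve_goodness(goodness, disc, eval_config)
    pidx = {g: i for i, g in enumerate(pool)}

    def score(sub: frozenset) -> float:
        g = good(sub)
        if log is not None:
            log.add(sub, g)
        return g

    open_heap: list = []  # entries: (key, counter, subset)
    counter = 0
    seen: set = set()

    def push(sub: frozenset, g: float):
        nonlocal counter
        heapq.heappush(open_heap, (_subset_key(sub, g, pidx), counter, sub))
        counter += 1

    if direction == "forward":
        start: frozenset = frozenset()
        start_good = float("-inf")
    else:
        start = frozenset(pool)
        start_good = score(start)
    seen.add(start)
    push(start, start_good)
    best, best_good = (start, start_good) if start else (None, float("-inf"))

    stale = 0
    while open_heap:
        _, _, sub = heapq.heappop(open_heap)
        if direction == "forward":
            children = [sub | {g} for g in pool if g not in sub]
        else:
            children = [sub - {g} for g in sub] if len(sub) > 1 else []
        improved = False
        for child in children:
            if child in seen:
                continue
            seen.add(child)
            cg = score(child)
            push(child, cg)
            if cg > best_good or (
                best is not None and cg == best_good
                and _subset_key(child, cg, pidx)
                < _subset_key(best, best_good, pidx)
            ):
                if cg > best_good:
                    improved = True
                best, best_good = child, cg
        if children:
            stale = 0 if improved else stale + 1
            if stale_limit is not None and stale >= stale_limit:
                break
    if best is None or not best:
        raise ValueError("search found no scoreable subset")
    return sorted(best, key=pidx.get)


def select_markers(matrix, config=None):
    """Full marker selection on a continuous expression matrix.

    Thin functional wrapper over :class:`lorenzgini.pipeline
    .MarkerSelectionModel`: discretize, rank, run the configured searches,
    and return ``(subset, fitted model, CVReport)``.
    """
    from .pipeline import MarkerSelectionModel, PipelineConfig

    cfg = config or PipelineConfig()
    res = MarkerSelectionModel(matrix, cfg).fit()
    return res.markers, res.model, res.cv_report
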