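"""Unsupervised discretization of per-gene expression values.

Each gene's continuous profile is modelled as a one-dimensional Gaussian
mixture fitted by EM; the value range is cut at the posterior crossing
points between adjacent (ascending-mean) components, giving ordered
expression ranges.  The number of components is chosen per gene by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .data import DiscretizedMatrix, ExpressionMatrix

__all__ = [
    "MixtureFit",
    "DegenerateInputError",
    "em_fit",
    "choose_components",
    "discretize_matrix",
    "component_boundaries",
    "apply_boundaries",
]

# k=1 must be available: BIC then leaves genuinely unimodal (non-splitting)
# genes as a single range, which the ranking maps to score 0; forcing a
# split on such genes manufactures near-empty ranges with degenerate
# gini-ratio scores.
DEFAULT_K_CANDIDATES = (1, 2, 3, 4)
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
# relative variance floor; keeps components from collapsing onto ties
VARIANCE_FLOOR_FRACTION = 1e-6
# ranges holding fewer than this fraction of the samples are merged into a
# neighbour: near-empty ranges carry no class evidence but make the
# splitting-status denominator of the gini ratio arbitrarily small
DEFAULT_MIN_RANGE_FRACTION = 0.025


class DegenerateInputError(ValueError):
    """Input cannot support the requested mixture (e.g. constant values)."""


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components in ascending-mean order."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    converged: bool
    log_likelihood: float
    bic: float
    n_iter: int = 0
    ll_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be in ascending-mean order")

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * (3 * self.k - 1)


def _log_density(x: np.ndarray, w, mu, var) -> np.ndarray:
    """Per-component weighted log density, shape (k, n)."""
    x = x[None, :]
    return (
        np.log(w)[:, None]
        - 0.5 * np.log(2.0 * np.pi * var)[:, None]
        - 0.5 * (x - mu[:, None]) ** 2 / var[:, None]
    )


def em_fit(
    values: Sequence[float],
    k: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MixtureFit:
    """Fit a k-component 1-D Gaussian mixture by EM.

    Initialization is deterministic given ``seed``: component means at the
    k interior quantiles, common variance, uniform weights (a seeded jitter
    is applied only when quantile means coincide).  The log-likelihood is
    non-decreasing across iterations; iteration stops when the relative
    change drops below ``tol``.  ``k=1`` is returned in closed form.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} values for k={k}, got {n}")
    sample_var = float(np.var(x))
    if k == 1:
        mu = float(np.mean(x))
        var = max(sample_var, 1e-300)
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * var)
                          - 0.5 * (x - mu) ** 2 / var))
        bic = -2.0 * ll + 2.0 * math.log(n)
        return MixtureFit(1, np.array([1.0]), np.array([mu]),
                          np.array([var]), True, ll, bic, 0,
                          np.array([ll]))
    if sample_var == 0.0:
        raise DegenerateInputError(
            "all values identical; a multi-component mixture is degenerate "
            "(use k=1)")

    floor = max(VARIANCE_FLOOR_FRACTION * sample_var, 1e-12)
    # quantile init: deterministic; jitter only on collisions
    q = (np.arange(k) + 0.5) / k
    mu = np.quantile(x, q)
    if np.unique(mu).size < k:
        rng = np.random.default_rng(seed)
        mu = mu + 1e-3 * math.sqrt(sample_var) * rng.standard_normal(k)
        mu.sort()
    var = np.full(k, sample_var)
    w = np.full(k, 1.0 / k)

    ll_prev = -np.inf
    traj = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logd = _log_density(x, w, mu, var)           # (k, n)
        ll_per_sample = logsumexp(logd, axis=0)
        ll = float(ll_per_sample.sum())
        traj.append(ll)
        resp = np.exp(logd - ll_per_sample[None, :])  # responsibilities
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ (x * x)) / nk - mu ** 2
        var = np.maximum(var, floor)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            converged = True
            break
        ll_prev = ll

    order = np.argsort(mu, kind="stable")
    w, mu, var = w[order], mu[order], var[order]
    ll = traj[-1]
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * math.log(n)
    return MixtureFit(k, w, mu, var, converged, ll, bic, it,
                      np.asarray(traj))


def choose_components(
    values: Sequence[float],
    k_candidates: Iterable[int] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MixtureFit:
    """Fit each candidate component count and keep the lowest-BIC mixture.

    Candidates whose fit errors out (degenerate input, too few values) are
    skipped; only if all fail is the last error re-raised.  Ties in BIC
    favour the smaller model.
    """
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ValueError("k_candidates must be non-empty")
    best = None
    last_err: Exception | None = None
    for k in candidates:
        try:
            fit = em_fit(values, k, seed=seed, max_iter=max_iter, tol=tol)
        except (DegenerateInputError, ValueError) as e:
            last_err = e
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise last_err if last_err is not None else ValueError("no candidates")
    return best


def component_boundaries(fit: MixtureFit) -> np.ndarray:
    """Posterior crossing point between each adjacent component pair.

    Between ascending-mean components i and i+1 the boundary is the root of
    the weighted log-density difference within (mu_i, mu_{i+1}); if the
    difference does not change sign there (one component dominates
    throughout) the midpoint is used.
    """
    bounds = []
    for i in range(fit.k - 1):
        wi, mi, vi = fit.weights[i], fit.means[i], fit.variances[i]
        wj, mj, vj = fit.weights[i + 1], fit.means[i + 1], fit.variances[i + 1]

        def f(t):
            return (math.log(wi) - 0.5 * math.log(vi) - (t - mi) ** 2 / (2 * vi)
                    - math.log(wj) + 0.5 * math.log(vj)
                    + (t - mj) ** 2 / (2 * vj))

        lo, hi = float(mi), float(mj)
        if lo == hi:
            bounds.append(lo)
            continue
        if f(lo) > 0 > f(hi):
            bounds.append(float(brentq(f, lo, hi)))
        else:
            bounds.append(0.5 * (lo + hi))
    b = np.asarray(bounds, dtype=float)
    # crossings of adjacent ascending-mean Gaussians are ascending in all
    # non-pathological fits; enforce strictness for downstream searchsorted
    for i in range(1, b.size):
        if b[i] <= b[i - 1]:
            b[i] = np.nextafter(b[i - 1], np.inf)
    return b


def apply_boundaries(values: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Map values to 0-based range codes given ascending cut points."""
    return np.searchsorted(np.asarray(boundaries, dtype=float),
                           np.asarray(values, dtype=float), side="left")


def _batched_em(
    X: np.ndarray,
    k: int,
    seeds: Sequence[int],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the same k-component 1-D mixture independently to every row of X.

    Vectorized twin of :func:`em_fit` (identical update equations and
    stopping rule, applied per row with a convergence mask); returns
    (weights, means, variances, ll, bic), components in ascending-mean
    order.  Rows are assumed non-constant with at least 2k values.
    """
    G, n = X.shape
    sample_var = X.var(axis=1)
    floor = np.maximum(VARIANCE_FLOOR_FRACTION * sample_var, 1e-12)
    q = (np.arange(k) + 0.5) / k
    mu = np.quantile(X, q, axis=1).T  # (G, k)
    for g in range(G):
        if np.unique(mu[g]).size < k:
            rng = np.random.default_rng(seeds[g])
            mu[g] = np.sort(mu[g] + 1e-3 * np.sqrt(sample_var[g])
                            * rng.standard_normal(k))
    var = np.repeat(sample_var[:, None], k, axis=1)
    w = np.full((G, k), 1.0 / k)

    ll_prev = np.full(G, -np.inf)
    ll = np.full(G, -np.inf)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        a = np.flatnonzero(active)
        if a.size == 0:
            break
        Xa = X[a][:, None, :]  # (Ga, 1, n)
        logd = (np.log(w[a])[:, :, None]
                - 0.5 * np.log(2.0 * np.pi * var[a])[:, :, None]
                - 0.5 * (Xa - mu[a][:, :, None]) ** 2 / var[a][:, :, None])
        ll_s = logsumexp(logd, axis=1)  # (Ga, n)
        ll_a = ll_s.sum(axis=1)
        resp = np.exp(logd - ll_s[:, None, :])
        nk = np.maximum(resp.sum(axis=2), 1e-300)
        w[a] = nk / n
        mu_a = np.einsum("gkn,gn->gk", resp, X[a]) / nk
        var_a = np.einsum("gkn,gn->gk", resp, X[a] ** 2) / nk - mu_a ** 2
        mu[a] = mu_a
        var[a] = np.maximum(var_a, floor[a][:, None])
        done = (np.isfinite(ll_prev[a])
                & (np.abs(ll_a - ll_prev[a]) <= tol * np.abs(ll_prev[a])))
        ll[a] = ll_a
        ll_prev[a] = ll_a
        active[a[done]] = False

    order = np.argsort(mu, axis=1, kind="stable")
    w = np.take_along_axis(w, order, axis=1)
    mu = np.take_along_axis(mu, order, axis=1)
    var = np.take_along_axis(var, order, axis=1)
    bic = -2.0 * ll + (3 * k - 1) * math.log(n)
    return w, mu, var, ll, bic


def _gene_seed(seed: int, gene_index: int) -> int:
    return int(np.random.SeedSequence([seed, gene_index]).generate_state(1)[0]
               % (2 ** 31))


def _compact_and_merge(
    codes: np.ndarray,
    k: int,
    bounds: np.ndarray,
    min_count: int,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Drop empty ranges, then merge under-occupied ranges into the smaller
    adjacent neighbour until every range holds >= min_count samples (or one
    range remains).  Returns compacted (codes, m, boundaries)."""
    counts = list(np.bincount(codes, minlength=k))
    cuts = list(bounds)  # cuts[i] separates range i from i+1
    # groups[i] = list of original bins merged into current range i
    groups = [[i] for i in range(k)]
    # empty ranges are just a special case of under-occupied ones
    min_count = max(min_count, 1)
    while len(groups) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = (i, j) if i < j else (j, i)
        counts[lo] += counts[hi]
        groups[lo].extend(groups[hi])
        del counts[hi], groups[hi], cuts[lo]
    remap = np.empty(k, dtype=np.intp)
    for new, grp in enumerate(groups):
        for old in grp:
            remap[old] = new
    return remap[codes], len(groups), np.asarray(cuts, dtype=float)


def _select_fit(fits: list, criterion: str) -> "MixtureFit":
    if criterion == "bic":
        return min(fits, key=lambda f: f.bic)
    if criterion == "aic":
        return min(fits, key=lambda f: f.aic)
    raise ValueError(f"unknown selection criterion {criterion!r}")


def discretize_gene(
    values: np.ndarray,
    k_candidates: Iterable[int] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_range_fraction: float = DEFAULT_MIN_RANGE_FRACTION,
    select_by: str = "aic",
) -> tuple[np.ndarray, int, np.ndarray]:
    """Discretize one gene; returns (codes, n_ranges, boundaries).

    The component count minimizing ``select_by`` (AIC by default — for a
    downstream class-separation step the sharper criterion splits marginal
    multimodality that BIC leaves unsplit) is fitted, values are cut at the
    posterior crossings, and empty or under-occupied ranges are merged so
    range indices are contiguous, ordered by ascending expression, and
    each range holds at least ``min_range_fraction`` of the samples.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0.0:
        return np.zeros(x.size, dtype=np.intp), 1, np.empty(0)
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ValueError("k_candidates must be non-empty")
    fits = []
    last_err: Exception | None = None
    for k in candidates:
        try:
            fits.append(em_fit(x, k, seed=seed, max_iter=max_iter, tol=tol))
        except (DegenerateInputError, ValueError) as e:
            last_err = e
    if not fits:
        raise last_err if last_err is not None else ValueError("no candidates")
    fit = _select_fit(fits, select_by)
    bounds = component_boundaries(fit)
    codes = apply_boundaries(x, bounds)
    min_count = int(np.ceil(min_range_fraction * x.size))
    return _compact_and_merge(codes, fit.k, bounds, min_count)


def discretize_matrix(
    matrix: ExpressionMatrix,
    k_candidates: Iterable[int] = DEFAULT_K_CANDIDATES,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    min_range_fraction: float = DEFAULT_MIN_RANGE_FRACTION,
    select_by: str = "aic",
) -> DiscretizedMatrix:
    """Discretize every gene of an expression matrix independently.

    Per-gene RNG streams are derived from ``seed`` and the gene's row index
    so results do not depend on how many genes precede it.  The EM fits are
    batched across genes per candidate component count (same update
    equations as :func:`em_fit`), which keeps genome-scale matrices fast.
    """
    n_genes = matrix.n_genes
    n = matrix.n_samples
    codes = np.empty((n_genes, n), dtype=np.intp)
    m_per_gene = [1] * n_genes
    bounds_per_gene: list[np.ndarray] = [np.empty(0)] * n_genes
    codes[:] = 0

    X = matrix.values
    variable = np.flatnonzero(np.ptp(X, axis=1) > 0)
    if variable.size == 0:
        return DiscretizedMatrix(
            list(matrix.gene_ids), list(matrix.sample_ids), codes,
            list(matrix.labels), list(matrix.class_set), m_per_gene,
            bounds_per_gene)
    candidates = sorted(set(int(k) for k in k_candidates))
    if not candidates:
        raise ValueError("k_candidates must be non-empty")
    seeds = [_gene_seed(seed, int(g)) for g in variable]
    Xv = X[variable]

    best_crit = np.full(variable.size, np.inf)
    best_k = np.zeros(variable.size, dtype=int)
    best_params: dict = {}
    for k in candidates:
        if k == 1:
            mu = Xv.mean(axis=1)
            var = np.maximum(Xv.var(axis=1), 1e-300)
            ll = np.sum(-0.5 * np.log(2 * np.pi * var)[:, None]
                        - 0.5 * (Xv - mu[:, None]) ** 2 / var[:, None],
                        axis=1)
            w = np.ones((variable.size, 1))
            params = (w, mu[:, None], var[:, None])
        elif n >= 2 * k:
            w, mu, var, ll, _ = _batched_em(Xv, k, seeds, max_iter, tol)
            params = (w, mu, var)
        else:
            continue
        n_params = 3 * k - 1
        if select_by == "bic":
            crit = -2.0 * ll + n_params * math.log(n)
        elif select_by == "aic":
            crit = -2.0 * ll + 2.0 * n_params
        else:
            raise ValueError(f"unknown selection criterion {select_by!r}")
        better = crit < best_crit  # strict: ties keep the smaller k
        best_crit = np.where(better, crit, best_crit)
        best_k[better] = k
        best_params[k] = params

    if np.any(best_k == 0):
        raise ValueError(
            f"no feasible component count among {candidates} for "
            f"{n} samples")
    min_count = int(np.ceil(min_range_fraction * n))
    for j, g in enumerate(variable):
        k = int(best_k[j])
        w, mu, var = best_params[k]
        fit = MixtureFit(k, w[j], mu[j], var[j], True,
                         0.0, float(best_crit[j]))
        b = component_boundaries(fit)
        c = apply_boundaries(X[g], b)
        codes[g], m_per_gene[g], bounds_per_gene[g] = _compact_and_merge(
            c, k, b, min_count)
    return DiscretizedMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), codes,
        list(matrix.labels), list(matrix.class_set), m_per_gene,
        bounds_per_gene)
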