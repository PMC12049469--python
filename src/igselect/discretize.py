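"""Discretization of continuous expression values into categorical features.

Two paths feed the information-gain scorer:

* single genes — a one-dimensional Gaussian mixture fitted by EM; each sample
  is assigned its maximum-posterior component (``em_discretize``);
* multi-gene blocks — fuzzy c-means (Bezdek) over the |S|-dimensional sample
  vectors; hard codes taken by row-wise argmax of the membership matrix
  (``fcm_cluster`` / ``fcm_discretize``).

Cluster labels are canonicalized (components by increasing mean, fuzzy
clusters by increasing centroid norm) so codes are deterministic under a
fixed seed and information gain is invariant to label permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .infotheory import CategoricalFeature

logger = logging.getLogger(__name__)

__all__ = [
    "EmSettings",
    "FcmSettings",
    "EmResult",
    "FcmResult",
    "em_discretize",
    "fcm_cluster",
    "fcm_discretize",
    "select_components_bic",
]


class DegenerateInputError(ValueError):
    """Input cannot support the requested number of clusters/components."""


@dataclass(frozen=True)
class EmSettings:
    """Gaussian-mixture EM settings for single-gene discretization.

    ``n_components`` defaults to 2: the discretized feature is scored against
    a two-class label, and more components only fragment the contingency
    counts. Set ``bic_select=True`` to pick the component count in
    ``bic_range`` by the Bayesian information criterion instead.
    """

    n_components: int = 2
    max_iter: int = 200
    tol: float = 1e-4
    bic_select: bool = False
    bic_range: tuple = (2, 3, 4)


@dataclass(frozen=True)
class FcmSettings:
    """Fuzzy c-means settings for multi-gene block discretization.

    ``c`` is the cluster count; the default ``None`` selects it adaptively
    per block as ``min(n_classes ** n_genes, cap)``: the cell count must be
    able to represent every joint low/high state of the block, otherwise
    purely synergistic gene pairs (jointly but not marginally informative)
    are invisible to the scorer. The cap is ``c_max`` when given, else an
    occupancy rule ``clamp(n_samples // 15, 2, 8)`` — roughly 15 samples
    expected per cell — because information gain computed from empirical
    cell frequencies inflates with arity, and under the search's
    max-over-thousands selection pressure an over-fragmented noise block
    would otherwise outscore genuine synergy.

    Other defaults follow standard Bezdek practice: fuzzifier m = 2,
    convergence on maximum membership change below 1e-5, at most 300
    iterations. Gene rows are z-scored before clustering by default so genes
    on different intensity scales contribute comparably to the Euclidean
    distance.
    """

    c: Optional[int] = None
    c_max: Optional[int] = None
    m: float = 2.0
    max_iter: int = 300
    tol: float = 1e-5
    standardize: bool = True
    n_init: int = 1

    def resolve_c(self, n_genes: int, n_samples: int, n_classes: int = 2) -> int:
        if self.c is not None:
            return self.c
        cap = self.c_max if self.c_max is not None else min(8, max(2, n_samples // 15))
        return max(2, min(n_classes**n_genes, cap, n_samples))


@dataclass(frozen=True)
class EmResult:
    assignments: CategoricalFeature
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_components: int
    converged: bool
    n_iter: int

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        if (np.asarray(self.variances) <= 0).any():
            raise ValueError("mixture variances must be positive")
        if self.assignments.arity > self.n_components:
            raise ValueError("assignment arity exceeds component count")


@dataclass(frozen=True)
class FcmResult:
    memberships: np.ndarray  # (n samples, c clusters), rows sum to 1
    centroids: np.ndarray  # (c, n_dims)
    assignments: CategoricalFeature
    objective: float
    objective_trace: tuple
    n_iter: int
    converged: bool

    def __post_init__(self):
        rows = np.asarray(self.memberships).sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-6:
            raise ValueError("membership rows must sum to 1")


def em_discretize(
    gene: Sequence[float],
    n_components: int = 2,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> EmResult:
    """Fit a 1-D Gaussian mixture by EM and return per-sample component codes.

    Components are relabeled in increasing order of mean so output codes are
    deterministic given the seed. Non-convergence within ``max_iter`` returns
    a result with ``converged=False`` and logs a warning.
    """
    x = np.asarray(gene, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("expression vector must be 1-D with length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("expression vector contains non-finite values")
    if n_components < 1:
        raise ValueError("n_components must be positive")
    n_distinct = len(np.unique(x))
    if n_components > n_distinct:
        raise DegenerateInputError(
            f"{n_components} components requested but only {n_distinct} distinct values"
        )
    if len(x) < n_components:
        raise ValueError("need at least as many samples as components")

    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**31),
        n_init=1,
        reg_covar=1e-6,
    )
    X = x[:, None]
    gm.fit(X)
    if not gm.converged_:
        logger.warning("EM did not converge within %d iterations", max_iter)
    order = np.argsort(gm.means_[:, 0], kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(n_components)
    raw = gm.predict(X)
    codes = rank[raw]
    return EmResult(
        assignments=CategoricalFeature(tuple(int(c) for c in codes)),
        means=gm.means_[order, 0].copy(),
        variances=gm.covariances_[order, 0].copy(),
        weights=gm.weights_[order].copy(),
        log_likelihood=float(gm.score(X) * len(x)),
        n_components=n_components,
        converged=bool(gm.converged_),
        n_iter=int(gm.n_iter_),
    )


def select_components_bic(
    gene: Sequence[float], seed: int = 0, candidates: Sequence[int] = (2, 3, 4)
) -> int:
    """Pick a component count by BIC; falls back to the largest feasible."""
    x = np.asarray(gene, dtype=float)[:, None]
    n_distinct = len(np.unique(x))
    best_k, best_bic = None, np.inf
    for k in candidates:
        if k > n_distinct or k > len(x):
            continue
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", random_state=int(seed) % (2**31),
            reg_covar=1e-6,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_k, best_bic = k, bic
    if best_k is None:
        raise DegenerateInputError("no candidate component count is feasible")
    return best_k


def _fcm_iterate_py(X, u, m, max_iter, tol):
    """One full FCM run from an initial membership matrix (numpy path)."""
    n, c = u.shape
    exponent = 2.0 / (m - 1.0)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((um * d2).sum()))
        zero = d2 <= 0
        with np.errstate(divide="ignore"):
            inv = d2 ** (-exponent / 2.0)
        u_new = np.where(np.isfinite(inv), inv, 0.0)
        zrows = zero.any(axis=1)
        if zrows.any():
            u_new[zrows] = 0.0
            first = zero[zrows].argmax(axis=1)
            u_new[np.flatnonzero(zrows), first] = 1.0
        u_new /= u_new.sum(axis=1, keepdims=True)
        shift = np.abs(u_new - u).max()
        u = u_new
        if shift < tol:
            converged = True
            break
    return u, it, converged, trace


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _fcm_iterate_nb(X, u, m, max_iter, tol):  # pragma: no cover
        n, d = X.shape
        c = u.shape[1]
        # with the standard fuzzifier m=2 the updates reduce to squares and
        # reciprocals; the general path needs float pow
        quadratic = m == 2.0
        inv_exp = -1.0 / (m - 1.0)
        trace = np.empty(max_iter)
        converged = False
        it = 0
        um = np.empty((n, c))
        centroids = np.empty((c, d))
        d2 = np.empty((n, c))
        u_new = np.empty((n, c))
        for it in range(1, max_iter + 1):
            for i in range(n):
                for k in range(c):
                    um[i, k] = u[i, k] * u[i, k] if quadratic else u[i, k] ** m
            # centroid update
            for k in range(c):
                wsum = 0.0
                for j in range(d):
                    centroids[k, j] = 0.0
                for i in range(n):
                    w = um[i, k]
                    wsum += w
                    for j in range(d):
                        centroids[k, j] += w * X[i, j]
                for j in range(d):
                    centroids[k, j] /= wsum
            # distances and objective
            obj = 0.0
            for i in range(n):
                for k in range(c):
                    s = 0.0
                    for j in range(d):
                        diff = X[i, j] - centroids[k, j]
                        s += diff * diff
                    d2[i, k] = s
                    obj += um[i, k] * s
            trace[it - 1] = obj
            # membership update with explicit zero-distance handling
            shift = 0.0
            for i in range(n):
                zero_k = -1
                for k in range(c):
                    if d2[i, k] <= 0.0:
                        zero_k = k
                        break
                if zero_k >= 0:
                    for k in range(c):
                        u_new[i, k] = 1.0 if k == zero_k else 0.0
                else:
                    tot = 0.0
                    for k in range(c):
                        u_new[i, k] = 1.0 / d2[i, k] if quadratic else d2[i, k] ** inv_exp
                        tot += u_new[i, k]
                    for k in range(c):
                        u_new[i, k] /= tot
                for k in range(c):
                    delta = abs(u_new[i, k] - u[i, k])
                    if delta > shift:
                        shift = delta
            for i in range(n):
                for k in range(c):
                    u[i, k] = u_new[i, k]
            if shift < tol:
                converged = True
                break
        return u, it, converged, trace[:it]

    def _fcm_iterate(X, u, m, max_iter, tol):
        u, it, converged, trace = _fcm_iterate_nb(
            np.ascontiguousarray(X), np.ascontiguousarray(u), float(m), int(max_iter), float(tol)
        )
        return u, it, converged, list(trace)

except ImportError:  # pragma: no cover
    _fcm_iterate = _fcm_iterate_py


def _standardize_rows(block: np.ndarray) -> np.ndarray:
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant gene contributes zero after centering
    return (block - mu) / sd


def fcm_cluster(
    block: Sequence[Sequence[float]],
    c: int = 2,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    standardize: bool = True,
    n_init: int = 1,
) -> FcmResult:
    """Fuzzy c-means over the sample vectors of a gene block.

    ``block`` is |S| gene rows x n sample columns; clustering operates on the
    n samples as points in |S| dimensions (Euclidean distance). Iterates the
    Bezdek updates

        v_k = sum_i u_ik^m x_i / sum_i u_ik^m
        u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))

    from a seed-controlled random row-stochastic membership matrix until the
    maximum membership change drops below ``tol`` or ``max_iter`` is reached.
    With ``n_init`` > 1, that many seed-derived initializations are run and
    the one with the lowest final objective wins (ties: lowest restart
    index), damping the local-minimum noise a single random start carries.
    A sample coinciding exactly with a centroid gets membership 1 there.
    Clusters are relabeled by increasing centroid norm for determinism.
    """
    B = np.atleast_2d(np.asarray(block, dtype=float))
    if not np.isfinite(B).all():
        raise ValueError("block contains non-finite values")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    n = B.shape[1]
    if c < 1 or c > n:
        raise ValueError(f"cluster count {c} must lie in [1, n={n}]")
    if standardize:
        B = _standardize_rows(B)
    X = B.T  # (n samples, d dims)

    if c == 1:
        centroid = X.mean(axis=0, keepdims=True)
        u = np.ones((n, 1))
        obj = float(((X - centroid) ** 2).sum())
        return FcmResult(u, centroid, CategoricalFeature((0,) * n), obj, (obj,), 0, True)

    if n_init < 1:
        raise ValueError("n_init must be positive")
    best = None
    for restart in range(n_init):
        rng = np.random.default_rng((int(seed) + 100003 * restart) % (2**31))
        u0 = rng.random((n, c))
        u0 /= u0.sum(axis=1, keepdims=True)
        u_r, it_r, conv_r, trace_r = _fcm_iterate(X, u0, m, max_iter, tol)
        um_r = u_r**m
        cent_r = (um_r.T @ X) / um_r.sum(axis=0)[:, None]
        d2_r = ((X[:, None, :] - cent_r[None, :, :]) ** 2).sum(axis=2)
        obj_r = float((um_r * d2_r).sum())
        if best is None or obj_r < best[0] - 1e-12:
            best = (obj_r, u_r, cent_r, it_r, conv_r, trace_r)
    objective, u, centroids, it, converged, trace = best
    if not converged:
        logger.debug("FCM did not converge within %d iterations", max_iter)

    # canonical order: ascending centroid norm, ties by centroid coordinates
    norms = np.linalg.norm(centroids, axis=1)
    order = np.lexsort(tuple(centroids[:, j] for j in reversed(range(centroids.shape[1]))) + (norms,))
    centroids = centroids[order]
    u = u[:, order]
    codes = u.argmax(axis=1)  # argmax breaks ties toward the lowest index
    return FcmResult(
        memberships=u,
        centroids=centroids,
        assignments=CategoricalFeature(tuple(int(x) for x in codes)),
        objective=objective,
        objective_trace=tuple(trace),
        n_iter=it,
        converged=converged,
    )


def fcm_discretize(
    block: Sequence[Sequence[float]],
    settings: Optional[FcmSettings] = None,
    seed: int = 0,
    n_classes: int = 2,
) -> CategoricalFeature:
    """Discretize a gene block with fuzzy c-means, returning only hard codes.

    Single-gene blocks are permitted (re-evaluating FCM(S) for |S| = 1).
    ``n_classes`` feeds the adaptive cluster-count rule when the settings do
    not pin ``c``.
    """
    settings = settings or FcmSettings()
    B = np.atleast_2d(np.asarray(block, dtype=float))
    return fcm_cluster(
        block,
        c=settings.resolve_c(B.shape[0], B.shape[1], n_classes),
        m=settings.m,
        seed=seed,
        max_iter=settings.max_iter,
        tol=settings.tol,
        standardize=settings.standardize,
        n_init=settings.n_init,
    ).assignments
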