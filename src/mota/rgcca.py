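"""Regularized generalized CCA and inter-omic differential edges.

rgCCA finds, for each data block X_l (n samples x h_l features,
column-standardized), a weight vector a_l whose composite y_l = X_l a_l
maximizes

    sum_{l,k} c_lk * g(cov(X_l a_l, X_k a_k))
    subject to (1 - tau_l) var(X_l a_l) + tau_l ||a_l||^2 = 1,

where C = (c_lk) is a binary design matrix connecting blocks, g is a convex
scheme function ("horst": g = identity, maximizing the sum of covariances),
and tau_l in [0, 1] interpolates between correlation (tau=0) and covariance
(tau=1) criteria.  The solver is the standard monotonically convergent
block-relaxation (Gauss-Seidel) scheme; components beyond the first are
obtained by deflating each block on its own previous component scores.

Per-group canonical similarities between a centric feature and an ancillary
feature are inner products of their coordinates in the plane spanned by the
first two canonical variates of their own blocks; edges are called where the
between-group difference exceeds a threshold in absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blocks import GroupedStudy
from .intra import standardize

__all__ = [
    "RgccaModel",
    "DeltaCcResult",
    "fit_rgcca",
    "feature_coordinates",
    "canonical_similarity",
    "delta_cc",
    "call_inter_edges",
    "build_inter_edges",
]

log = logging.getLogger("mota")

#: relative eigenvalue floor under which a within-block covariance counts as
#: rank-deficient, triggering the small-tau fallback at tau=0
_RANK_EPS = 1e-10
_TAU_FALLBACK = 1e-8


@dataclass
class RgccaModel:
    """Fitted rgCCA: per-block weights and component scores.

    ``weights[l]`` is ``h_l x T``; ``components[l]`` is ``n x T`` with
    column t the component-t score vector ``y_l^(t)``.
    """

    weights: list[np.ndarray]
    components: list[np.ndarray]
    design: np.ndarray
    tau: np.ndarray
    scheme: str
    n_components: int
    objective_trace: list[np.ndarray] = field(default_factory=list)
    blocks_std: list[np.ndarray] = field(default_factory=list)


@dataclass
class DeltaCcResult:
    """Per-group canonical similarities and the thresholded edge set."""

    cc1: np.ndarray
    cc2: np.ndarray
    delta: np.ndarray
    threshold: float
    edges: set[tuple[int, int]]
    centric_features: list[str] = field(default_factory=list)
    other_features: list[str] = field(default_factory=list)


def _constraint_matrix(X: np.ndarray, tau: float) -> np.ndarray:
    """M_l = tau I + (1 - tau) X'X / n defining a' M a = 1."""
    n = X.shape[0]
    return tau * np.eye(X.shape[1]) + (1 - tau) * (X.T @ X) / n


def _effective_tau(X: np.ndarray, tau: float, deflated: bool = False) -> float:
    """Replace tau=0 by a tiny shrinkage when X'X is rank-deficient.

    With more features than samples the variance constraint var(X a) = 1 is
    singular; a minimal ridge keeps the constraint matrix invertible and is
    logged loudly rather than applied silently.  After deflation the block
    loses one rank by construction, so the same fallback is applied there
    quietly.
    """
    if tau > 0:
        return tau
    C = X.T @ X / X.shape[0]
    eig = np.linalg.eigvalsh(C)
    if eig[0] <= _RANK_EPS * max(eig[-1], 1.0):
        log.log(
            logging.DEBUG if deflated else logging.WARNING,
            "within-block covariance is rank-deficient (h=%d, n=%d); "
            "substituting tau=%g for tau=0", X.shape[1], X.shape[0],
            _TAU_FALLBACK,
        )
        return _TAU_FALLBACK
    return tau


def fit_rgcca(
    blocks: list[np.ndarray],
    design: np.ndarray | None = None,
    tau: float | list[float] = 0.0,
    scheme: str = "horst",
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> RgccaModel:
    """Fit rgCCA by monotone block relaxation.

    Parameters
    ----------
    blocks
        Column-standardized matrices sharing the sample axis.
    design
        Binary symmetric connection matrix; defaults to all blocks connected
        (complete design, zero diagonal).
    tau
        Scalar or per-block shrinkage in [0, 1]; tau=0 maximizes correlation,
        tau=1 covariance.
    scheme
        Only ``"horst"`` (g = identity) is supported; other schemes are
        refused.
    n_components
        Number of deflated components to extract (the similarity projection
        uses the first two).

    Weight signs are fixed deterministically: if the centric block's largest
    |weight| entry is negative the whole component (all blocks) is flipped,
    which preserves the objective exactly.
    """
    if scheme != "horst":
        raise ValueError(f"unsupported scheme {scheme!r}; only 'horst' is available")
    L = len(blocks)
    if L < 2:
        raise ValueError("rgCCA needs at least two blocks")
    blocks = [np.asarray(X, dtype=float) for X in blocks]
    n = blocks[0].shape[0]
    if any(X.shape[0] != n for X in blocks):
        raise ValueError("all blocks must share the sample axis")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if design is None:
        design = np.ones((L, L)) - np.eye(L)
    design = np.asarray(design, dtype=float)
    if design.shape != (L, L) or not np.allclose(design, design.T):
        raise ValueError("design must be a symmetric L x L matrix")
    if np.any(np.diag(design) != 0):
        raise ValueError("design diagonal must be zero")
    taus = np.full(L, tau, dtype=float) if np.isscalar(tau) else np.asarray(tau, dtype=float)
    if taus.shape != (L,):
        raise ValueError("tau must be scalar or one value per block")
    if np.any((taus < 0) | (taus > 1)):
        raise ValueError("tau values must lie in [0, 1]")

    weights = [np.zeros((X.shape[1], n_components)) for X in blocks]
    comps = [np.zeros((n, n_components)) for X in blocks]
    traces: list[np.ndarray] = []
    work = [X.copy() for X in blocks]

    for t in range(n_components):
        a, y, trace = _fit_component(work, design, taus, tol, max_iter,
                                     deflated=t > 0)
        # deterministic sign: orient so the first block's dominant weight > 0
        j = int(np.argmax(np.abs(a[0])))
        if a[0][j] < 0:
            a = [-al for al in a]
            y = [-yl for yl in y]
        for l in range(L):
            weights[l][:, t] = a[l]
            comps[l][:, t] = y[l]
        traces.append(trace)
        if t + 1 < n_components:
            # deflate each block on its own component scores
            work = [
                Xl - np.outer(yl, yl @ Xl) / float(yl @ yl)
                for Xl, yl in zip(work, y)
            ]

    return RgccaModel(
        weights=weights,
        components=comps,
        design=design,
        tau=taus,
        scheme=scheme,
        n_components=n_components,
        objective_trace=traces,
        blocks_std=blocks,
    )


def _fit_component(
    blocks: list[np.ndarray],
    design: np.ndarray,
    taus: np.ndarray,
    tol: float,
    max_iter: int,
    deflated: bool = False,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """One component by Gauss-Seidel updates; returns (weights, scores, trace)."""
    L = len(blocks)
    n = blocks[0].shape[0]
    eff_tau = [_effective_tau(X, t, deflated=deflated) for X, t in zip(blocks, taus)]
    M = [_constraint_matrix(X, t) for X, t in zip(blocks, eff_tau)]
    M_chol = [np.linalg.cholesky(Ml) for Ml in M]

    def normalize(al: np.ndarray, l: int) -> np.ndarray:
        q = float(al @ M[l] @ al)
        if q <= 0:
            raise np.linalg.LinAlgError(
                "singular constraint matrix; raise tau for this block"
            )
        return al / np.sqrt(q)

    # deterministic init: dominant right singular vector of each block
    a = []
    for l, X in enumerate(blocks):
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        a.append(normalize(vt[0], l))
    y = [X @ al for X, al in zip(blocks, a)]

    def objective() -> float:
        return sum(
            design[l, k] * float(y[l] @ y[k]) / n
            for l in range(L)
            for k in range(L)
            if design[l, k] != 0
        )

    trace = [objective()]
    for _ in range(max_iter):
        for l in range(L):
            grad = np.zeros(n)
            for k in range(L):
                if design[l, k] != 0:
                    grad += design[l, k] * y[k]
            z = blocks[l].T @ grad / n
            al = np.linalg.solve(M[l], z)
            nrm = float(al @ M[l] @ al)
            if nrm <= 0:
                raise np.linalg.LinAlgError("degenerate rgCCA update")
            a[l] = al / np.sqrt(nrm)
            y[l] = blocks[l] @ a[l]
        obj = objective()
        if obj < trace[-1] - 1e-10:
            raise RuntimeError(
                f"rgCCA objective decreased ({trace[-1]:.12g} -> {obj:.12g}); "
                "this should never happen for the horst scheme"
            )
        trace.append(obj)
        if obj - trace[-2] < tol:
            break
    else:
        raise RuntimeError(
            f"rgCCA did not converge in {max_iter} iterations; "
            f"objective trace tail: {trace[-5:]}"
        )
    return a, y, np.asarray(trace)


def feature_coordinates(model: RgccaModel, block: int) -> np.ndarray:
    """Project each feature of one block onto its first two canonical variates.

    Feature j's coordinate is ``(cor(x_j, y^(1)), cor(x_j, y^(2)))`` where
    the ``y^(t)`` are the block's own component scores; entries lie in
    [-1, 1].
    """
    if model.n_components < 2:
        raise ValueError("need at least 2 fitted components for coordinates")
    X = model.blocks_std[block]
    Y = model.components[block][:, :2]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xs = np.linalg.norm(Xc, axis=0)
    ys = np.linalg.norm(Yc, axis=0)
    if np.any(ys == 0):
        raise ValueError("degenerate (constant) component score vector")
    coords = (Xc.T @ Yc) / np.outer(xs, ys)
    return np.clip(coords, -1.0, 1.0)


def canonical_similarity(coords_centric: np.ndarray, coords_other: np.ndarray) -> np.ndarray:
    """Inner products of 2-D feature coordinates: cc_ij = <coord_i, coord_j>."""
    coords_centric = np.asarray(coords_centric, dtype=float)
    coords_other = np.asarray(coords_other, dtype=float)
    if coords_centric.shape[1] != 2 or coords_other.shape[1] != 2:
        raise ValueError("coordinate matrices must have exactly 2 columns")
    return coords_centric @ coords_other.T


def delta_cc(cc1: np.ndarray, cc2: np.ndarray) -> np.ndarray:
    """Differential canonical similarity, group 1 minus group 2."""
    cc1 = np.asarray(cc1, dtype=float)
    cc2 = np.asarray(cc2, dtype=float)
    if cc1.shape != cc2.shape:
        raise ValueError("shape mismatch between group similarities")
    return cc1 - cc2


def call_inter_edges(delta: np.ndarray, threshold: float = 0.5) -> set[tuple[int, int]]:
    """Edges where |delta_cc| strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(np.abs(delta) > threshold))}


def build_inter_edges(
    study: GroupedStudy,
    other: int | str,
    threshold: float = 0.5,
    tau: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> DeltaCcResult:
    """Inter-omic stage for one (centric, ancillary) block pair.

    rgCCA is fitted separately per biological group on within-group
    standardized data with a two-block design, features are projected onto
    the first two canonical variates of their own block, and an edge is
    called where the between-group change in coordinate inner product
    exceeds the threshold in magnitude.
    """
    centric = study.centric
    other_block = study.get_block(other)
    ccs = {}
    for g in (1, 2):
        Xc = standardize(study.group_matrix(0, g), centric.feature_ids)
        Xo = standardize(
            study.group_matrix(other_block.name, g), other_block.feature_ids
        )
        model = fit_rgcca([Xc, Xo], tau=tau, scheme="horst", n_components=2,
                          tol=tol, max_iter=max_iter)
        cc = canonical_similarity(
            feature_coordinates(model, 0), feature_coordinates(model, 1)
        )
        ccs[g] = cc
    delta = delta_cc(ccs[1], ccs[2])
    edges = call_inter_edges(delta, threshold=threshold)
    return DeltaCcResult(
        cc1=ccs[1],
        cc2=ccs[2],
        delta=delta,
        threshold=threshold,
        edges=edges,
        centric_features=list(centric.feature_ids),
        other_features=list(other_block.feature_ids),
    )
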