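"""Intra-omic differential network on the centric block.

For each biological group the features are standardized within-group, a
sparse precision matrix is estimated by the graphical lasso (the l1-penalized
Gaussian maximum-likelihood estimator), and partial correlations are read off
the precision matrix as

    pc_ij = -theta_ij / sqrt(theta_ii * theta_jj).

The differential partial correlation delta_pc = pc(group 1) - pc(group 2) is
compared against an empirical null obtained by permuting the group labels;
a pair becomes an intra-omic edge when its delta_pc lands in either tail of
that null distribution (default 2.5% per tail).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .blocks import GroupedStudy

__all__ = [
    "GlassoError",
    "PrecisionFit",
    "DeltaPcResult",
    "standardize",
    "graphical_lasso",
    "select_rho",
    "partial_corr",
    "delta_pc",
    "permutation_null",
    "call_intra_edges",
    "build_intra_network",
]

log = logging.getLogger("mota")

#: off-diagonal entries smaller than this (absolute) count as zero when
#: measuring the support of an estimated precision matrix
SUPPORT_TOL = 1e-12


class GlassoError(RuntimeError):
    """Graphical-lasso failure, carrying solver diagnostics."""


@dataclass
class PrecisionFit:
    """One group's fitted precision matrix and the inputs that produced it."""

    group: int
    rho: float
    theta: np.ndarray
    sample_cov: np.ndarray
    objective: float


@dataclass
class DeltaPcResult:
    """Differential partial correlations plus the permutation-null decision."""

    pc1: np.ndarray
    pc2: np.ndarray
    delta: np.ndarray
    null_samples: np.ndarray
    lower_cut: float
    upper_cut: float
    edges: set[tuple[int, int]]
    rho: tuple[float, float] = (np.nan, np.nan)
    feature_ids: list[str] = field(default_factory=list)


def standardize(X: np.ndarray, feature_ids: list[str] | None = None) -> np.ndarray:
    """Column-standardize to mean 0 and unit sample variance (ddof=1).

    Raises on any zero-variance column, naming the feature when ids are
    supplied.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = feature_ids[j] if feature_ids else f"column {j}"
        raise ValueError(f"zero-variance feature {name!r} cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def _glasso_objective(theta: np.ndarray, S: np.ndarray, rho: float) -> float:
    """Penalized log-likelihood log det(T) - tr(S T) - rho * ||T||_1,offdiag."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return logdet - float(np.trace(S @ theta)) - rho * pen


def graphical_lasso(
    S: np.ndarray,
    rho: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """Estimate a sparse precision matrix from a covariance matrix.

    Maximizes ``log det(Theta) - tr(S Theta) - rho * ||Theta||_1`` with the
    l1 penalty on the off-diagonal entries (the convention of Friedman's
    coordinate-descent implementation: variances are not shrunk).  At
    ``rho = 0`` the solution is the unpenalized MLE, the plain matrix
    inverse of ``S``.

    Returns ``(theta, objective)``.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if rho == 0:
        theta = np.linalg.inv(S)
        theta = (theta + theta.T) / 2
        return theta, _glasso_objective(theta, S, 0.0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            _, theta = _sk_graphical_lasso(S, alpha=rho, tol=tol, max_iter=max_iter)
        except FloatingPointError as exc:  # non-SPD / divergence
            raise GlassoError(
                f"graphical lasso failed at rho={rho:g} (tol={tol:g}, "
                f"max_iter={max_iter}): {exc}"
            ) from exc
    for w in caught:
        # the cd solver can oscillate with a tiny residual dual gap; accept
        # that, but a gap far above tol is a genuine non-convergence
        msg = str(w.message)
        if "did not converge" in msg:
            gap = _parse_dual_gap(msg)
            if gap is not None and abs(gap) > 100 * tol:
                raise GlassoError(
                    f"graphical lasso did not converge at rho={rho:g}: {msg}"
                )
            log.debug("glasso convergence wobble accepted: %s", msg)
    theta = (theta + theta.T) / 2
    return theta, _glasso_objective(theta, S, rho)


def _parse_dual_gap(message: str) -> float | None:
    m = re.search(r"dual gap:\s*(-?[\d.]+(?:[eE][+-]?\d+)?)", message)
    return float(m.group(1)) if m else None


def support_size(theta: np.ndarray, tol: float = SUPPORT_TOL) -> int:
    """Number of nonzero off-diagonal entries (counting both triangles)."""
    off = theta - np.diag(np.diag(theta))
    return int(np.count_nonzero(np.abs(off) > tol))


def default_rho_grid(S: np.ndarray, size: int = 20, rho_min: float = 0.01) -> np.ndarray:
    """Log-spaced penalty grid spanning [rho_min, max |off-diagonal of S|]."""
    off = np.abs(S - np.diag(np.diag(S)))
    hi = float(off.max())
    if hi <= rho_min:
        hi = rho_min * 10
    return np.geomspace(rho_min, hi, size)


def select_rho(
    X: np.ndarray,
    folds: int = 5,
    grid: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[float, dict]:
    """Pick the glasso penalty by K-fold CV with the one-standard-error rule.

    The CV loss is the held-out Gaussian negative log-likelihood
    ``tr(S_test Theta) - log det(Theta)``.  The returned rho is the LARGEST
    grid value whose mean loss is within one standard error of the grid
    minimum — the sparsest model statistically indistinguishable from the
    best-fitting one.

    Returns ``(rho, info)`` where ``info`` carries the CV curve for logging.
    """
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = default_rho_grid(np.cov(X, rowvar=False))
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size < 1:
        raise ValueError("empty rho grid")
    if grid.size == 1:
        return float(grid[0]), {"grid": grid, "mean_loss": None, "se_loss": None}
    if folds < 2:
        raise ValueError("folds must be >= 2")

    kf = KFold(n_splits=folds, shuffle=False)
    losses = np.full((grid.size, folds), np.nan)
    for k, (tr, te) in enumerate(kf.split(X)):
        S_tr = np.cov(X[tr], rowvar=False)
        S_te = np.cov(X[te], rowvar=False)
        for i, rho in enumerate(grid):
            try:
                theta, _ = graphical_lasso(S_tr, float(rho), tol=tol, max_iter=max_iter)
            except GlassoError:
                continue
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                continue
            losses[i, k] = float(np.trace(S_te @ theta)) - logdet

    ok = ~np.isnan(losses).any(axis=1)
    if not ok.any():
        raise GlassoError("graphical lasso failed for every rho in the CV grid")
    mean_loss = np.full(grid.size, np.inf)
    se_loss = np.full(grid.size, np.inf)
    mean_loss[ok] = losses[ok].mean(axis=1)
    se_loss[ok] = losses[ok].std(axis=1, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_loss))
    cutoff = mean_loss[i_min] + se_loss[i_min]
    eligible = np.flatnonzero(ok & (mean_loss <= cutoff))
    i_sel = int(eligible.max())  # largest eligible rho = sparsest model
    info = {
        "grid": grid,
        "mean_loss": mean_loss,
        "se_loss": se_loss,
        "rho_min_cv": float(grid[i_min]),
        "rho_one_se": float(grid[i_sel]),
    }
    return float(grid[i_sel]), info


def partial_corr(theta: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    ``pc_ij = -theta_ij / sqrt(theta_ii theta_jj)`` with zeros on the
    diagonal.  For a positive-definite precision the values are bounded by 1
    in magnitude.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(theta)
    if np.any(d <= 0):
        raise ValueError("precision matrix has a nonpositive diagonal entry")
    denom = np.sqrt(np.outer(d, d))
    pc = -theta / denom
    np.fill_diagonal(pc, 0.0)
    return pc


def delta_pc(pc1: np.ndarray, pc2: np.ndarray) -> np.ndarray:
    """Elementwise differential partial correlation, group 1 minus group 2."""
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if pc1.shape != pc2.shape:
        raise ValueError("shape mismatch between group partial correlations")
    return pc1 - pc2


def _group_delta_pc(
    X: np.ndarray,
    labels: np.ndarray,
    rho1: float,
    rho2: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """delta_pc for one labelling of the rows of X (helper for permutations)."""
    pcs = []
    for g, rho in ((1, rho1), (2, rho2)):
        Xg = standardize(X[labels == g])
        S = np.cov(Xg, rowvar=False)
        theta, _ = graphical_lasso(S, rho, tol=tol, max_iter=max_iter)
        pcs.append(partial_corr(theta))
    return pcs[0] - pcs[1]


def permutation_null(
    study: GroupedStudy,
    rho1: float,
    rho2: float,
    n_perm: int = 1000,
    seed: int | None = None,
    pooled: bool = True,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> np.ndarray:
    """Permutation null distribution of the differential partial correlation.

    Group labels are shuffled across samples (group sizes preserved), both
    pseudo-groups are re-standardized and refit with the penalties selected
    on the unpermuted data, and the off-diagonal delta_pc values are pooled
    over feature pairs and permutations.

    Returns a vector of length ``n_perm * h*(h-1)/2`` when ``pooled`` (the
    default), else an ``(n_perm, h*(h-1)/2)`` matrix for per-pair nulls.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable tail quantiles")
    if seed is None:
        raise ValueError("a seed is required: permutation runs must be reproducible")
    rng = np.random.default_rng(seed)
    X = study.centric.values
    labels = study.labels()
    h = X.shape[1]
    iu = np.triu_indices(h, k=1)
    out = np.empty((n_perm, iu[0].size))
    for p in range(n_perm):
        perm = rng.permutation(labels)
        d = _group_delta_pc(X, perm, rho1, rho2, tol=tol, max_iter=max_iter)
        out[p] = d[iu]
    return out.ravel() if pooled else out


def call_intra_edges(
    delta: np.ndarray,
    null: np.ndarray,
    tail: float = 0.025,
) -> tuple[set[tuple[int, int]], float, float]:
    """Edges = feature pairs whose delta_pc lands in a tail of the null.

    Quantiles use the inclusive linear-interpolation convention (numpy
    ``method='linear'``, R type 7).  Returns ``(edges, lower_cut, upper_cut)``.
    """
    null = np.asarray(null, dtype=float).ravel()
    if null.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    lower = float(np.quantile(null, tail, method="linear"))
    upper = float(np.quantile(null, 1 - tail, method="linear"))
    h = delta.shape[0]
    edges = {
        (i, j)
        for i in range(h)
        for j in range(i + 1, h)
        if delta[i, j] < lower or delta[i, j] > upper
    }
    return edges, lower, upper


def build_intra_network(
    study: GroupedStudy,
    n_perm: int = 1000,
    seed: int | None = None,
    tail: float = 0.025,
    folds: int = 5,
    grid_size: int = 20,
    grid_min: float = 0.01,
    pooled: bool = True,
    perm_tol: float = 1e-3,
) -> DeltaPcResult:
    """Run the full intra-omic stage on the centric block.

    Standardizes each group, selects the glasso penalty per group by
    one-standard-error CV, fits both precision matrices, and calls edges
    against the permutation null.
    """
    block = study.centric
    fits: dict[int, np.ndarray] = {}
    rhos: dict[int, float] = {}
    for g in (1, 2):
        Xg = standardize(study.group_matrix(0, g), block.feature_ids)
        S = np.cov(Xg, rowvar=False)
        grid = default_rho_grid(S, size=grid_size, rho_min=grid_min)
        rho, info = select_rho(Xg, folds=folds, grid=grid)
        log.info("group %d: rho one-SE = %.4g (CV minimum at %.4g)", g,
                 info.get("rho_one_se", rho), info.get("rho_min_cv", np.nan))
        theta, _ = graphical_lasso(S, rho)
        fits[g] = partial_corr(theta)
        rhos[g] = rho
    delta = delta_pc(fits[1], fits[2])
    null = permutation_null(
        study, rhos[1], rhos[2], n_perm=n_perm, seed=seed, pooled=pooled,
        tol=perm_tol,
    )
    if pooled:
        edges, lo, hi = call_intra_edges(delta, null, tail=tail)
    else:
        # per-pair nulls: compare each pair against its own permutation column
        h = delta.shape[0]
        iu = np.triu_indices(h, k=1)
        edges = set()
        lo = hi = np.nan
        for col, (i, j) in enumerate(zip(*iu)):
            e, _, _ = call_intra_edges(
                np.array([[0, delta[i, j]], [0, 0]]), null[:, col], tail=tail
            )
            if e:
                edges.add((int(i), int(j)))
    return DeltaPcResult(
        pc1=fits[1],
        pc2=fits[2],
        delta=delta,
        null_samples=np.asarray(null),
        lower_cut=lo,
        upper_cut=hi,
        edges=edges,
        rho=(rhos[1], rhos[2]),
        feature_ids=list(block.feature_ids),
    )
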