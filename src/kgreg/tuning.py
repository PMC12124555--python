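"""Hyperparameter tuning by cross-validated grid search, and graph builders.

Tuning holds out folds of the *observed times*: the model is fit on the
remaining times and scored by mean squared error on the held-out columns at
the observed nodes. Grids are evaluated exhaustively; an optional Nelder-Mead
refinement polishes the best grid point in log-parameter space (all tuned
parameters are positive).

Also provides a simplified coordinate-based graph builder (plain Euclidean
MST or symmetric kNN union with weights ``exp(-d / median(d))``) for when no
graph is given a priori.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph
from scipy.spatial.distance import squareform, pdist

from .graphs import Graph, GraphFilter
from .gls import fit_gls_kgr
from .kgr import KernelSpec, SelectionPattern, fit_kgr

__all__ = ["cv_folds", "tune_hyperparameters", "build_distance_graph"]


def cv_folds(times: np.ndarray, n_folds: int, seed: int | None = None) -> list[np.ndarray]:
    """Partition the observed times uniformly at random into ``n_folds`` folds."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    times = np.asarray(times)
    if len(times) < n_folds:
        raise ValueError("fewer observed times than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(times))
    return [np.sort(times[perm[k::n_folds]]) for k in range(n_folds)]


def _cv_loss(params, Y, X, graph, selection, n_folds, seed, use_gls, alpha, filter_family):
    gamma, beta, sigma = params
    filt = GraphFilter(filter_family, beta)
    kern = KernelSpec(sigma=sigma)
    folds = cv_folds(selection.observed_times, n_folds, seed)
    losses = []
    time_pos = {t: j for j, t in enumerate(selection.observed_times)}
    for hold in folds:
        keep = np.setdiff1d(selection.observed_times, hold)
        sub_sel = SelectionPattern(
            selection.observed_nodes, keep,
            n_total=selection.n_total, t_total=selection.t_total,
        )
        keep_cols = [time_pos[t] for t in keep]
        hold_cols = [time_pos[t] for t in hold]
        Y_train = Y[:, keep_cols]
        if use_gls:
            res = fit_gls_kgr(
                Y_train, X, graph, filt, gamma=gamma, alpha=alpha,
                selection=sub_sel, kernel=kern,
            )
            f_hat = res.f_star
        else:
            f_hat = fit_kgr(Y_train, X, graph, filt, gamma, sub_sel, kern).f_star
        pred = f_hat[np.ix_(selection.observed_nodes, hold)]
        losses.append(float(np.mean((pred - Y[:, hold_cols]) ** 2)))
    return float(np.mean(losses))


def tune_hyperparameters(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    selection: SelectionPattern,
    gamma_grid,
    beta_grid,
    sigma_grid,
    n_folds: int = 4,
    seed: int | None = None,
    use_gls: bool = False,
    alpha: float = 0.1,
    filter_family: str = "exponential",
    refine: bool = False,
):
    """Exhaustive CV grid search over (gamma, beta, sigma), optional polish.

    Returns ``(best_params_dict, cv_table)`` where the table has one row per
    grid point with its mean held-out MSE. With ``refine=True`` a Nelder-Mead
    search in log space starts from the best grid point.
    """
    rows = []
    for gamma in gamma_grid:
        for beta in beta_grid:
            for sigma in sigma_grid:
                loss = _cv_loss(
                    (gamma, beta, sigma), Y, X, graph, selection,
                    n_folds, seed, use_gls, alpha, filter_family,
                )
                rows.append({"gamma": gamma, "beta": beta, "sigma": sigma, "cv_mse": loss})
    table = pd.DataFrame(rows)
    if not np.isfinite(table["cv_mse"]).any():
        raise ValueError("cross-validation loss is non-finite at every grid point")
    best = table.loc[table["cv_mse"].idxmin()].to_dict()
    if refine:
        x0 = np.log([best["gamma"], best["beta"], best["sigma"]])
        res = scipy.optimize.minimize(
            lambda z: _cv_loss(
                np.exp(z), Y, X, graph, selection, n_folds, seed,
                use_gls, alpha, filter_family,
            ),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-2, "fatol": 1e-6, "maxiter": 100},
        )
        gamma, beta, sigma = np.exp(res.x)
        best = {"gamma": gamma, "beta": beta, "sigma": sigma, "cv_mse": float(res.fun)}
    return best, table


def build_distance_graph(
    coordinates: np.ndarray,
    method: str = "mst",
    k: int | None = None,
    normalized: bool = False,
) -> Graph:
    """Sparse graph over points: Euclidean MST or symmetric kNN union.

    Edge weights are ``exp(-d / median(d))`` with the median over all pairwise
    distances, so nearby points couple strongly. The MST is connected by
    construction; ties between equal distances are broken by index order (the
    deterministic behaviour of the underlying sparse MST routine).
    """
    P = np.asarray(coordinates, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2 or not np.isfinite(P).all():
        raise ValueError("need >= 2 points with finite coordinates")
    n = P.shape[0]
    D = squareform(pdist(P))
    med = np.median(D[np.triu_indices(n, k=1)])
    med = med if med > 0 else 1.0
    W = np.exp(-D / med)
    A = np.zeros((n, n))
    if method == "mst":
        mst = scipy.sparse.csgraph.minimum_spanning_tree(scipy.sparse.csr_matrix(D))
        ii, jj = mst.nonzero()
        A[ii, jj] = W[ii, jj]
        A[jj, ii] = W[ii, jj]
    elif method == "knn":
        if k is None or k < 1:
            raise ValueError("knn method requires k >= 1")
        for i in range(n):
            order = np.argsort(D[i])
            neigh = [j for j in order if j != i][:k]
            A[i, neigh] = W[i, neigh]
        A = np.maximum(A, A.T)  # symmetric union
    else:
        raise ValueError(f"unknown method {method!r}; use 'mst' or 'knn'")
    np.fill_diagonal(A, 0.0)
    return Graph(A, normalized=normalized)
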