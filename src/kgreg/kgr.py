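"""Kernel graph regression with constant-subset missingness.

The model: a latent signal ``F`` (N nodes x T times) is observed on a fixed
subset of ``N'`` nodes at ``T'`` times through ``Y = S_N F S_T^T + E`` with
i.i.d. unit Gaussian noise ``E``. The prior couples times through a Mercer
kernel Gram matrix ``K`` over explanatory features and nodes through a squared
graph filter ``H^2``:

    vec(F) ~ N(0, (K x H^2) / gamma).

The MAP estimate solves a Tikhonov-regularised least-squares problem whose
naive solution inverts an ``NT x NT`` system. The efficient solver used here
reduces every dense eigendecomposition to the observed sizes ``N'`` and ``T'``:

    F* = H^2 S_N^T Ubar (J o (Ubar^T Y Vbar)) Vbar^T S_T K

with ``S_T K S_T^T = Vbar LamK Vbar^T``, ``S_N H^2 S_N^T = Ubar LamH Ubar^T``
and ``J_ij = 1 / (lamH_i lamK_j + gamma)`` (``o`` is the Hadamard product).
The same algebra reconstructs signals on Cartesian product graphs when ``K``
is replaced by a second, time-like graph filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .graphs import Graph, GraphFilter, filter_matrix, filter_matrix_squared

__all__ = [
    "SelectionPattern",
    "KernelSpec",
    "KGRFit",
    "gram_matrix",
    "fit_kgr",
    "fit_kgr_naive",
    "predict",
    "reconstruct_product",
]

#: size guard for the dense NT x NT oracles
NAIVE_GUARD = 2000


@dataclass(frozen=True)
class SelectionPattern:
    """Index sets realising the binary selection matrices ``S_N`` and ``S_T``.

    ``S_N`` picks the observed node rows out of N; ``S_T`` the observed time
    columns out of T. The implementation never materialises the 0/1 matrices:
    selection is fancy-indexing, its transpose is scatter-addition.
    """

    observed_nodes: np.ndarray
    observed_times: np.ndarray
    n_total: int
    t_total: int

    def __post_init__(self):
        nodes = np.asarray(self.observed_nodes, dtype=int)
        times = np.asarray(self.observed_times, dtype=int)
        for name, idx, total in (
            ("observed_nodes", nodes, self.n_total),
            ("observed_times", times, self.t_total),
        ):
            if idx.ndim != 1 or len(idx) == 0:
                raise ValueError(f"{name} must be a non-empty 1-d index set")
            if len(np.unique(idx)) != len(idx):
                raise ValueError(f"{name} contains duplicate indices")
            if idx.min() < 0 or idx.max() >= total:
                raise ValueError(f"{name} out of range [0, {total})")
        object.__setattr__(self, "observed_nodes", np.sort(nodes))
        object.__setattr__(self, "observed_times", np.sort(times))

    @property
    def n_prime(self) -> int:
        return len(self.observed_nodes)

    @property
    def t_prime(self) -> int:
        return len(self.observed_times)

    def s_n(self) -> np.ndarray:
        """Dense ``(N', N)`` selection matrix (oracle/testing use)."""
        S = np.zeros((self.n_prime, self.n_total))
        S[np.arange(self.n_prime), self.observed_nodes] = 1.0
        return S

    def s_t(self) -> np.ndarray:
        """Dense ``(T', T)`` selection matrix (oracle/testing use)."""
        S = np.zeros((self.t_prime, self.t_total))
        S[np.arange(self.t_prime), self.observed_times] = 1.0
        return S

    def hidden_nodes(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_total), self.observed_nodes)

    def hidden_times(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.t_total), self.observed_times)

    def observed_mask(self) -> np.ndarray:
        """Boolean ``(N, T)`` mask of observed node-times."""
        m = np.zeros((self.n_total, self.t_total), dtype=bool)
        m[np.ix_(self.observed_nodes, self.observed_times)] = True
        return m


@dataclass(frozen=True)
class KernelSpec:
    """Mercer kernel specification; currently the Gaussian (RBF) family."""

    family: str = "gaussian"
    sigma: float = 1.0

    def __post_init__(self):
        if self.family != "gaussian":
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")


def gram_matrix(features: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Gram matrix over the columns of the ``(M, T)`` feature matrix.

    Gaussian kernel: ``K_ij = exp(-|x_i - x_j|^2 / (2 sigma^2))``; symmetric
    PSD with unit diagonal.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite entries")
    D2 = cdist(X.T, X.T, metric="sqeuclidean")
    K = np.exp(-D2 / (2.0 * kernel.sigma**2))
    return 0.5 * (K + K.T)


@dataclass
class KGRFit:
    """Result of a kernel graph regression fit.

    ``f_star`` is the full ``(N, T)`` latent estimate, including unobserved
    node-times. The spectral factors that produced it are retained so that
    downstream prediction and diagnostics never re-decompose.
    """

    f_star: np.ndarray
    gamma: float
    j_matrix: np.ndarray
    u_bar: np.ndarray
    v_bar: np.ndarray
    lam_h: np.ndarray
    lam_k: np.ndarray
    h2: np.ndarray
    k: np.ndarray
    selection: SelectionPattern


def _fit_core(Y, K, H2, gamma, selection):
    """Shared reduced-size solver for the Hadamard-product MAP solution."""
    nodes, times = selection.observed_nodes, selection.observed_times
    H2_bar = H2[np.ix_(nodes, nodes)]
    K_bar = K[np.ix_(times, times)]
    lam_h, U_bar = np.linalg.eigh(H2_bar)
    lam_k, V_bar = np.linalg.eigh(K_bar)
    lam_h = np.maximum(lam_h, 0.0)
    lam_k = np.maximum(lam_k, 0.0)
    J = 1.0 / (np.outer(lam_h, lam_k) + gamma)
    core = U_bar @ (J * (U_bar.T @ Y @ V_bar)) @ V_bar.T
    F = H2[:, nodes] @ core @ K[times, :]
    return F, J, U_bar, V_bar, lam_h, lam_k


def _validate_fit_inputs(Y, gamma, selection):
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (selection.n_prime, selection.t_prime):
        raise ValueError(
            f"Y shape {Y.shape} does not match selection "
            f"({selection.n_prime}, {selection.t_prime})"
        )
    if np.isnan(Y).any():
        raise ValueError(
            "Y contains NaN; missingness must be expressed through the selection pattern"
        )
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    return Y


def fit_kgr(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    selection: SelectionPattern,
    kernel: KernelSpec = KernelSpec(),
) -> KGRFit:
    """MAP estimate of the latent signal under the ``K x H^2`` prior.

    All dense eigendecompositions act on the observed-size blocks
    ``S_N H^2 S_N^T`` (N' x N') and ``S_T K S_T^T`` (T' x T').
    """
    Y = _validate_fit_inputs(Y, gamma, selection)
    K = gram_matrix(X, kernel)
    H2 = filter_matrix_squared(graph, filt)
    F, J, U_bar, V_bar, lam_h, lam_k = _fit_core(Y, K, H2, gamma, selection)
    return KGRFit(
        f_star=F, gamma=gamma, j_matrix=J, u_bar=U_bar, v_bar=V_bar,
        lam_h=lam_h, lam_k=lam_k, h2=H2, k=K, selection=selection,
    )


def _naive_solve(Y, K, H2, gamma, selection, sigma_n=None, sigma_t=None):
    """Dense Kronecker-assembled oracle (guarded); GLS when covariances given."""
    N, T = selection.n_total, selection.t_total
    if N * T > NAIVE_GUARD:
        raise ValueError(f"naive oracle guard exceeded: N*T = {N * T} > {NAIVE_GUARD}")
    Sn, St = selection.s_n(), selection.s_t()
    jit = 1e-10
    K_inv = np.linalg.inv(K + jit * np.eye(T))
    H2_inv = np.linalg.inv(H2 + jit * np.eye(N))
    if sigma_n is None:
        sigma_n_inv = np.eye(selection.n_prime)
    else:
        sigma_n_inv = np.linalg.inv(sigma_n)
    if sigma_t is None:
        sigma_t_inv = np.eye(selection.t_prime)
    else:
        sigma_t_inv = np.linalg.inv(sigma_t)
    A = np.kron(St.T @ sigma_t_inv @ St, Sn.T @ sigma_n_inv @ Sn) + gamma * np.kron(
        K_inv, H2_inv
    )
    rhs = np.kron(St.T @ sigma_t_inv, Sn.T @ sigma_n_inv) @ Y.flatten(order="F")
    f = np.linalg.solve(A, rhs)
    return f.reshape((N, T), order="F")


def fit_kgr_naive(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    selection: SelectionPattern,
    kernel: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """Brute-force oracle: solve the full ``NT x NT`` normal equations.

    Only for verification at small sizes (guarded at ``N*T <= 2000``); adds a
    1e-10 jitter to ``K`` and ``H^2`` before inversion so singular filters do
    not break the oracle.
    """
    Y = _validate_fit_inputs(Y, gamma, selection)
    K = gram_matrix(X, kernel)
    H2 = filter_matrix_squared(graph, filt)
    return _naive_solve(Y, K, H2, gamma, selection)


def predict(
    fit: KGRFit,
    nodes: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Entries of ``F*`` at the requested node/time index sets.

    Defaults to all nodes/times. Unobserved node-times are permitted — they
    are the point of the method.
    """
    F = fit.f_star
    nodes = np.arange(F.shape[0]) if nodes is None else np.asarray(nodes, dtype=int)
    times = np.arange(F.shape[1]) if times is None else np.asarray(times, dtype=int)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= F.shape[0]):
        raise IndexError("node index out of range")
    if times.size and (times.min() < 0 or times.max() >= F.shape[1]):
        raise IndexError("time index out of range")
    return F[np.ix_(nodes, times)]


def reconstruct_product(
    Y: np.ndarray,
    time_graph: Graph,
    space_graph: Graph,
    time_filter: GraphFilter,
    space_filter: GraphFilter,
    gamma: float,
    selection: SelectionPattern,
) -> np.ndarray:
    """Signal reconstruction on a Cartesian product graph.

    Identical algebra to :func:`fit_kgr` with the kernel Gram matrix replaced
    by a time-like graph filter, i.e. prior ``vec(F) ~ N(0, (H_T x H_N)/gamma)``.
    """
    Y = _validate_fit_inputs(Y, gamma, selection)
    H_T = filter_matrix_squared(time_graph, time_filter)
    H2 = filter_matrix_squared(space_graph, space_filter)
    F, *_ = _fit_core(Y, H_T, H2, gamma, selection)
    return F
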