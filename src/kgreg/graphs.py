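"""Graphs, Laplacians, spectral decompositions, graph filters and spectral priors.

A graph signal is a vector ``f`` with one real value per vertex. Its roughness
with respect to the graph is the Laplacian quadratic form

    f^T L f = sum_{(i,j) in E} A_ij (f_i - f_j)^2 >= 0,

zero iff ``f`` is constant on every connected component. The Laplacian
eigendecomposition ``L = U diag(lam) U^T`` (eigenvalues ascending) defines the
graph Fourier transform ``a = U^T f``; small eigenvalues correspond to smooth
eigenvectors. A graph filter is ``H = U eta(lam) U^T`` for a non-increasing
response ``eta`` with ``eta(0) = 1``, and ``H^2`` serves as the covariance of a
smoothness-encouraging Gaussian prior ``f ~ N(0, H^2 / gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Graph",
    "SpectralDecomposition",
    "GraphFilter",
    "FILTER_FAMILIES",
    "build_laplacian",
    "smoothness",
    "gft",
    "igft",
    "eta",
    "filter_matrix",
    "sample_spectral_prior",
    "cartesian_product",
    "is_separable_check",
]


# ---------------------------------------------------------------------------
# Graph container


class Graph:
    """A static, undirected, non-negatively weighted graph.

    Parameters
    ----------
    adjacency
        Symmetric ``(N, N)`` weight matrix with zero diagonal and entries >= 0.
    normalized
        If True the Laplacian is the symmetric-normalized variant
        ``D^{-1/2} (D - A) D^{-1/2}`` (spectrum in [0, 2]); otherwise the plain
        combinatorial Laplacian ``D - A``.
    """

    def __init__(self, adjacency: np.ndarray, normalized: bool = False):
        A = np.asarray(adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if not np.isfinite(A).all():
            raise ValueError("adjacency contains non-finite entries")
        if not np.allclose(A, A.T, atol=1e-12 * max(1.0, np.abs(A).max())):
            raise ValueError("adjacency must be symmetric")
        if (A < 0).any():
            raise ValueError("adjacency weights must be non-negative")
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0.0)
        self.adjacency = A
        self.normalized = bool(normalized)
        self._laplacian: np.ndarray | None = None
        self._decomp: SpectralDecomposition | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        if self._laplacian is None:
            self._laplacian = build_laplacian(self)
        return self._laplacian

    @property
    def decomposition(self) -> "SpectralDecomposition":
        if self._decomp is None:
            self._decomp = SpectralDecomposition.from_matrix(self.laplacian)
        return self._decomp

    @property
    def lam_max(self) -> float:
        return float(self.decomposition.eigenvalues[-1])

    def n_components(self, rtol: float = 1e-8) -> int:
        """Connected components, counted as (near-)zero Laplacian eigenvalues."""
        lam = self.decomposition.eigenvalues
        thresh = rtol * max(lam[-1], 1.0)
        return int(np.count_nonzero(lam < thresh))

    def __repr__(self) -> str:  # pragma: no cover
        kind = "normalized" if self.normalized else "plain"
        return f"Graph(n_nodes={self.n_nodes}, laplacian={kind})"


@dataclass(frozen=True)
class SpectralDecomposition:
    """Eigendecomposition ``M = U diag(lam) U^T``, eigenvalues ascending."""

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "SpectralDecomposition":
        lam, U = np.linalg.eigh(matrix)
        # eigh returns ascending order already; clip tiny negatives from rounding
        lam = np.where(np.abs(lam) < 1e-12 * max(abs(lam[-1]), 1.0), np.maximum(lam, 0.0), lam)
        return cls(eigenvectors=U, eigenvalues=lam)

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


def build_laplacian(graph: Graph) -> np.ndarray:
    """Return ``D - A``, or ``D^{-1/2}(D - A)D^{-1/2}`` for a normalized graph.

    Degree-zero (isolated) nodes give a zero row/column in both variants.
    """
    A = graph.adjacency
    d = A.sum(axis=1)
    L = np.diag(d) - A
    if graph.normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        L = dinv[:, None] * L * dinv[None, :]
    return L


def smoothness(f: np.ndarray, graph: Graph) -> float:
    """Laplacian quadratic form ``f^T L f`` (graph roughness of the signal)."""
    f = np.asarray(f, dtype=float)
    if f.shape != (graph.n_nodes,):
        raise ValueError(f"signal length {f.shape} does not match N={graph.n_nodes}")
    return float(f @ graph.laplacian @ f)


def gft(f: np.ndarray, decomp: SpectralDecomposition) -> np.ndarray:
    """Graph Fourier transform ``a = U^T f``."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != decomp.n:
        raise ValueError("signal length does not match decomposition size")
    return decomp.eigenvectors.T @ f


def igft(a: np.ndarray, decomp: SpectralDecomposition) -> np.ndarray:
    """Inverse graph Fourier transform ``f = U a``."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] != decomp.n:
        raise ValueError("coefficient length does not match decomposition size")
    return decomp.eigenvectors @ a


# ---------------------------------------------------------------------------
# Graph filters

def _eta_inverse(lam, beta, lam_max):
    return 1.0 / (1.0 + beta * lam)


def _eta_exponential(lam, beta, lam_max):
    return np.exp(-beta * lam)


def _eta_relu(lam, beta, lam_max):
    return np.maximum(1.0 - beta * lam, 0.0)


def _eta_sigmoid(lam, beta, lam_max):
    return 2.0 / (1.0 + np.exp(beta * lam))


def _eta_cosine(lam, beta, lam_max):
    if lam_max is None:
        raise ValueError("cosine filter requires the graph's largest eigenvalue")
    if lam_max <= 0:
        # edgeless graph: only lam = 0 occurs and eta(0) = 1
        return np.ones_like(np.asarray(lam, dtype=float))
    x = np.clip(np.asarray(lam, dtype=float) / lam_max, 0.0, 1.0)
    return np.cos(x * np.pi / 2.0) ** beta


def _eta_cutoff(lam, beta, lam_max):
    return np.where(np.asarray(lam, dtype=float) <= beta, 1.0, 0.0)


FILTER_FAMILIES: dict[str, Callable] = {
    "inverse": _eta_inverse,
    "exponential": _eta_exponential,
    "relu": _eta_relu,
    "sigmoid": _eta_sigmoid,
    "cosine": _eta_cosine,
    "cutoff": _eta_cutoff,
}


@dataclass(frozen=True)
class GraphFilter:
    """A low-pass spectral response ``eta(lam; beta)`` with ``eta(0) = 1``.

    Families: inverse ``(1+b*lam)^-1``, exponential ``exp(-b*lam)``, relu
    ``max(1-b*lam, 0)``, sigmoid ``2/(1+exp(b*lam))``, cosine
    ``cos(lam*pi/(2*lam_max))^b`` and cutoff ``1{lam <= b}``.
    """

    family: str
    beta: float

    def __post_init__(self):
        if self.family not in FILTER_FAMILIES:
            raise ValueError(
                f"unknown filter family {self.family!r}; "
                f"choose from {sorted(FILTER_FAMILIES)}"
            )
        if not (self.beta > 0):
            raise ValueError("beta must be positive")

    def response(self, lam, lam_max: float | None = None) -> np.ndarray:
        return eta(self, lam, lam_max=lam_max)


def eta(filt: GraphFilter, lam, lam_max: float | None = None):
    """Evaluate the filter response at eigenvalue(s) ``lam``."""
    lam_arr = np.asarray(lam, dtype=float)
    if (lam_arr < -1e-12).any():
        raise ValueError("graph-frequency lam must be non-negative")
    out = FILTER_FAMILIES[filt.family](np.maximum(lam_arr, 0.0), filt.beta, lam_max)
    return out if np.ndim(lam) else float(out)


def filter_matrix(graph: Graph, filt: GraphFilter) -> np.ndarray:
    """Return ``H = U eta(Lam) U^T`` for the graph's Laplacian spectrum."""
    dec = graph.decomposition
    h = filt.response(dec.eigenvalues, lam_max=graph.lam_max)
    return (dec.eigenvectors * h) @ dec.eigenvectors.T


def filter_matrix_squared(graph: Graph, filt: GraphFilter) -> np.ndarray:
    """Return ``H^2 = U eta(Lam)^2 U^T``, the spectral-prior covariance scale."""
    dec = graph.decomposition
    h = filt.response(dec.eigenvalues, lam_max=graph.lam_max)
    return (dec.eigenvectors * h**2) @ dec.eigenvectors.T


def sample_spectral_prior(
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    n_samples: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_samples`` signals from the prior ``N(0, H^2 / gamma)``.

    Each draw is the filter applied to white Gaussian noise of precision
    ``gamma``; returns an ``(n_samples, N)`` array.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    rng = np.random.default_rng(seed)
    H = filter_matrix(graph, filt)
    W = rng.standard_normal((n_samples, graph.n_nodes)) / np.sqrt(gamma)
    return W @ H  # H symmetric


# ---------------------------------------------------------------------------
# Cartesian product graphs


def cartesian_product(time_graph: Graph, space_graph: Graph) -> Graph:
    """Cartesian product of a time-like and a space-like graph.

    The product has ``N*T`` nodes and adjacency equal to the Kronecker sum
    ``A_T (+) A_N = A_T x I_N + I_T x A_N``; its Laplacian is ``L_T (+) L_N``
    and its spectrum is the multiset of pairwise eigenvalue sums.
    """
    At, An = time_graph.adjacency, space_graph.adjacency
    T, N = At.shape[0], An.shape[0]
    A = np.kron(At, np.eye(N)) + np.kron(np.eye(T), An)
    return Graph(A, normalized=False)


def is_separable_check(
    filt: GraphFilter,
    time_graph: Graph,
    space_graph: Graph,
    tol: float = 1e-12,
) -> tuple[bool, float]:
    """Check numerically whether ``eta(lam_T + lam_N) = eta(lam_T) eta(lam_N)``.

    Separable filters (e.g. the exponential family) let the product-graph
    filter factor as ``H = H_T x H_N``. Returns ``(separable, max_deviation)``.
    """
    lam_t = time_graph.decomposition.eigenvalues
    lam_n = space_graph.decomposition.eigenvalues
    lam_max_t = time_graph.lam_max
    lam_max_n = space_graph.lam_max
    lam_max_sum = lam_max_t + lam_max_n
    joint = filt.response(lam_t[:, None] + lam_n[None, :], lam_max=lam_max_sum)
    sep = (
        filt.response(lam_t, lam_max=lam_max_t)[:, None]
        * filt.response(lam_n, lam_max=lam_max_n)[None, :]
    )
    dev = float(np.abs(joint - sep).max())
    return dev < tol, dev
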