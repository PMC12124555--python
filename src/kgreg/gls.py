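"""Generalized least squares kernel graph regression.

Real sensor residuals are rarely white: readings at the same node are serially
correlated and different nodes share common shocks. This module models the
prediction error as matrix normal,

    vec(E) ~ N(0, Sigma_T x Sigma_N),

with the time factor constrained to an AR(1) correlation matrix
``(Sigma_T)_st = theta^|s-t|`` (so the Kronecker scale ambiguity is resolved)
and the node factor an arbitrary SPD covariance. Given the covariances, the
best linear unbiased estimator of the latent signal has the same
Hadamard-product structure as plain KGR after whitening by the covariance
eigenfactors; given the signal, ``theta`` has a closed-form MAP estimate (the
real root of a cubic) and ``Sigma_N`` is estimated by Rao-Blackwell
Ledoit-Wolf shrinkage of the autocorrelation-corrected ML covariance. The
full algorithm alternates the two until the signal estimate stabilises,
keeping O(N'^3 + T'^3) cost per iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .graphs import Graph, GraphFilter, filter_matrix_squared
from .kgr import (
    KernelSpec,
    SelectionPattern,
    _naive_solve,
    _validate_fit_inputs,
    gram_matrix,
)

__all__ = [
    "NoiseModel",
    "AR1Bands",
    "GLSFactorization",
    "GLSKGRResult",
    "sigma_t",
    "sigma_t_inv",
    "ar1_bands",
    "theta_cost",
    "theta_map",
    "sigma_ml",
    "rho_rblw",
    "sigma_n_shrinkage",
    "flip_flop",
    "fit_gls_blue",
    "fit_gls_naive",
    "fit_gls_kgr",
    "gls_cost",
]


# ---------------------------------------------------------------------------
# AR(1) time correlation


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not abs(theta) < 1.0:
        raise ValueError(f"AR(1) coefficient must satisfy |theta| < 1, got {theta}")
    return theta


def sigma_t(theta: float, t_prime: int) -> np.ndarray:
    """AR(1) correlation matrix with entries ``theta^|s-t|`` (unit diagonal)."""
    theta = _check_theta(theta)
    if t_prime < 1:
        raise ValueError("t_prime must be >= 1")
    col = theta ** np.arange(t_prime)
    return toeplitz(col)


@dataclass(frozen=True)
class AR1Bands:
    """Band matrices entering the tridiagonal AR(1) inverse.

    ``b1`` has ones on the first off-diagonals (zero diagonal); ``b2`` is the
    identity with its first and last diagonal entries zeroed.
    """

    b1: np.ndarray
    b2: np.ndarray


def ar1_bands(t_prime: int) -> AR1Bands:
    B1 = np.zeros((t_prime, t_prime))
    idx = np.arange(t_prime - 1)
    B1[idx, idx + 1] = 1.0
    B1[idx + 1, idx] = 1.0
    B2 = np.eye(t_prime)
    B2[0, 0] = 0.0
    B2[-1, -1] = 0.0
    return AR1Bands(b1=B1, b2=B2)


def sigma_t_inv(theta: float, t_prime: int) -> np.ndarray:
    """Tridiagonal inverse ``(I - theta B1 + theta^2 B2) / (1 - theta^2)``."""
    theta = _check_theta(theta)
    bands = ar1_bands(t_prime)
    return (np.eye(t_prime) - theta * bands.b1 + theta**2 * bands.b2) / (1.0 - theta**2)


# ---------------------------------------------------------------------------
# theta estimation


def _residual_traces(E: np.ndarray, sigma_n: np.ndarray):
    """Quadratic-form traces a, b, c of the whitened residuals.

    a = tr(E^T Sn^-1 E), b = tr(E^T Sn^-1 E B1), c = tr(E^T Sn^-1 E B2);
    computed in O(N'^2 T') without forming the T' x T' products.
    """
    M = np.linalg.solve(sigma_n, E)
    a = float(np.sum(E * M))
    b = 2.0 * float(np.sum(E[:, 1:] * M[:, :-1]))
    c = float(np.sum(E[:, 1:-1] * M[:, 1:-1]))
    return a, b, c


def theta_cost(
    theta,
    E: np.ndarray,
    sigma_n: np.ndarray,
    alpha: float,
) -> float | np.ndarray:
    """Negative log posterior of ``theta`` (up to a constant), vectorised.

    ``N'(T'-1) ln(1-theta^2) + tr(E^T Sn^-1 E St^-1(theta)) + N'T' alpha/(1-theta^2)``.
    The trace term uses the tridiagonal inverse, reducing to
    ``(a - theta b + theta^2 c) / (1 - theta^2)``.
    """
    th = np.asarray(theta, dtype=float)
    if (np.abs(th) >= 1.0).any():
        raise ValueError("theta must lie in (-1, 1)")
    n_prime, t_prime = E.shape
    a, b, c = _residual_traces(E, sigma_n)
    one_m = 1.0 - th**2
    cost = (
        n_prime * (t_prime - 1) * np.log(one_m)
        + (a - th * b + th**2 * c) / one_m
        + n_prime * t_prime * alpha / one_m
    )
    return cost if np.ndim(theta) else float(cost)


#: grid used by the fallback minimiser when the cubic yields no feasible root
_THETA_GRID = np.linspace(-0.9999, 0.9999, 19999)


def theta_map(E: np.ndarray, sigma_n: np.ndarray, alpha: float) -> float:
    """MAP estimate of the AR(1) coefficient: real cubic root in (-1, 1).

    Stationarity enters through a prior ~ exp(-N'T' alpha / (2(1-theta^2)))
    that vanishes towards the unit roots. When several real roots are
    feasible the one minimising :func:`theta_cost` is returned; when none is
    (numerically possible for extreme residuals) a dense grid minimisation is
    used and a warning issued.
    """
    n_prime, t_prime = E.shape
    if t_prime < 2:
        raise ValueError("need at least two time points to estimate theta")
    a, b, c = _residual_traces(E, sigma_n)
    nt1 = n_prime * (t_prime - 1)
    # cubic: -nt1 th^3 + (b/2) th^2 + (nt1 - a - c - N'T' alpha) th + b/2 = 0
    coeffs = [-nt1, b / 2.0, nt1 - a - c - n_prime * t_prime * alpha, b / 2.0]
    roots = np.roots(coeffs)
    feasible = [
        float(r.real)
        for r in roots
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and abs(r.real) < 1.0 - 1e-12
    ]
    if not feasible:
        warnings.warn(
            "no real cubic root in (-1, 1); falling back to grid minimisation",
            RuntimeWarning,
        )
        costs = theta_cost(_THETA_GRID, E, sigma_n, alpha)
        return float(_THETA_GRID[np.argmin(costs)])
    if len(feasible) == 1:
        return feasible[0]
    costs = theta_cost(np.array(feasible), E, sigma_n, alpha)
    return feasible[int(np.argmin(costs))]


# ---------------------------------------------------------------------------
# Sigma_N estimation


def sigma_ml(E: np.ndarray, theta: float) -> np.ndarray:
    """Autocorrelation-corrected ML node covariance ``E St^-1(theta) E^T / T'``.

    Uses the banded AR(1) inverse so the cost is O(N'^2 T').
    """
    theta = _check_theta(theta)
    t_prime = E.shape[1]
    EB1E = E[:, 1:] @ E[:, :-1].T
    EB1E = EB1E + EB1E.T
    EB2E = E[:, 1:-1] @ E[:, 1:-1].T
    S = (E @ E.T - theta * EB1E + theta**2 * EB2E) / (1.0 - theta**2)
    S /= t_prime
    return 0.5 * (S + S.T)


def rho_rblw(sigma_ml_matrix: np.ndarray, n_prime: int, t_prime: int) -> float:
    """Rao-Blackwell Ledoit-Wolf shrinkage weight, clamped to [0, 1].

    rho = min[ ((T'-2)/T' tr(S^2) + tr(S)^2) / ((T'+2)(tr(S^2) - tr(S)^2/N')), 1 ].
    A sample covariance proportional to the identity makes the denominator
    vanish; then the shrinkage target coincides with the estimate and 1 is
    returned.
    """
    S = sigma_ml_matrix
    tr_s = float(np.trace(S))
    tr_s2 = float(np.sum(S * S))  # tr(S^2) for symmetric S
    denom = (t_prime + 2) * (tr_s2 - tr_s**2 / n_prime)
    if denom <= 1e-14 * max(tr_s**2, 1e-300):
        return 1.0
    num = (t_prime - 2) / t_prime * tr_s2 + tr_s**2
    return float(np.clip(num / denom, 0.0, 1.0))


def sigma_n_shrinkage(E: np.ndarray, theta: float, rho: float) -> np.ndarray:
    """Shrunk node covariance ``(1-rho) S_ML + (rho/N') tr(S_ML) I``.

    Convex combination of the high-variance ML estimate and the
    well-conditioned scaled identity; preserves the trace for every rho.
    Eigenvalues are floored at ``1e-10 tr/N'`` so downstream inverse square
    roots stay finite.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if not np.any(E):
        raise ValueError("residual matrix is identically zero; nothing to estimate")
    n_prime = E.shape[0]
    S = sigma_ml(E, theta)
    out = (1.0 - rho) * S + (rho / n_prime) * np.trace(S) * np.eye(n_prime)
    floor = 1e-10 * np.trace(out) / n_prime
    lam, Q = np.linalg.eigh(out)
    if lam[0] < floor:
        out = (Q * np.maximum(lam, floor)) @ Q.T
    return out


@dataclass
class NoiseModel:
    """Matrix-normal error law ``vec(E) ~ N(0, Sigma_T(theta) x Sigma_N)``."""

    theta: float
    alpha: float
    sigma_n: np.ndarray
    t_prime: int

    def __post_init__(self):
        _check_theta(self.theta)
        S = np.asarray(self.sigma_n, dtype=float)
        if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
            raise ValueError("sigma_n must be symmetric")
        self.sigma_n = 0.5 * (S + S.T)

    @property
    def n_prime(self) -> int:
        return self.sigma_n.shape[0]

    def sigma_t_matrix(self) -> np.ndarray:
        return sigma_t(self.theta, self.t_prime)

    @classmethod
    def identity(cls, n_prime: int, t_prime: int, alpha: float = 0.1) -> "NoiseModel":
        return cls(theta=0.0, alpha=alpha, sigma_n=np.eye(n_prime), t_prime=t_prime)


def flip_flop(
    E: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[NoiseModel, int, bool]:
    """Alternating MAP estimation of ``(theta, Sigma_N)`` from residuals.

    From ``Sigma_N = I, theta = 0``: update theta by the cubic MAP given
    Sigma_N, then Sigma_N by RBLW-shrunk ML given theta, until both changes
    fall below ``tol`` (absolute in theta, relative Frobenius in Sigma_N).

    Returns ``(noise_model, n_iterations, converged)``.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("E must be at least 2 x 2")
    if not np.isfinite(E).all():
        raise ValueError("E contains non-finite entries")
    n_prime, t_prime = E.shape
    theta = 0.0
    sigma_n = np.eye(n_prime)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_new = theta_map(E, sigma_n, alpha)
        S = sigma_ml(E, theta_new)
        rho = rho_rblw(S, n_prime, t_prime)
        sigma_n_new = sigma_n_shrinkage(E, theta_new, rho)
        d_theta = abs(theta_new - theta)
        d_sigma = np.linalg.norm(sigma_n_new - sigma_n) / max(
            np.linalg.norm(sigma_n), 1e-300
        )
        theta, sigma_n = theta_new, sigma_n_new
        if d_theta < tol and d_sigma < tol:
            converged = True
            break
    model = NoiseModel(theta=theta, alpha=alpha, sigma_n=sigma_n, t_prime=t_prime)
    return model, it, converged


# ---------------------------------------------------------------------------
# GLS BLUE estimator


@dataclass
class GLSFactorization:
    """Whitened spectral factors behind the GLS BLUE solution."""

    psi: np.ndarray
    lam_sigma_t: np.ndarray
    phi: np.ndarray
    lam_sigma_n: np.ndarray
    u_bar: np.ndarray
    v_bar: np.ndarray
    lam_h: np.ndarray
    lam_k: np.ndarray
    b_matrix: np.ndarray
    c_matrix: np.ndarray
    y_bar: np.ndarray
    j_matrix: np.ndarray


def _spd_eig(M: np.ndarray, name: str):
    lam, Q = np.linalg.eigh(0.5 * (M + M.T))
    if lam[0] < 1e-12 * max(np.trace(M), 1e-300):
        raise ValueError(f"{name} is not positive definite (min eig {lam[0]:.3e})")
    return lam, Q


def _gls_core(Y, K, H2, gamma, sigma_n, sigma_t_mat, selection):
    nodes, times = selection.observed_nodes, selection.observed_times
    lam_sn, Phi = _spd_eig(sigma_n, "sigma_n")
    lam_st, Psi = _spd_eig(sigma_t_mat, "sigma_t")
    isq_n = 1.0 / np.sqrt(lam_sn)
    isq_t = 1.0 / np.sqrt(lam_st)

    K_bar = K[np.ix_(times, times)]
    H2_bar = H2[np.ix_(nodes, nodes)]
    Kw = (isq_t[:, None] * Psi.T) @ K_bar @ (Psi * isq_t[None, :])
    Hw = (isq_n[:, None] * Phi.T) @ H2_bar @ (Phi * isq_n[None, :])
    lam_k, V_bar = np.linalg.eigh(0.5 * (Kw + Kw.T))
    lam_h, U_bar = np.linalg.eigh(0.5 * (Hw + Hw.T))
    lam_k = np.maximum(lam_k, 0.0)
    lam_h = np.maximum(lam_h, 0.0)

    J = 1.0 / (gamma + np.outer(lam_h, lam_k))
    B = H2[:, nodes] @ (Phi * isq_n[None, :]) @ U_bar
    C = K[:, times] @ (Psi * isq_t[None, :]) @ V_bar
    Y_bar = U_bar.T @ (isq_n[:, None] * (Phi.T @ Y @ Psi) * isq_t[None, :]) @ V_bar
    F = B @ (J * Y_bar) @ C.T
    fac = GLSFactorization(
        psi=Psi, lam_sigma_t=lam_st, phi=Phi, lam_sigma_n=lam_sn,
        u_bar=U_bar, v_bar=V_bar, lam_h=lam_h, lam_k=lam_k,
        b_matrix=B, c_matrix=C, y_bar=Y_bar, j_matrix=J,
    )
    return F, fac


def fit_gls_blue(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    sigma_n: np.ndarray,
    sigma_t_matrix: np.ndarray,
    selection: SelectionPattern,
    kernel: KernelSpec = KernelSpec(),
) -> tuple[np.ndarray, GLSFactorization]:
    """Best linear unbiased estimate of ``F`` for known error covariances.

    Whitens the observed blocks by the covariance eigenfactors, then applies
    the same Hadamard-product solve as plain KGR; with identity covariances it
    reduces exactly to :func:`kgreg.kgr.fit_kgr`. All dense
    eigendecompositions are of size at most ``max(N', T')``.
    """
    Y = _validate_fit_inputs(Y, gamma, selection)
    K = gram_matrix(X, kernel)
    H2 = filter_matrix_squared(graph, filt)
    return _gls_core(Y, K, H2, gamma, sigma_n, sigma_t_matrix, selection)


def fit_gls_naive(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    sigma_n: np.ndarray,
    sigma_t_matrix: np.ndarray,
    selection: SelectionPattern,
    kernel: KernelSpec = KernelSpec(),
) -> np.ndarray:
    """Dense Kronecker-assembled GLS oracle (guarded at ``N*T <= 2000``)."""
    Y = _validate_fit_inputs(Y, gamma, selection)
    K = gram_matrix(X, kernel)
    H2 = filter_matrix_squared(graph, filt)
    return _naive_solve(Y, K, H2, gamma, selection, sigma_n=sigma_n, sigma_t=sigma_t_matrix)


def gls_cost(
    F: np.ndarray,
    Y: np.ndarray,
    K: np.ndarray,
    H2: np.ndarray,
    gamma: float,
    sigma_n: np.ndarray,
    sigma_t_matrix: np.ndarray,
    selection: SelectionPattern,
) -> float:
    """GLS objective: whitened data misfit plus the Kronecker-prior penalty.

    ``tr((Y - S_N F S_T^T)^T Sn^-1 (Y - S_N F S_T^T) St^-1) + gamma tr(K^-1 F^T H^-2 F)``.
    The prior term inverts jittered ``K`` and ``H^2`` (diagnostic use only).
    """
    nodes, times = selection.observed_nodes, selection.observed_times
    R = Y - F[np.ix_(nodes, times)]
    misfit = float(
        np.trace(R.T @ np.linalg.solve(sigma_n, R) @ np.linalg.inv(sigma_t_matrix))
    )
    jit = 1e-10
    KiF = np.linalg.solve(K + jit * np.eye(K.shape[0]), F.T)
    H2iF = np.linalg.solve(H2 + jit * np.eye(H2.shape[0]), F)
    prior = gamma * float(np.sum(KiF.T * H2iF))
    return misfit + prior


# ---------------------------------------------------------------------------
# Full alternating algorithm


@dataclass
class GLSKGRResult:
    """Output of the alternating GLS-KGR algorithm."""

    f_star: np.ndarray
    noise: NoiseModel
    outer_iterations: int
    inner_iterations: int
    converged: bool
    history: list = field(default_factory=list)
    factorization: GLSFactorization | None = None
    final_cost: float = np.nan
    diagnostic: str = ""

    @property
    def total_iterations(self) -> int:
        return self.outer_iterations + self.inner_iterations


def fit_gls_kgr(
    Y: np.ndarray,
    X: np.ndarray,
    graph: Graph,
    filt: GraphFilter,
    gamma: float,
    alpha: float = 0.1,
    tol_outer: float = 1e-6,
    tol_inner: float = 1e-8,
    max_outer: int = 50,
    max_inner: int = 100,
    selection: SelectionPattern | None = None,
    kernel: KernelSpec = KernelSpec(),
) -> GLSKGRResult:
    """Joint estimation of the latent signal and the matrix-normal noise law.

    Alternates the BLUE signal estimate (given the current ``theta, Sigma_N``)
    with flip-flop covariance estimation on the residuals
    ``E = Y - S_N F* S_T^T``, starting from white noise
    (``Sigma_N = I, theta = 0``). Stops when the relative Frobenius change of
    ``F*`` drops below ``tol_outer``. If the GLS objective (evaluated at the
    current covariance estimates) rises while the signal updates grow, on
    three consecutive outer iterations, the loop stops early, flagged
    unconverged with a diagnostic. (A rising cost alone is not divergence:
    the objective is evaluated at freshly *updated* covariances, so small
    increases occur even on healthy, converging runs.)
    """
    if selection is None:
        raise ValueError("a SelectionPattern is required")
    Y = _validate_fit_inputs(Y, gamma, selection)
    K = gram_matrix(X, kernel)
    H2 = filter_matrix_squared(graph, filt)
    n_prime, t_prime = selection.n_prime, selection.t_prime
    nodes, times = selection.observed_nodes, selection.observed_times

    noise = NoiseModel.identity(n_prime, t_prime, alpha=alpha)
    F_prev = None
    inner_total = 0
    history: list[dict] = []
    converged = False
    diagnostic = ""
    n_cost_rises = 0
    prev_cost = np.inf
    prev_rel = np.inf
    fac = None
    outer = 0
    for outer in range(1, max_outer + 1):
        st_mat = noise.sigma_t_matrix()
        F, fac = _gls_core(Y, K, H2, gamma, noise.sigma_n, st_mat, selection)
        E = Y - F[np.ix_(nodes, times)]
        noise, n_inner, _ = flip_flop(E, alpha, tol=tol_inner, max_iter=max_inner)
        inner_total += n_inner
        cost = gls_cost(F, Y, K, H2, gamma, noise.sigma_n, noise.sigma_t_matrix(), selection)
        history.append(
            {
                "outer": outer,
                "theta": noise.theta,
                "sigma_n_fro": float(np.linalg.norm(noise.sigma_n)),
                "inner_iterations": n_inner,
                "cost": cost,
            }
        )
        rel = np.inf
        if F_prev is not None:
            rel = np.linalg.norm(F - F_prev) / max(np.linalg.norm(F_prev), 1e-300)
            history[-1]["rel_change"] = rel
            if rel < tol_outer:
                F_prev = F
                converged = True
                break
        diverging_step = cost > prev_cost and rel > prev_rel
        n_cost_rises = n_cost_rises + 1 if diverging_step else 0
        if n_cost_rises >= 3:
            diagnostic = (
                f"objective rose on {n_cost_rises} consecutive outer iterations "
                f"(last cost {cost:.6g}); stopping early"
            )
            warnings.warn("GLS-KGR diverging: " + diagnostic, RuntimeWarning)
            F_prev = F
            break
        prev_cost = cost
        prev_rel = rel
        F_prev = F

    return GLSKGRResult(
        f_star=F_prev,
        noise=noise,
        outer_iterations=outer,
        inner_iterations=inner_total,
        converged=converged,
        history=history,
        factorization=fac,
        final_cost=history[-1]["cost"] if history else np.nan,
        diagnostic=diagnostic,
    )
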