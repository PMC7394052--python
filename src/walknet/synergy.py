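"""Muscle-synergy extraction by multiplicative-update NMF with rank
selection and per-synergy contribution measures.

The envelope matrix ``X`` (SC*N rows x 26 muscle columns) is factorized as
X^T ~= W A with non-negative muscle weights W (26 x m) and activation
waveforms A (m x SC*N).  The reconstruction quality

    lambda(m) = (1 - ||X - W A||_F^2 / ||X||_F^2) * 100%

drives rank selection: the smallest m with lambda(m) >= lambda_cutoff while
every rank up to m still adds >= delta_lambda_cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynergyModel",
    "RankSelectionCriteria",
    "nmf",
    "reconstruction_quality",
    "synergy_contribution",
    "select_rank",
    "order_synergies",
    "fit",
]

_EPS = 1e-12


@dataclass
class SynergyModel:
    W: np.ndarray  # (n_muscles, m), unit-max columns
    A: np.ndarray  # (m, SC*N)
    m: int
    lambda_total: float  # %
    lambda_per_synergy: np.ndarray  # (m,), %
    ordering: np.ndarray | None = None  # permutation applied, 0-based
    lambda_profile: dict | None = None  # rank -> lambda %


@dataclass
class RankSelectionCriteria:
    lambda_cutoff: float = 80.0
    delta_lambda_cutoff: float = 1.5
    max_rank: int = 10
    n_restarts: int = 20
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if self.lambda_cutoff <= 0 or self.delta_lambda_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


# --------------------------------------------------------------------------
# core multiplicative-update engine (V ~= W H, V non-negative, rows x cols)
# --------------------------------------------------------------------------

def _mu_nmf_once(
    V: np.ndarray,
    m: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    n, t = V.shape
    if init is not None:
        W, H = init[0].copy(), init[1].copy()
    else:
        scale = np.sqrt(V.mean() / m)
        W = scale * rng.random((n, m)) + _EPS
        H = scale * rng.random((m, t)) + _EPS
    norm_v = np.linalg.norm(V)
    err_prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(V - W @ H)
        if err_prev - err < tol * norm_v:
            break
        err_prev = err
    return W, H, float(err)


def _best_nmf(
    V: np.ndarray,
    m: int,
    n_restarts: int,
    seed: int,
    tol: float,
    max_iter: int,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    best = None
    inits = [None] * n_restarts
    if warm is not None:
        inits.append(warm)
    for init in inits:
        W, H, err = _mu_nmf_once(V, m, rng, tol, max_iter, init=init)
        if best is None or err < best[2]:
            best = (W, H, err)
    return best[0], best[1]


def _normalize_unit_max(W: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-maximum W columns with compensating scale pushed into A."""
    W, A = W.copy(), A.copy()
    peaks = W.max(axis=0)
    nz = peaks > 0
    W[:, nz] /= peaks[nz]
    A[nz, :] *= peaks[nz, None]
    return W, A


# --------------------------------------------------------------------------
# public operations (X oriented time x muscles, as stored in EnvelopeMatrix)
# --------------------------------------------------------------------------

def _check_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not np.any(X > 0):
        raise ValueError("X is all zeros: degenerate factorization")
    return X


def nmf(
    X: np.ndarray,
    m: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-restarts multiplicative-update NMF of X^T: returns W
    (muscles x m, unit-max columns) and A (m x time)."""
    X = _check_X(X)
    if not 1 <= m <= min(X.shape):
        raise ValueError(f"rank {m} out of range")
    V = X.T
    W, A = _best_nmf(V, m, n_restarts, seed, tol, max_iter, warm=warm)
    return _normalize_unit_max(W, A)


def reconstruction_quality(X: np.ndarray, W: np.ndarray, A: np.ndarray) -> float:
    """lambda = (1 - ||X - W A||_F^2 / ||X||_F^2) * 100, on X^T orientation."""
    X = np.asarray(X, dtype=float)
    norm2 = np.linalg.norm(X) ** 2
    if norm2 == 0:
        raise ValueError("||X|| = 0: reconstruction quality undefined")
    resid2 = np.linalg.norm(X.T - np.asarray(W) @ np.asarray(A)) ** 2
    return float((1.0 - resid2 / norm2) * 100.0)


def synergy_contribution(X: np.ndarray, w_s: np.ndarray, a_s: np.ndarray) -> float:
    """Contribution of a single synergy: lambda_s from the lone rank-1 term
    w_s a_s.  May be negative for a poor lone approximation."""
    w = np.asarray(w_s, dtype=float).reshape(-1, 1)
    a = np.asarray(a_s, dtype=float).reshape(1, -1)
    return reconstruction_quality(X, w, a)


def select_rank(
    X: np.ndarray, criteria: RankSelectionCriteria
) -> tuple[int, dict, dict]:
    """Rank by the dual-cutoff rule; returns (m, lambda profile, factors).

    ``factors`` maps rank -> (W, A) so the selected model need not be refit.
    Each rank is additionally warm-started from the previous rank's solution
    (plus a small random extra column), making the profile non-decreasing.
    """
    X = _check_X(X)
    max_rank = min(criteria.max_rank, *X.shape)
    profile: dict[int, float] = {}
    factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rng = np.random.default_rng(criteria.seed)
    prev = None
    for m in range(1, max_rank + 1):
        warm = None
        if prev is not None:
            Wp, Ap = prev
            extra_w = 0.01 * rng.random((Wp.shape[0], 1)) + _EPS
            extra_a = 0.01 * rng.random((1, Ap.shape[1])) + _EPS
            warm = (np.hstack([Wp, extra_w]), np.vstack([Ap, extra_a]))
        W, A = nmf(
            X, m,
            n_restarts=criteria.n_restarts,
            seed=criteria.seed + m,
            tol=criteria.tol,
            max_iter=criteria.max_iter,
            warm=warm,
        )
        profile[m] = reconstruction_quality(X, W, A)
        factors[m] = (W, A)
        prev = (W, A)

    for m in range(1, max_rank + 1):
        increments_ok = all(
            profile[r] - profile[r - 1] >= criteria.delta_lambda_cutoff
            for r in range(2, m + 1)
        )
        if profile[m] >= criteria.lambda_cutoff and increments_ok:
            return m, profile, factors
    warnings.warn(
        "no rank satisfies the selection rule; returning max_rank", stacklevel=2
    )
    return max_rank, profile, factors


def _circular_mean_pct(locations_pct: np.ndarray) -> float:
    ang = 2 * np.pi * np.asarray(locations_pct, dtype=float) / 100.0
    mean = np.angle(np.mean(np.exp(1j * ang)))
    return float((mean % (2 * np.pi)) * 100.0 / (2 * np.pi))


def order_synergies(model: SynergyModel, n: int) -> SynergyModel:
    """Sort synergies by the circular-mean gait-cycle position of their
    per-stride activation maxima; ties broken by dominant-muscle index."""
    A = model.A
    if A.shape[1] % n != 0:
        raise ValueError("activation length is not a multiple of the stride length")
    sc = A.shape[1] // n
    strides = A.reshape(model.m, sc, n)
    peak_pct = np.array(
        [_circular_mean_pct(np.argmax(strides[s], axis=1) * 100.0 / n)
         for s in range(model.m)]
    )
    tiebreak = np.argmax(model.W, axis=0)
    order = np.lexsort((tiebreak, np.round(peak_pct, 6)))
    return SynergyModel(
        W=model.W[:, order],
        A=model.A[order, :],
        m=model.m,
        lambda_total=model.lambda_total,
        lambda_per_synergy=np.asarray(model.lambda_per_synergy)[order],
        ordering=order,
        lambda_profile=model.lambda_profile,
    )


def fit(
    X: np.ndarray, criteria: RankSelectionCriteria | None = None, n: int = 200
) -> SynergyModel:
    """Full synergy analysis: rank selection, contributions, peak ordering."""
    criteria = criteria or RankSelectionCriteria()
    m, profile, factors = select_rank(X, criteria)
    W, A = factors[m]
    lam = profile[m]
    lam_s = np.array(
        [synergy_contribution(X, W[:, s], A[s, :]) for s in range(m)]
    )
    model = SynergyModel(
        W=W, A=A, m=m, lambda_total=lam, lambda_per_synergy=lam_s,
        lambda_profile=profile,
    )
    if A.shape[1] % n == 0:
        model = order_synergies(model, n)
    return model
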