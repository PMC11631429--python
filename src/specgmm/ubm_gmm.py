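"""Universal Background Model GMM: EM training, posteriors, MAP mean adaptation.

A single diagonal-covariance Gaussian mixture (the UBM) is fitted by
expectation-maximization on window spectra pooled across all training
sequences.  Each sequence is then represented by MAP-adapting only the
component means toward that sequence's responsibility-weighted frame means:

    n_k   = sum_t P(k | x_t)
    E_k   = (1 / n_k) sum_t P(k | x_t) x_t
    alpha = n_k / (n_k + r)
    mu'_k = alpha * E_k + (1 - alpha) * mu_k

with relevance factor r controlling how far per-sequence data pulls the means
away from the UBM prior.  Concatenating the K adapted means gives a fixed
(K x D)-dimensional mean supervector per sequence, regardless of sequence
length.  This mirrors the adapted-GMM construction long used for speaker
verification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

__all__ = [
    "GMMParams",
    "MeanSupervector",
    "fit_ubm",
    "log_posteriors",
    "posteriors",
    "map_adapt_means",
    "save_gmm",
    "load_gmm",
]

DEFAULT_RELEVANCE = 16.0
VARIANCE_FLOOR_FACTOR = 1e-4


@dataclass
class GMMParams:
    """Diagonal-covariance Gaussian mixture parameters (UBM or adapted model)."""

    weights: np.ndarray   # (K,)
    means: np.ndarray     # (K, D)
    variances: np.ndarray  # (K, D) diagonal covariances
    log_likelihoods: list[float] = field(default_factory=list, repr=False)
    seed: int | None = None

    @property
    def K(self) -> int:
        return int(self.weights.shape[0])

    @property
    def D(self) -> int:
        return int(self.means.shape[1])

    def validate(self, atol: float = 1e-9) -> None:
        if not np.all(self.weights >= 0) or abs(self.weights.sum() - 1.0) > atol:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if not np.all(self.variances > 0):
            raise ValueError("variances must be strictly positive")


@dataclass(frozen=True)
class MeanSupervector:
    """Concatenated adapted means for one sequence (component 1 first)."""

    id: str
    vector: np.ndarray
    K: int
    D: int


# ---------------------------------------------------------------------------
# Densities


def _log_gauss(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Log density of each row of X under each diagonal Gaussian: (N, K)."""
    # log N(x; mu, diag(v)) = -0.5 [ D log(2pi) + sum log v + sum (x-mu)^2 / v ]
    const = -0.5 * (means.shape[1] * np.log(2.0 * np.pi) + np.log(variances).sum(axis=1))
    # (N, K) quadratic term via expansion to avoid a (N, K, D) intermediate
    inv = 1.0 / variances
    quad = (
        (X**2) @ inv.T
        - 2.0 * X @ (means * inv).T
        + np.sum(means**2 * inv, axis=1)
    )
    return const - 0.5 * quad


def _log_resp(gmm: GMMParams, X: np.ndarray):
    lg = _log_gauss(X, gmm.means, gmm.variances) + np.log(gmm.weights)
    norm = logsumexp(lg, axis=1, keepdims=True)
    return lg - norm, norm.sum()


def log_posteriors(gmm: GMMParams, frames: np.ndarray) -> np.ndarray:
    """Log responsibilities of each component for each frame, shape (N, K)."""
    X = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if X.shape[1] != gmm.D:
        raise ValueError(f"frame dimension {X.shape[1]} != model D {gmm.D}")
    lr, _ = _log_resp(gmm, X)
    return lr


def posteriors(gmm: GMMParams, frame: np.ndarray) -> np.ndarray:
    """K-dim posterior (responsibility) vector for a single frame; sums to 1.

    Computed in log space for numerical stability.
    """
    return np.exp(log_posteriors(gmm, frame))[0]


# ---------------------------------------------------------------------------
# EM training


def _em_once(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    var_floor: np.ndarray,
    global_var: np.ndarray,
) -> GMMParams:
    N, D = X.shape
    seed = int(rng.integers(0, 2**31 - 1))
    means, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    weights = np.full(K, 1.0 / K)
    variances = np.tile(np.maximum(global_var, var_floor), (K, 1))
    gmm = GMMParams(weights=weights, means=means, variances=variances, seed=seed)

    prev_ll = -np.inf
    for it in range(max_iter):
        log_r, total_ll = _log_resp(gmm, X)
        gmm.log_likelihoods.append(float(total_ll))
        resp = np.exp(log_r)
        nk = resp.sum(axis=0)

        # degenerate component: reseed from a random data point
        dead = nk < 1e-10
        if np.any(dead):
            for k in np.flatnonzero(dead):
                idx = int(rng.integers(0, N))
                gmm.means[k] = X[idx]
                gmm.variances[k] = np.maximum(global_var, var_floor)
                logger.info("EM iteration %d: reseeded empty component %d", it, k)
            nk = np.maximum(nk, 1e-10)

        gmm.weights = nk / nk.sum()
        gmm.means = (resp.T @ X) / nk[:, None]
        ex2 = (resp.T @ (X**2)) / nk[:, None]
        gmm.variances = np.maximum(ex2 - gmm.means**2, var_floor)

        if prev_ll > -np.inf:
            rel = (total_ll - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < tol:
                break
        prev_ll = total_ll

    _, final_ll = _log_resp(gmm, X)
    gmm.log_likelihoods.append(float(final_ll))
    return gmm


def fit_ubm(
    frames: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_init: int = 3,
    variance_floor_factor: float = VARIANCE_FLOOR_FACTOR,
) -> GMMParams:
    """Fit the K-component diagonal-covariance UBM by EM on pooled frames.

    Initialization is k-means++ seeded from ``seed``; ``n_init`` restarts are
    run and the model with the best final log-likelihood is kept.  Variances
    are floored at ``variance_floor_factor`` times the per-dimension global
    variance.  The per-iteration total log-likelihood trace is recorded on the
    returned model.
    """
    X = np.asarray(frames, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("frames must be a 2-D array (n_frames, D)")
    N = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K ({K}) exceeds number of frames ({N})")

    global_var = X.var(axis=0)
    var_floor = np.maximum(variance_floor_factor * global_var, 1e-12)

    rng = np.random.default_rng(seed)
    best: GMMParams | None = None
    for _ in range(n_init):
        cand = _em_once(X, K, rng, max_iter, tol, var_floor, global_var)
        if best is None or cand.log_likelihoods[-1] > best.log_likelihoods[-1]:
            best = cand
    assert best is not None
    best.seed = seed
    best.validate(atol=1e-6)
    logger.info(
        "UBM fit: K=%d, %d frames, %d EM iterations, final LL %.4f",
        K, N, len(best.log_likelihoods) - 1, best.log_likelihoods[-1],
    )
    return best


# ---------------------------------------------------------------------------
# MAP adaptation


def map_adapt_means(
    ubm: GMMParams,
    sequence_frames: np.ndarray,
    relevance_r: float = DEFAULT_RELEVANCE,
    sequence_id: str = "",
) -> tuple[GMMParams, MeanSupervector]:
    """MAP-adapt only the means of the UBM toward one sequence's frames.

    Components that receive zero total responsibility keep the UBM mean
    (alpha_k = 0 by the convention 0 / (0 + r)).  Weights and variances are
    left untouched.  Returns the adapted model and the (K x D) mean
    supervector (component 1 means first).
    """
    X = np.atleast_2d(np.asarray(sequence_frames, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("MAP adaptation requires at least one frame")
    if relevance_r < 0:
        raise ValueError("relevance_r must be >= 0")

    resp = np.exp(log_posteriors(ubm, X))        # (N, K)
    nk = resp.sum(axis=0)                        # (K,)
    weighted = resp.T @ X                        # (K, D)

    denom = nk + relevance_r
    with np.errstate(invalid="ignore", divide="ignore"):
        Ek = np.where(nk[:, None] > 0, weighted / np.where(nk == 0, 1.0, nk)[:, None], 0.0)
        alpha = np.where(denom > 0, nk / np.where(denom == 0, 1.0, denom), 1.0)

    adapted_means = alpha[:, None] * Ek + (1.0 - alpha[:, None]) * ubm.means
    adapted = GMMParams(
        weights=ubm.weights.copy(),
        means=adapted_means,
        variances=ubm.variances.copy(),
        seed=ubm.seed,
    )
    sv = MeanSupervector(
        id=sequence_id, vector=adapted_means.reshape(-1).copy(), K=ubm.K, D=ubm.D
    )
    return adapted, sv


# ---------------------------------------------------------------------------
# Serialization (portable JSON layout, round-trip exact)


def save_gmm(gmm: GMMParams, path, config: dict | None = None) -> None:
    payload = {
        "K": gmm.K,
        "D": gmm.D,
        "weights": gmm.weights.tolist(),
        "means": gmm.means.tolist(),
        "variances": gmm.variances.tolist(),
        "log_likelihoods": list(gmm.log_likelihoods),
        "seed": gmm.seed,
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_gmm(path) -> GMMParams:
    with open(path) as fh:
        payload = json.load(fh)
    gmm = GMMParams(
        weights=np.asarray(payload["weights"], dtype=np.float64),
        means=np.asarray(payload["means"], dtype=np.float64),
        variances=np.asarray(payload["variances"], dtype=np.float64),
        log_likelihoods=[float(v) for v in payload.get("log_likelihoods", [])],
        seed=payload.get("seed"),
    )
    gmm.validate(atol=1e-6)
    return gmm
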