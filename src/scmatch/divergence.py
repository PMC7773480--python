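"""kNN-based Kullback-Leibler divergence between two sets of latent codes.

Integration quality cannot be read off adversarial losses, so the package
scores a latent space by a nonparametric divergence between the code clouds
of two technologies: for each point, the ratio of its k-th nearest-neighbor
distance within its own sample to that within the other sample estimates the
local density ratio.  The symmetrized average of the two directed estimates
is the *divergence score*; values near zero mean the technologies are well
mixed in latent space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datasets import LatentCodes

__all__ = ["DivergenceEstimate", "knn_kl", "divergence_score", "select_model"]

#: floor applied to nearest-neighbor distances before taking logs, so that
#: duplicated points cannot produce infinite estimates
DISTANCE_FLOOR = 1e-12


@dataclass
class DivergenceEstimate:
    """Symmetric divergence between two code sets."""

    value: float
    k: int
    n_p: int
    n_q: int

    def __float__(self) -> float:
        return self.value


def _as_array(points) -> np.ndarray:
    if isinstance(points, LatentCodes):
        return points.codes
    a = np.asarray(points, dtype=float)
    if a.ndim != 2:
        raise ValueError("point sets must be 2-D arrays (points x dimensions)")
    return a


def knn_kl(P, Q, k: int = 5) -> float:
    """Directed kNN estimate of KL(P || Q) in nats.

    For each ``p_i`` in ``P``, ``nu_k`` is the Euclidean distance to its k-th
    nearest neighbor in ``Q`` and ``rho_k`` the distance to its k-th nearest
    neighbor within ``P`` excluding ``p_i`` itself.  The estimate is

        (d / |P|) * sum_i log(nu_k / rho_k) + log(|P| / (|Q| - 1))

    with ``d`` the dimension.  Distances are floored at a tiny constant so
    coincident points stay finite.
    """
    P, Q = _as_array(P), _as_array(Q)
    if P.shape[1] != Q.shape[1]:
        raise ValueError("P and Q must share a dimension")
    n, m, d = P.shape[0], Q.shape[0], P.shape[1]
    if k >= n:
        raise ValueError(f"k={k} requires |P| > k (got |P|={n})")
    if k > m:
        raise ValueError(f"k={k} requires |Q| >= k (got |Q|={m})")
    # self is its own 1st neighbor in P, so ask for k+1 there
    rho = cKDTree(P).query(P, k=[k + 1])[0][:, 0]
    nu = cKDTree(Q).query(P, k=[k])[0][:, 0]
    rho = np.maximum(rho, DISTANCE_FLOOR)
    nu = np.maximum(nu, DISTANCE_FLOOR)
    return float((d / n) * np.sum(np.log(nu / rho)) + np.log(n / (m - 1)))


def divergence_score(Zs, Zt, k: int = 5) -> DivergenceEstimate:
    """Symmetric divergence: the average of the two directed kNN estimates.

    Exactly symmetric in its arguments by construction.
    """
    P, Q = _as_array(Zs), _as_array(Zt)
    value = 0.5 * knn_kl(P, Q, k=k) + 0.5 * knn_kl(Q, P, k=k)
    return DivergenceEstimate(value=value, k=k, n_p=P.shape[0], n_q=Q.shape[0])


def select_model(
    runs: list[tuple],
    div_threshold: float,
    rec_threshold: float,
):
    """Pick the best hyperparameter run by divergence under dual thresholds.

    ``runs`` holds ``(config, divergence, reconstruction_error)`` triples.  A
    run is *successful* when both its divergence and reconstruction error
    fall below the respective thresholds; among successful runs the one with
    minimal divergence wins (ties broken by lower reconstruction error).
    Returns ``None`` when no run qualifies — no arbitrary pick is made.
    """
    if not runs:
        raise ValueError("runs must not be empty")
    passing = [
        r for r in runs if float(r[1]) <= div_threshold and float(r[2]) <= rec_threshold
    ]
    if not passing:
        return None
    return min(passing, key=lambda r: (float(r[1]), float(r[2])))
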