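"""Classification-certainty and profile-distinctiveness metrics.

All entropies use the natural logarithm.  The entropy reduction statistic
compares a model's total classification entropy to the maximum possible
(n log T); values near 1 mean participants are assigned to profiles with
near certainty, values near 0 mean the assignment is uninformative.
Profile distinctiveness is the precision-weighted Euclidean (Mahalanobis)
distance between profile mean vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DistanceSummary:
    """Pairwise profile distances: full symmetric matrix, min and mean
    over the T(T-1)/2 unordered pairs."""

    pairwise: np.ndarray
    min_offdiag: float
    mean_offdiag: float


def classification_entropy(phi, atol: float = 1e-9) -> float:
    """Entropy (nats) of one participant's profile-membership probabilities.

    -sum_t phi_t log(phi_t), with 0 log 0 = 0.  Entries must be nonnegative
    and sum to 1 within ``atol``.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("membership probabilities must be nonnegative")
    if abs(phi.sum() - 1.0) > atol:
        raise ValueError(f"probabilities sum to {phi.sum()!r}, not 1")
    pos = phi[phi > 0]
    return float(-(pos * np.log(pos)).sum())


def entropy_reduction(resp: np.ndarray) -> float:
    """Proportional entropy reduction of an n x T responsibility matrix.

    1 - (total entropy) / (n log T): 1 when every row is one-hot (total
    classification confidence), 0 when every row is uniform.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.ndim != 2:
        raise ValueError("expected an n x T matrix")
    n, T = resp.shape
    if T < 2:
        raise ValueError("entropy reduction is undefined for T = 1 (max entropy is zero)")
    if np.any(resp < 0) or np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each row must be a probability vector")
    with np.errstate(divide="ignore", invalid="ignore"):
        total = -np.sum(np.where(resp > 0, resp * np.log(resp), 0.0))
    return float(1.0 - total / (n * np.log(T)))


def mahalanobis_distance(mu_a, mu_b, xi) -> float:
    """Precision-weighted distance between two profile mean vectors:
    sqrt(sum_j xi_j (mu_{j,a} - mu_{j,b})^2)."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if not (mu_a.shape == mu_b.shape == xi.shape):
        raise ValueError("mu_a, mu_b, and xi must have equal lengths")
    if np.any(xi <= 0):
        raise ValueError("precisions must be strictly positive")
    return float(np.sqrt((xi * (mu_a - mu_b) ** 2).sum()))


def distance_summary(profiles) -> DistanceSummary:
    """Pairwise Mahalanobis distances between a fit's profiles.

    Accepts any object with ``means`` (T x m) and ``precisions`` (m); the
    fit's shared precisions weight every pair.
    """
    means = np.asarray(profiles.means, dtype=float)
    xi = np.asarray(profiles.precisions, dtype=float)
    T = means.shape[0]
    if T < 2:
        raise ValueError("need at least 2 profiles for pairwise distances")
    diff = means[:, None, :] - means[None, :, :]
    pairwise = np.sqrt((xi[None, None, :] * diff**2).sum(axis=2))
    iu = np.triu_indices(T, k=1)
    off = pairwise[iu]
    return DistanceSummary(
        pairwise=pairwise,
        min_offdiag=float(off.min()),
        mean_offdiag=float(off.mean()),
    )
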