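"""Graded response model: boundary/category probabilities, Fisher
information, and the marginal-reliability ↔ standard-error mapping.

All parameters are in the logistic metric (the bank's metric), so the
cumulative boundary curve is P*_k(θ) = logistic(αθ − t_k) with no extra
scaling constant.  θ is the latent distress score, standardized to the
population (mean 0, variance 1); working values are clamped to
[−THETA_MAX, THETA_MAX].
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.special import expit

from .bank import GRMItem, ItemBank

#: Working range of the latent trait.  Covers the plotted trait range with
#: margin; estimators clamp to ±THETA_MAX for stability.
THETA_MAX = 4.5


class PrecisionTarget:
    """A stopping precision, expressed equivalently as a marginal
    reliability r or a standard-error cutoff; on the unit-variance latent
    scale the two are linked by r = 1 − SE²."""

    __slots__ = ("marginal_reliability", "se_cutoff")

    def __init__(self, marginal_reliability: float | None = None,
                 se_cutoff: float | None = None):
        if (marginal_reliability is None) == (se_cutoff is None):
            raise ValueError("give exactly one of marginal_reliability, se_cutoff")
        if marginal_reliability is not None:
            self.se_cutoff = reliability_to_se(marginal_reliability)
            self.marginal_reliability = float(marginal_reliability)
        else:
            if se_cutoff <= 0:
                raise ValueError("se_cutoff must be positive")
            self.se_cutoff = float(se_cutoff)
            self.marginal_reliability = se_to_reliability(se_cutoff)

    def __repr__(self) -> str:
        return (f"PrecisionTarget(r={self.marginal_reliability:.4f}, "
                f"se={self.se_cutoff:.4f})")


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------

def boundary_prob(discrimination: float, threshold: float, theta) -> float | np.ndarray:
    """P*(θ) = 1 / (1 + exp(−(αθ − t))): probability of responding in or
    above the category boundary."""
    return expit(np.asarray(discrimination) * theta - threshold)


def boundary_probs_arrays(alpha: np.ndarray, thresholds: np.ndarray,
                          theta) -> np.ndarray:
    """Boundary probabilities for all items; shape (..., M, K−1)."""
    theta = np.asarray(theta, dtype=float)
    eta = alpha[:, None] * theta[..., None, None] - thresholds
    return expit(eta)


def category_probs_arrays(alpha: np.ndarray, thresholds: np.ndarray,
                          theta) -> np.ndarray:
    """Category probabilities P_k = P*_{k−1} − P*_k (with P*_0 = 1,
    P*_K = 0); shape (..., M, K)."""
    pstar = boundary_probs_arrays(alpha, thresholds, theta)
    shape = pstar.shape[:-1]
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    ext = np.concatenate([ones, pstar, zeros], axis=-1)
    return ext[..., :-1] - ext[..., 1:]


def category_probs(item: GRMItem, theta: float) -> np.ndarray:
    """Response-category probabilities of one item at θ; length K, sums to 1."""
    out = category_probs_arrays(
        np.array([item.discrimination]), np.array([item.thresholds]), float(theta)
    )
    return out[0]


# ---------------------------------------------------------------------------
# information
# ---------------------------------------------------------------------------

def item_informations_arrays(alpha: np.ndarray, thresholds: np.ndarray,
                             theta) -> np.ndarray:
    """Fisher information of each item at θ; shape (..., M).

    I_i(θ) = Σ_k (P*'_{k−1} − P*'_k)² / P_k with P*' = α P*(1−P*); equals the
    expected negative second derivative of the item log-likelihood.
    """
    pstar = boundary_probs_arrays(alpha, thresholds, theta)
    dstar = alpha[:, None] * pstar * (1.0 - pstar)
    shape = pstar.shape[:-1]
    pad = np.zeros(shape + (1,))
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    ext_p = np.concatenate([ones, pstar, zeros], axis=-1)
    ext_d = np.concatenate([pad, dstar, pad], axis=-1)
    pk = ext_p[..., :-1] - ext_p[..., 1:]
    dk = ext_d[..., :-1] - ext_d[..., 1:]
    return (dk**2 / np.clip(pk, 1e-300, None)).sum(axis=-1)


def item_information(item: GRMItem, theta: float) -> float:
    """Fisher information of one item at θ."""
    return float(
        item_informations_arrays(
            np.array([item.discrimination]), np.array([item.thresholds]),
            float(theta),
        )[0]
    )


def test_information(items: ItemBank | Iterable[GRMItem], theta) -> float | np.ndarray:
    """Total Fisher information of an item set at θ (sum over items).

    The test-information curve of the GHQ-30 bank rises with θ: the
    instrument is most informative for respondents with elevated distress.
    """
    if isinstance(items, ItemBank):
        alpha, thr = items.discriminations, items.thresholds
    else:
        items = list(items)
        if not items:
            raise ValueError("test_information requires a nonempty item set")
        alpha = np.array([it.discrimination for it in items])
        thr = np.array([it.thresholds for it in items])
    if alpha.size == 0:
        raise ValueError("test_information requires a nonempty item set")
    info = item_informations_arrays(alpha, thr, theta).sum(axis=-1)
    return float(info) if np.ndim(info) == 0 else info


# ---------------------------------------------------------------------------
# precision mapping
# ---------------------------------------------------------------------------

def reliability_to_se(r: float) -> float:
    """SE cutoff implied by a marginal reliability: SE = √(1 − r)."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"marginal reliability must be in (0, 1), got {r}")
    return float(np.sqrt(1.0 - r))


def se_to_reliability(se: float) -> float:
    """Marginal reliability implied by a standard error: r = 1 − SE²."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return float(1.0 - se**2)
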