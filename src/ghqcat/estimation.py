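"""Latent-trait estimation from a (partial) response pattern.

Three estimators, matching common CAT practice:

* MLE  — maximum likelihood over the clamped range [−θ_max, θ_max];
         SE = 1/√I(θ̂) over the answered items.
* BME  — Bayesian modal (MAP); with a uniform prior on the working range it
         is formally equivalent to MLE.  The reported SE includes the
         prior's information term (1/sd² for a normal prior, 0 for uniform).
* EAP  — posterior mean and posterior SD by fixed-grid quadrature.

Optimization is a coarse grid bracket followed by bounded Brent refinement:
the likelihood can be monotone (flat toward one boundary) for extreme
response patterns, and bracketing keeps those cases stable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .bank import ItemBank
from .grm import THETA_MAX, category_probs_arrays, item_informations_arrays

#: Default EAP quadrature: equally spaced nodes on the working range.
EAP_NODES = 101

#: Coarse-grid step for the MLE/BME bracket.
GRID_STEP = 0.1


@dataclasses.dataclass(frozen=True)
class Prior:
    """Prior for BME/EAP: standard normal by default, or uniform on the
    working θ range."""

    kind: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    support: tuple[float, float] = (-THETA_MAX, THETA_MAX)

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform"):
            raise ValueError(f"prior kind must be 'normal' or 'uniform', got {self.kind!r}")
        if self.kind == "normal" and self.sd <= 0:
            raise ValueError("normal prior sd must be positive")
        if self.support[1] <= self.support[0]:
            raise ValueError("prior support must be a nonempty interval")

    def log_density(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.kind == "uniform":
            lo, hi = self.support
            out = np.where(
                (theta >= lo) & (theta <= hi), -math.log(hi - lo), -np.inf
            )
            return out
        z = (theta - self.mean) / self.sd
        return -0.5 * z**2 - math.log(self.sd) - 0.5 * math.log(2 * math.pi)

    @property
    def information(self) -> float:
        """Fisher information contributed by the prior (0 if uniform)."""
        return 0.0 if self.kind == "uniform" else 1.0 / self.sd**2


@dataclasses.dataclass(frozen=True)
class ThetaEstimate:
    """A point estimate of latent distress with its standard error."""

    value: float
    se: float
    method: str
    n_items: int
    at_bound: bool = False


class ResponseValidationError(ValueError):
    """Raised for responses to unknown items or out-of-range categories."""


def _subset_arrays(responses: Mapping[int, int], bank: ItemBank):
    """Validate a response map and return (positions, categories−1)."""
    idx = np.empty(len(responses), dtype=int)
    cats = np.empty(len(responses), dtype=int)
    K = bank.n_categories
    for j, (item_id, cat) in enumerate(responses.items()):
        if item_id not in bank:
            raise ResponseValidationError(f"response to unknown item {item_id}")
        if not 1 <= int(cat) <= K:
            raise ResponseValidationError(
                f"item {item_id}: category {cat} outside 1..{K}"
            )
        idx[j] = bank.position(item_id)
        cats[j] = int(cat) - 1
    return idx, cats


def log_likelihood(responses: Mapping[int, int], bank: ItemBank, theta) -> float | np.ndarray:
    """GRM log-likelihood of a response pattern at θ (0 for an empty pattern)."""
    idx, cats = _subset_arrays(responses, bank)
    theta_arr = np.asarray(theta, dtype=float)
    if idx.size == 0:
        return 0.0 if theta_arr.ndim == 0 else np.zeros(theta_arr.shape)
    probs = category_probs_arrays(
        bank.discriminations[idx], bank.thresholds[idx], theta_arr
    )
    ll = np.log(np.clip(probs, 1e-300, None))[..., np.arange(idx.size), cats].sum(axis=-1)
    return float(ll) if ll.ndim == 0 else ll


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def _maximize(obj, lo: float, hi: float, step: float = GRID_STEP) -> float:
    """Coarse grid bracket then bounded Brent; returns the argmax in [lo, hi]."""
    grid = _grid(lo, hi, step)
    vals = obj(grid)
    j = int(np.argmax(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    if a == b:
        return float(grid[j])
    res = minimize_scalar(
        lambda t: -obj(np.asarray(t)), bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    cands = [float(grid[j]), float(res.x)]
    return max(cands, key=lambda t: float(obj(np.asarray(t))))


def _objective(responses, bank: ItemBank, prior: Prior | None):
    idx, cats = _subset_arrays(responses, bank)
    alpha = bank.discriminations[idx]
    thr = bank.thresholds[idx]
    cols = np.arange(idx.size)

    def obj(theta):
        theta = np.asarray(theta, dtype=float)
        if idx.size:
            probs = category_probs_arrays(alpha, thr, theta)
            ll = np.log(np.clip(probs, 1e-300, None))[..., cols, cats].sum(axis=-1)
        else:
            ll = np.zeros(theta.shape) if theta.ndim else 0.0
        if prior is not None:
            ll = ll + prior.log_density(theta)
        return ll

    return obj, idx


def _observed_se(bank: ItemBank, idx: np.ndarray, theta: float,
                 prior_info: float = 0.0) -> float:
    info = item_informations_arrays(
        bank.discriminations[idx], bank.thresholds[idx], theta
    ).sum() + prior_info
    return float(1.0 / math.sqrt(info)) if info > 0 else math.inf


def estimate_mle(responses: Mapping[int, int], bank: ItemBank,
                 theta_range: tuple[float, float] = (-THETA_MAX, THETA_MAX)) -> ThetaEstimate:
    """Maximum-likelihood estimate; boundary solutions are clamped to the
    working range and flagged via ``at_bound``."""
    if len(responses) == 0:
        raise ResponseValidationError("MLE requires at least one response")
    obj, idx = _objective(responses, bank, prior=None)
    lo, hi = theta_range
    value = _maximize(obj, lo, hi)
    at_bound = value <= lo + 1e-9 or value >= hi - 1e-9
    se = _observed_se(bank, idx, value)
    return ThetaEstimate(value, se, "MLE", len(responses), at_bound)


def estimate_bme(responses: Mapping[int, int], bank: ItemBank, prior: Prior,
                 theta_range: tuple[float, float] = (-THETA_MAX, THETA_MAX)) -> ThetaEstimate:
    """Bayesian modal (MAP) estimate.  SE = 1/√(item information at the mode
    + prior information); a uniform prior reproduces MLE exactly."""
    if len(responses) == 0:
        if prior.kind != "normal":
            raise ResponseValidationError(
                "BME with no responses needs an informative (normal) prior"
            )
        return ThetaEstimate(prior.mean, prior.sd, "BME", 0)
    obj, idx = _objective(responses, bank, prior=prior)
    lo, hi = theta_range
    if prior.kind == "uniform":
        lo = max(lo, prior.support[0])
        hi = min(hi, prior.support[1])
    value = _maximize(obj, lo, hi)
    at_bound = value <= lo + 1e-9 or value >= hi - 1e-9
    se = _observed_se(bank, idx, value, prior_info=prior.information)
    return ThetaEstimate(value, se, "BME", len(responses), at_bound)


def estimate_eap(responses: Mapping[int, int], bank: ItemBank, prior: Prior,
                 n_nodes: int = EAP_NODES,
                 theta_range: tuple[float, float] = (-THETA_MAX, THETA_MAX)) -> ThetaEstimate:
    """Expected-a-posteriori estimate: posterior mean, SE = posterior SD,
    by fixed-grid quadrature on the working range."""
    lo, hi = theta_range
    if prior.kind == "uniform":
        lo = max(lo, prior.support[0])
        hi = min(hi, prior.support[1])
    idx, cats = _subset_arrays(responses, bank)
    grid = np.linspace(lo, hi, n_nodes)
    if idx.size:
        tbl = bank.log_prob_table(grid)
        ll = tbl[:, idx, cats].sum(axis=1)
    else:
        ll = np.zeros(n_nodes)
    logpost = ll + prior.log_density(grid)
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    mean = float(np.dot(w, grid))
    var = float(np.dot(w, (grid - mean) ** 2))
    se = math.sqrt(max(var, 1e-300))
    return ThetaEstimate(mean, se, "EAP", len(responses))


def eap_scores(values: np.ndarray, bank: ItemBank, prior: Prior | None = None,
               n_nodes: int = EAP_NODES,
               theta_range: tuple[float, float] = (-THETA_MAX, THETA_MAX)
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized full-bank EAP scoring of a complete response matrix.

    ``values`` is an (n, M) array of categories 1..K in bank item order.
    Returns (posterior means, posterior SDs), identical to calling
    :func:`estimate_eap` row by row.
    """
    prior = prior or Prior()
    values = np.asarray(values, dtype=int)
    n, M = values.shape
    if M != len(bank):
        raise ResponseValidationError("matrix width does not match the bank")
    lo, hi = theta_range
    if prior.kind == "uniform":
        lo, hi = max(lo, prior.support[0]), min(hi, prior.support[1])
    grid = np.linspace(lo, hi, n_nodes)
    tbl = bank.log_prob_table(grid)
    cats = values - 1
    cols = np.arange(M)
    ll = np.empty((n_nodes, n))
    for g in range(n_nodes):
        ll[g] = tbl[g][cols, cats].sum(axis=1)
    logpost = ll + prior.log_density(grid)[:, None]
    logpost -= logpost.max(axis=0, keepdims=True)
    w = np.exp(logpost)
    w /= w.sum(axis=0, keepdims=True)
    means = w.T @ grid
    var = (w * (grid[:, None] - means[None, :]) ** 2).sum(axis=0)
    return means, np.sqrt(np.clip(var, 1e-300, None))
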