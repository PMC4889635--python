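"""Next-item selection rules.

UW-FI administers the unanswered item with maximum Fisher information at
the current point estimate θ̂.  FP-KL administers the item with maximum
pointwise Kullback–Leibler divergence between the response distributions at
θ̂+δ and θ̂−δ; as δ→0, KL ≈ 2δ²·I(θ̂) so the two rules rank items
identically in the limit.  Ties are broken deterministically by lowest
item id.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bank import GRMItem, ItemBank
from .estimation import ThetaEstimate
from .grm import category_probs_arrays, item_informations_arrays

#: Default half-width δ of the FP-KL evaluation interval θ̂ ± δ.
KL_HALFWIDTH = 0.1


@dataclasses.dataclass
class SelectionContext:
    """State handed to a selection rule: current estimate, the set of
    already-administered item ids, the bank, and the KL half-width."""

    current_estimate: ThetaEstimate
    administered: frozenset[int] | set[int]
    bank: ItemBank
    kl_halfwidth: float = KL_HALFWIDTH


def kl_divergence(item: GRMItem, theta_a: float, theta_b: float) -> float:
    """KL(θ_b ‖ θ_a) of one item's response distribution:
    Σ_k P_k(θ_b)·ln[P_k(θ_b)/P_k(θ_a)].  Nonnegative; zero iff the two
    distributions coincide."""
    alpha = np.array([item.discrimination])
    thr = np.array([item.thresholds])
    pa = np.clip(category_probs_arrays(alpha, thr, float(theta_a))[0], 1e-300, None)
    pb = np.clip(category_probs_arrays(alpha, thr, float(theta_b))[0], 1e-300, None)
    return float(np.sum(pb * np.log(pb / pa)))


def _candidates(ctx: SelectionContext) -> np.ndarray:
    mask = ~np.isin(ctx.bank.item_ids, list(ctx.administered))
    cand = np.flatnonzero(mask)
    if cand.size == 0:
        raise ValueError("no unadministered items remain")
    return cand


def _argmax_lowest_id(ctx: SelectionContext, cand: np.ndarray,
                      crit: np.ndarray) -> int:
    best = crit.max()
    tied = cand[crit >= best - 1e-12]
    return int(ctx.bank.item_ids[tied].min())


def select_uwfi(ctx: SelectionContext) -> int:
    """Unweighted Fisher information: argmax_i I_i(θ̂) over unanswered items."""
    cand = _candidates(ctx)
    theta = ctx.current_estimate.value
    info = item_informations_arrays(
        ctx.bank.discriminations[cand], ctx.bank.thresholds[cand], theta
    )
    return _argmax_lowest_id(ctx, cand, info)


def select_fpkl(ctx: SelectionContext) -> int:
    """Fixed pointwise KL: argmax_i KL_i(θ̂+δ ‖ θ̂−δ) over unanswered items."""
    cand = _candidates(ctx)
    theta = ctx.current_estimate.value
    d = ctx.kl_halfwidth
    alpha = ctx.bank.discriminations[cand]
    thr = ctx.bank.thresholds[cand]
    pa = np.clip(category_probs_arrays(alpha, thr, theta - d), 1e-300, None)
    pb = np.clip(category_probs_arrays(alpha, thr, theta + d), 1e-300, None)
    kl = (pb * np.log(pb / pa)).sum(axis=-1)
    return _argmax_lowest_id(ctx, cand, kl)


SELECTORS = {"UW-FI": select_uwfi, "FP-KL": select_fpkl}
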