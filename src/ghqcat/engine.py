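"""The adaptive administration loop for one respondent.

One pass of :func:`run_cat`: estimate θ̂ (start value before any response),
select the next item, fetch the response, re-estimate, and stop once the
standard error meets the precision cutoff (after at least ``min_items``
responses) or the bank is exhausted.  The engine itself contains no
randomness: given a fixed response source and configuration, the trace is
identical on every run.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import pandas as pd

from .bank import ItemBank
from .estimation import (
    Prior,
    ThetaEstimate,
    estimate_bme,
    estimate_eap,
    estimate_mle,
)
from .grm import THETA_MAX, PrecisionTarget
from .selection import KL_HALFWIDTH, SELECTORS, SelectionContext

ESTIMATORS = ("MLE", "BME", "EAP")

#: A response source maps an item id to that respondent's category (1..K).
ResponseSource = Callable[[int], int]


class CATConfigError(ValueError):
    """Raised for inconsistent engine configurations."""


@dataclasses.dataclass
class CATConfig:
    """Configuration of one CAT administration policy."""

    estimator: str = "MLE"
    prior: Prior | None = None
    selector: str = "UW-FI"
    precision: PrecisionTarget = dataclasses.field(
        default_factory=lambda: PrecisionTarget(marginal_reliability=0.84)
    )
    max_items: int = 30
    min_items: int = 1
    start_theta: float = 0.0
    kl_halfwidth: float = KL_HALFWIDTH
    theta_range: tuple[float, float] = (-THETA_MAX, THETA_MAX)
    eap_nodes: int = 101

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise CATConfigError(f"unknown estimator {self.estimator!r}")
        if self.selector not in SELECTORS:
            raise CATConfigError(f"unknown selector {self.selector!r}")
        if self.estimator in ("BME", "EAP") and self.prior is None:
            raise CATConfigError(f"{self.estimator} requires a prior")
        if self.estimator == "MLE" and self.prior is not None:
            raise CATConfigError("MLE does not take a prior")
        if not 1 <= self.min_items <= self.max_items:
            raise CATConfigError("need 1 <= min_items <= max_items")

    @property
    def prior_label(self) -> str:
        return "-" if self.prior is None else self.prior.kind

    def label(self) -> str:
        return f"{self.estimator}/{self.selector}/{self.prior_label}"


@dataclasses.dataclass
class CATTrace:
    """Record of one simulee's adaptive administration."""

    item_sequence: list[int]
    responses: list[int]
    estimates: list[tuple[float, float]]
    final: ThetaEstimate
    reached: bool

    @property
    def n_administered(self) -> int:
        return len(self.item_sequence)

    def to_frame(self, simulee_id=None) -> pd.DataFrame:
        """One row per administered item:
        ``simulee_id,step,item_id,response,theta_hat,se``."""
        n = self.n_administered
        return pd.DataFrame(
            {
                "simulee_id": [simulee_id] * n,
                "step": range(1, n + 1),
                "item_id": self.item_sequence,
                "response": self.responses,
                "theta_hat": [e[0] for e in self.estimates],
                "se": [e[1] for e in self.estimates],
            }
        )


def _estimate(responses: dict[int, int], bank: ItemBank,
              config: CATConfig) -> ThetaEstimate:
    if config.estimator == "MLE":
        if not responses:
            # selection needs a point before the first response
            return ThetaEstimate(config.start_theta, math.inf, "MLE", 0)
        return estimate_mle(responses, bank, theta_range=config.theta_range)
    if config.estimator == "BME":
        if not responses and config.prior.kind == "uniform":
            return ThetaEstimate(config.start_theta, math.inf, "BME", 0)
        return estimate_bme(responses, bank, config.prior,
                            theta_range=config.theta_range)
    return estimate_eap(responses, bank, config.prior,
                        n_nodes=config.eap_nodes, theta_range=config.theta_range)


def run_cat(response_source: ResponseSource | Mapping[int, int],
            bank: ItemBank, config: CATConfig) -> CATTrace:
    """Run one adaptive administration and return its trace.

    ``response_source`` is either a callable ``item_id -> category`` or a
    complete/partial mapping (a row of a response matrix).
    """
    if isinstance(response_source, Mapping):
        row = response_source
        source = lambda item_id: row[item_id]  # noqa: E731
    else:
        source = response_source
    max_items = min(config.max_items, len(bank))
    cutoff = config.precision.se_cutoff

    answered: dict[int, int] = {}
    seq: list[int] = []
    cats: list[int] = []
    path: list[tuple[float, float]] = []
    est = _estimate(answered, bank, config)
    while True:
        ctx = SelectionContext(
            current_estimate=est,
            administered=answered.keys(),
            bank=bank,
            kl_halfwidth=config.kl_halfwidth,
        )
        item_id = SELECTORS[config.selector](ctx)
        try:
            cat = int(source(item_id))
        except Exception as exc:
            raise RuntimeError(
                f"response source failed for item {item_id}: {exc}"
            ) from exc
        answered[item_id] = cat
        seq.append(item_id)
        cats.append(cat)
        est = _estimate(answered, bank, config)
        path.append((est.value, est.se))
        n = len(seq)
        if (est.se <= cutoff and n >= config.min_items) or n >= max_items:
            break
    return CATTrace(
        item_sequence=seq,
        responses=cats,
        estimates=path,
        final=est,
        reached=bool(est.se <= cutoff),
    )


def score_full_bank(response_row: Mapping[int, int], bank: ItemBank,
                    config: CATConfig) -> ThetaEstimate:
    """Reference (non-adaptive) score over the complete bank — the
    full-length administration a CAT is compared against."""
    missing = [int(i) for i in bank.item_ids if i not in response_row]
    if missing:
        raise ValueError(f"incomplete response row; missing items {missing}")
    full = {int(i): int(response_row[int(i)]) for i in bank.item_ids}
    return _estimate(full, bank, config)


def traces_to_frame(traces: Sequence[CATTrace],
                    simulee_ids: Sequence | None = None) -> pd.DataFrame:
    """Concatenate trace exports for a population of simulees."""
    ids = simulee_ids if simulee_ids is not None else range(len(traces))
    return pd.concat(
        [t.to_frame(s) for t, s in zip(traces, ids)], ignore_index=True
    )
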