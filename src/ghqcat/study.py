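"""The two simulation experiments.

``run_grid`` sweeps CAT policies (estimator × selector × prior) against a
grid of marginal-reliability stopping rules and reports, per cell, the mean
number of administered items and the percentage of administrations that
reached the precision target within the full bank.  ``change_analysis``
scores a longitudinal population twice — full bank and CAT — and correlates
the two change scores θ_followup − θ_baseline.  ``trait_profile`` summarizes
how workload depends on the trait level (the targeting picture: a
distress bank is least informative, hence most expensive, at low θ).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank
from .engine import CATConfig, CATTrace, run_cat, score_full_bank
from .grm import PrecisionTarget, test_information
from .synthetic import ResponseMatrix


@dataclasses.dataclass
class GridCellResult:
    """One cell of the workload grid."""

    estimator: str
    selector: str
    prior: str
    reliability: float
    avg_items: float
    avg_items_rounded: int
    prop_reached: float  # percent
    n_simulees: int


@dataclasses.dataclass
class ChangeCellResult:
    """One cell of the change-score correlation table."""

    estimator: str
    selector: str
    prior: str
    reliability: float
    correlation: float
    n_simulees: int


@dataclasses.dataclass
class TraitProfile:
    """Per-θ-bin workload and information summary."""

    bin_centers: np.ndarray
    mean_items: np.ndarray  # NaN where a bin is empty
    sd_items: np.ndarray
    test_information: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_bin_center": self.bin_centers,
                "mean_items": self.mean_items,
                "sd_items": self.sd_items,
                "test_information": self.test_information,
            }
        )


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _with_precision(config: CATConfig, reliability: float) -> CATConfig:
    return dataclasses.replace(
        config, precision=PrecisionTarget(marginal_reliability=reliability)
    )


def run_cell(responses: ResponseMatrix, bank: ItemBank,
             config: CATConfig) -> list[CATTrace]:
    """Run the CAT once per respondent row under one fixed policy."""
    return [run_cat(responses.row(i), bank, config) for i in range(responses.n)]


def summarize_cell(traces: Sequence[CATTrace], config: CATConfig) -> GridCellResult:
    n_items = np.array([t.n_administered for t in traces], dtype=float)
    reached = np.array([t.reached for t in traces], dtype=float)
    avg = float(n_items.mean())
    return GridCellResult(
        estimator=config.estimator,
        selector=config.selector,
        prior=config.prior_label,
        reliability=config.precision.marginal_reliability,
        avg_items=avg,
        avg_items_rounded=_round_half_away(avg),
        prop_reached=float(100.0 * reached.mean()),
        n_simulees=len(traces),
    )


def run_grid(responses: ResponseMatrix, bank: ItemBank,
             configs: Sequence[CATConfig],
             reliabilities: Sequence[float]) -> list[GridCellResult]:
    """Evaluate every (policy, reliability) cell on one response matrix.

    All cells replay the same respondents, so differences between cells
    reflect the policy alone, not sampling noise.
    """
    out = []
    for config in configs:
        for r in reliabilities:
            cell_cfg = _with_precision(config, r)
            traces = run_cell(responses, bank, cell_cfg)
            out.append(summarize_cell(traces, cell_cfg))
    return out


def grid_to_frame(cells: Sequence[GridCellResult]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(c) for c in cells])
    return df.rename(columns={"prop_reached": "prop_reached_pct",
                              "n_simulees": "n"})


def trait_profile(traces: Sequence[CATTrace], thetas: np.ndarray,
                  bank: ItemBank, n_bins: int = 9,
                  theta_range: tuple[float, float] = (-3.0, 3.0)) -> TraitProfile:
    """Bin simulees by true θ and summarize items administered per bin,
    together with the bank's test information at the bin centers.  Empty
    bins are reported as NaN, not zero."""
    thetas = np.asarray(thetas, dtype=float)
    if len(traces) != thetas.size:
        raise ValueError("traces and theta vector are misaligned")
    edges = np.linspace(theta_range[0], theta_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_items = np.array([t.n_administered for t in traces], dtype=float)
    which = np.clip(np.digitize(thetas, edges) - 1, 0, n_bins - 1)
    # simulees outside the range fall into the edge bins
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = n_items[which == b]
        if sel.size:
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=1) if sel.size > 1 else 0.0
    info = np.array([test_information(bank, c) for c in centers])
    return TraitProfile(centers, mean, sd, info)


def change_analysis(base_responses: ResponseMatrix,
                    follow_responses: ResponseMatrix,
                    base_bank: ItemBank, follow_bank: ItemBank,
                    config: CATConfig,
                    reliabilities: Sequence[float]) -> list[ChangeCellResult]:
    """Correlate full-bank and CAT change scores per reliability cutoff.

    For each simulee, Δ_full is the difference of full-bank estimates and
    Δ_cat the difference of CAT estimates terminated at the cutoff; the cell
    statistic is Pearson corr(Δ_full, Δ_cat) over the population.
    """
    if not np.array_equal(base_responses.simulee_ids, follow_responses.simulee_ids):
        raise ValueError("baseline and follow-up simulee ids do not match")
    n = base_responses.n
    full_base = np.array(
        [score_full_bank(base_responses.row(i), base_bank, config).value
         for i in range(n)]
    )
    full_follow = np.array(
        [score_full_bank(follow_responses.row(i), follow_bank, config).value
         for i in range(n)]
    )
    delta_full = full_follow - full_base
    out = []
    for r in reliabilities:
        cell_cfg = _with_precision(config, r)
        cat_base = np.array(
            [run_cat(base_responses.row(i), base_bank, cell_cfg).final.value
             for i in range(n)]
        )
        cat_follow = np.array(
            [run_cat(follow_responses.row(i), follow_bank, cell_cfg).final.value
             for i in range(n)]
        )
        delta_cat = cat_follow - cat_base
        corr = float(np.corrcoef(delta_full, delta_cat)[0, 1])
        out.append(
            ChangeCellResult(
                estimator=config.estimator,
                selector=config.selector,
                prior=config.prior_label,
                reliability=r,
                correlation=corr,
                n_simulees=n,
            )
        )
    return out


def change_to_frame(cells: Sequence[ChangeCellResult]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(c) for c in cells])
    return df.rename(columns={"n_simulees": "n"})


def grid_markdown(cells: Sequence[GridCellResult]) -> str:
    """Workload grid as a text table: rows are policies, columns the
    reliability cutoffs, cells 'items (reached %)'."""
    df = grid_to_frame(cells)
    df["cell"] = [
        f"{r.avg_items_rounded} ({r.prop_reached_pct:.1f}%)"
        for r in df.itertuples()
    ]
    wide = df.pivot_table(
        index=["estimator", "selector", "prior"], columns="reliability",
        values="cell", aggfunc="first", sort=False,
    )
    wide = wide[sorted(wide.columns, reverse=True)]
    return wide.to_markdown()


def change_markdown(cells: Sequence[ChangeCellResult]) -> str:
    df = change_to_frame(cells)
    wide = df.pivot_table(
        index=["estimator", "selector", "prior"], columns="reliability",
        values="correlation", aggfunc="first", sort=False,
    )
    wide = wide[sorted(wide.columns, reverse=True)]
    return wide.round(2).to_markdown()
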