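"""Synthetic simulee populations and GRM response matrices.

The generator emulates the statistical structure the analysis assumes for a
general-population distress survey: latent distress θ drawn N(0, 1) — the
standardization under which the bank was calibrated — and item responses
sampled from the graded response model at the bank's printed parameters.
For longitudinal designs a bivariate-normal (baseline, follow-up) θ with
configurable correlation is drawn (default ρ = 0.5, a conservative
mid-value for a multi-year distress retest).  Optional DIF injection shifts
a chosen subset of items for one group/occasion, as a test harness for the
DIF screen.

One experiment seed governs everything; each simulee's response stream is
derived deterministically from (seed, simulee_id), so individual traces are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import BankValidationError, ItemBank
from .grm import category_probs_arrays


@dataclasses.dataclass
class PopulationSpec:
    """A simulee population: size, latent distribution, and (optionally)
    a bivariate baseline/follow-up structure."""

    n: int
    mean: float = 0.0
    sd: float = 1.0
    longitudinal: bool = False
    theta_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.sd <= 0:
            raise ValueError("theta sd must be positive")
        if not -1.0 <= self.theta_correlation <= 1.0:
            raise ValueError(
                f"theta correlation must be in [-1, 1], got {self.theta_correlation}"
            )


@dataclasses.dataclass
class ResponseMatrix:
    """Complete respondent × item matrix of ordinal categories (1..K)."""

    simulee_ids: np.ndarray
    item_ids: np.ndarray
    values: np.ndarray  # (n, M) integer categories
    occasion: str = "custom"

    def __post_init__(self) -> None:
        self.simulee_ids = np.asarray(self.simulee_ids)
        self.item_ids = np.asarray(self.item_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.simulee_ids), len(self.item_ids)):
            raise ValueError("response matrix shape does not match id vectors")

    @property
    def n(self) -> int:
        return len(self.simulee_ids)

    def row(self, i: int) -> dict[int, int]:
        """Row i as an item_id -> category map (a CAT response source)."""
        return dict(zip(self.item_ids.tolist(), self.values[i].tolist()))

    def column(self, item_id: int) -> np.ndarray:
        (j,) = np.nonzero(self.item_ids == item_id)
        if j.size == 0:
            raise KeyError(f"item {item_id} not in matrix")
        return self.values[:, j[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"item_{i}" for i in self.item_ids]
        )
        df.insert(0, "occasion", self.occasion)
        df.insert(0, "simulee_id", self.simulee_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a response matrix from CSV: wide format
    ``simulee_id,occasion,item_1..item_M`` or long format
    ``simulee_id,item_id,category``."""
    df = pd.read_csv(path)
    if "category" in df.columns and "item_id" in df.columns:
        wide = df.pivot(index="simulee_id", columns="item_id", values="category")
        return ResponseMatrix(
            simulee_ids=wide.index.to_numpy(),
            item_ids=wide.columns.to_numpy(),
            values=wide.to_numpy(),
            occasion=str(df["occasion"].iloc[0]) if "occasion" in df.columns else "custom",
        )
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        raise ValueError("no item_* columns and no long-format columns found")
    return ResponseMatrix(
        simulee_ids=df["simulee_id"].to_numpy(),
        item_ids=np.array([int(c.split("_", 1)[1]) for c in item_cols]),
        values=df[item_cols].to_numpy(),
        occasion=str(df["occasion"].iloc[0]) if "occasion" in df.columns else "custom",
    )


def draw_thetas(spec: PopulationSpec) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Draw latent distress scores; a (baseline, follow-up) pair of vectors
    if the spec is longitudinal, one vector otherwise."""
    rng = np.random.default_rng(spec.seed)
    if not spec.longitudinal:
        return rng.normal(spec.mean, spec.sd, size=spec.n)
    # explicit bivariate construction so |rho| = 1 degenerates cleanly
    rho = spec.theta_correlation
    z1 = rng.normal(size=spec.n)
    z2 = rng.normal(size=spec.n)
    base = spec.mean + spec.sd * z1
    follow = spec.mean + spec.sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return base, follow


def sample_responses(bank: ItemBank, thetas: np.ndarray, seed: int,
                     occasion: str | None = None,
                     simulee_ids: np.ndarray | None = None) -> ResponseMatrix:
    """Sample a complete GRM response matrix: one category per (simulee,
    item), drawn by inverse CDF over the item's category probabilities at
    the simulee's θ.  Each simulee uses the substream (seed, simulee_id)."""
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    ids = (np.arange(n) if simulee_ids is None else np.asarray(simulee_ids))
    M = len(bank)
    values = np.empty((n, M), dtype=int)
    cum = None
    for i in range(n):
        probs = category_probs_arrays(
            bank.discriminations, bank.thresholds, thetas[i]
        )
        cum = np.cumsum(probs, axis=-1)
        u = np.random.default_rng([int(seed), int(ids[i])]).random(M)
        values[i] = 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)
    return ResponseMatrix(
        simulee_ids=ids,
        item_ids=bank.item_ids.copy(),
        values=values,
        occasion=occasion if occasion is not None else bank.occasion,
    )


def inject_dif(bank: ItemBank, item_ids, discrimination_factor: float = 1.0,
               threshold_shift: float = 0.0) -> ItemBank:
    """Return a copy of the bank with the chosen items altered:
    discriminations multiplied by ``discrimination_factor`` and every
    threshold shifted by ``threshold_shift``.  Untouched items are shared."""
    if discrimination_factor <= 0:
        raise ValueError("discrimination factor must be positive")
    targets = set(int(i) for i in np.atleast_1d(item_ids))
    unknown = targets - {int(i) for i in bank.item_ids}
    if unknown:
        raise KeyError(f"items not in bank: {sorted(unknown)}")
    overrides = {}
    for item_id in targets:
        it = bank.item(item_id)
        shifted = tuple(t + threshold_shift for t in it.thresholds)
        try:
            overrides[item_id] = dataclasses.replace(
                it,
                discrimination=it.discrimination * discrimination_factor,
                thresholds=shifted,
            )
        except BankValidationError as exc:
            raise BankValidationError(
                f"DIF injection breaks threshold order on item {item_id}: {exc}"
            ) from exc
    return bank.with_overrides(overrides, occasion=f"{bank.occasion}+dif")
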