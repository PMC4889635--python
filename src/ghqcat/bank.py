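"""Item bank: GRM item parameters, the packaged GHQ-30 calibration, and
factor-loading ↔ IRT conversion.

The GHQ-30 bank ships in the logistic metric.  Items calibrated under a
bifactor factor model (one general distress factor plus a wording method
factor) enter through :func:`loadings_to_irt`, which converts normal-ogive
loadings/thresholds into logistic discriminations/thresholds; only the
general-factor loading contributes to the discrimination, the method loading
enters solely through the communality in the denominator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Normal-ogive → logistic scaling constant.
SCALING_D = 1.7

#: Item ids that show differential item functioning between occasions.
GHQ30_DIF_ITEMS = (16, 19, 25)


class BankValidationError(ValueError):
    """Raised when an item or bank violates its structural invariants."""


@dataclasses.dataclass(frozen=True)
class GRMItem:
    """One polytomous graded-response item.

    ``discrimination`` is the general-factor slope α (logistic metric);
    ``thresholds`` are the K−1 ordered cumulative-boundary locations t_k.
    Zero discrimination is allowed and describes an item carrying no
    information about the latent trait (useful in degenerate checks); the
    packaged GHQ-30 items all have α > 0.
    """

    item_id: int
    stem: str
    discrimination: float
    thresholds: tuple[float, ...]
    wording: str = "negative"
    dif: bool = False

    def __post_init__(self) -> None:
        if self.discrimination < 0 or not math.isfinite(self.discrimination):
            raise BankValidationError(
                f"item {self.item_id}: discrimination must be a finite "
                f"non-negative number, got {self.discrimination}"
            )
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) < 1:
            raise BankValidationError(
                f"item {self.item_id}: need at least one threshold (K >= 2)"
            )
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise BankValidationError(
                f"item {self.item_id}: thresholds must be strictly "
                f"increasing, got {thr}"
            )
        if self.wording not in ("positive", "negative"):
            raise BankValidationError(
                f"item {self.item_id}: wording must be 'positive' or "
                f"'negative', got {self.wording!r}"
            )
        object.__setattr__(self, "thresholds", thr)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclasses.dataclass(frozen=True)
class FactorItemEstimates:
    """Bifactor estimates for one item in the normal-ogive metric.

    ``loading_general``/``loading_method`` are the standardized loadings on
    the general and wording-method factors; ``tau`` the ordered normal-ogive
    thresholds.
    """

    loading_general: float
    loading_method: float
    tau: tuple[float, ...]
    item_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tau", tuple(float(t) for t in self.tau))

    @property
    def communality(self) -> float:
        return self.loading_general**2 + self.loading_method**2


class ItemBank:
    """Ordered collection of GRM items for one occasion.

    The unit a CAT operates on.  Validates id uniqueness and a common
    number of response categories, and caches the parameter arrays and
    per-grid log category-probability tables that the estimators use.
    """

    def __init__(self, items: Sequence[GRMItem], occasion: str = "custom"):
        items = list(items)
        if not items:
            raise BankValidationError("bank must contain at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise BankValidationError(f"duplicate item ids: {dupes}")
        ks = {it.n_categories for it in items}
        if len(ks) != 1:
            raise BankValidationError(
                f"all items must share the same number of categories, got {ks}"
            )
        self.items: tuple[GRMItem, ...] = tuple(items)
        self.occasion = occasion
        self._index = {it.item_id: i for i, it in enumerate(self.items)}
        self._logp_tables: dict[tuple, np.ndarray] = {}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __contains__(self, item_id: int) -> bool:
        return item_id in self._index

    def item(self, item_id: int) -> GRMItem:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"no item with id {item_id} in bank") from None

    def position(self, item_id: int) -> int:
        return self._index[item_id]

    # -- cached parameter arrays --------------------------------------------
    @property
    def item_ids(self) -> np.ndarray:
        if not hasattr(self, "_ids"):
            self._ids = np.array([it.item_id for it in self.items], dtype=int)
        return self._ids

    @property
    def discriminations(self) -> np.ndarray:
        if not hasattr(self, "_alpha"):
            self._alpha = np.array(
                [it.discrimination for it in self.items], dtype=float
            )
        return self._alpha

    @property
    def thresholds(self) -> np.ndarray:
        if not hasattr(self, "_thr"):
            self._thr = np.array([it.thresholds for it in self.items], dtype=float)
        return self._thr

    @property
    def n_categories(self) -> int:
        return self.items[0].n_categories

    def log_prob_table(self, grid: np.ndarray) -> np.ndarray:
        """Log category probabilities on a θ grid, shape (G, M, K), cached."""
        key = (float(grid[0]), float(grid[-1]), len(grid))
        tbl = self._logp_tables.get(key)
        if tbl is None:
            from .grm import category_probs_arrays

            probs = category_probs_arrays(
                self.discriminations, self.thresholds, grid
            )
            tbl = np.log(np.clip(probs, 1e-300, None))
            self._logp_tables[key] = tbl
        return tbl

    def subset(self, item_ids: Iterable[int]) -> "ItemBank":
        return ItemBank([self.item(i) for i in item_ids], occasion=self.occasion)

    def with_overrides(self, overrides: dict[int, GRMItem], occasion: str) -> "ItemBank":
        """Sparse per-occasion overrides keyed by item_id (the Table-1 'id'
        convention: unlisted items keep their baseline parameters)."""
        unknown = set(overrides) - set(self._index)
        if unknown:
            raise BankValidationError(f"override for unknown item ids: {sorted(unknown)}")
        return ItemBank(
            [overrides.get(it.item_id, it) for it in self.items], occasion=occasion
        )

    def __repr__(self) -> str:
        return f"ItemBank(occasion={self.occasion!r}, n_items={len(self)}, K={self.n_categories})"


# ---------------------------------------------------------------------------
# factor-loading ↔ IRT conversion
# ---------------------------------------------------------------------------

def loadings_to_irt(est: FactorItemEstimates) -> tuple[float, tuple[float, ...]]:
    """Convert bifactor normal-ogive estimates to logistic GRM parameters.

        α = 1.7·λ_g / √(1 − λ_g² − λ_m²),   t_k = 1.7·τ_k / √(1 − λ_g² − λ_m²)

    Only the general-factor loading produces the discrimination; the method
    loading enters through the communality in the denominator.
    """
    label = f"item {est.item_id}" if est.item_id is not None else "item"
    comm = est.communality
    if comm >= 1.0:
        raise BankValidationError(
            f"{label}: communality {comm:.4f} >= 1, loadings are infeasible"
        )
    if any(b <= a for a, b in zip(est.tau, est.tau[1:])):
        raise BankValidationError(f"{label}: tau must be strictly increasing")
    denom = math.sqrt(1.0 - comm)
    alpha = SCALING_D * est.loading_general / denom
    thresholds = tuple(SCALING_D * t / denom for t in est.tau)
    return alpha, thresholds


def irt_to_loadings(item: GRMItem, loading_method: float) -> FactorItemEstimates:
    """Algebraic inverse of :func:`loadings_to_irt` given the method loading."""
    if abs(loading_method) >= 1.0:
        raise BankValidationError(
            f"item {item.item_id}: |method loading| must be < 1"
        )
    c = item.discrimination / SCALING_D
    resid = 1.0 - loading_method**2
    # α = D·λ_g/√(1−λ_g²−λ_m²)  ⇒  λ_g² = c²·(1−λ_m²)/(1+c²)
    lam_g = math.sqrt(c**2 * resid / (1.0 + c**2))
    denom = math.sqrt(1.0 - lam_g**2 - loading_method**2)
    tau = tuple(t * denom / SCALING_D for t in item.thresholds)
    return FactorItemEstimates(
        loading_general=lam_g,
        loading_method=loading_method,
        tau=tau,
        item_id=item.item_id,
    )


# ---------------------------------------------------------------------------
# packaged GHQ-30 bank and bank I/O
# ---------------------------------------------------------------------------

def _rows_to_items(df: pd.DataFrame) -> list[GRMItem]:
    thr_cols = sorted(
        (c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not thr_cols:
        raise BankValidationError("no threshold columns (t1, t2, ...) found")
    items = []
    for _, row in df.iterrows():
        items.append(
            GRMItem(
                item_id=int(row["item_id"]),
                stem=str(row.get("stem", "")),
                discrimination=float(row["discrimination"]),
                thresholds=tuple(float(row[c]) for c in thr_cols),
                wording=str(row.get("wording", "negative")),
                dif=bool(int(row["dif"])) if "dif" in row else False,
            )
        )
    return items


def _bank_from_frame(df: pd.DataFrame, occasion: str) -> ItemBank:
    missing = [c for c in ("item_id", "discrimination") if c not in df.columns]
    if missing:
        raise BankValidationError(f"bank file missing required columns: {missing}")
    if "occasion" in df.columns:
        occ = df["occasion"].fillna("").astype(str)
        base = df[occ == ""]
        over = df[occ == occasion]
    else:
        base, over = df, df.iloc[0:0]
    bank = ItemBank(_rows_to_items(base), occasion=occasion if len(over) == 0 else "baseline")
    if len(over):
        overrides = {it.item_id: it for it in _rows_to_items(over)}
        bank = bank.with_overrides(overrides, occasion=occasion)
    return bank


def builtin_ghq30(occasion: str = "baseline") -> ItemBank:
    """The packaged GHQ-30 calibration (logistic metric).

    ``occasion`` is ``"baseline"`` or ``"followup"``; the follow-up bank
    differs from baseline only on the three DIF items (16, 19, 25), whose
    parameters were estimated separately per occasion.
    """
    if occasion not in ("baseline", "followup"):
        raise ValueError(f"occasion must be 'baseline' or 'followup', got {occasion!r}")
    with resources.files("ghqcat").joinpath("data/ghq30_bank.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    bank = _bank_from_frame(df, occasion=occasion)
    bank.occasion = occasion
    return bank


def read_bank(path: str | Path, occasion: str = "custom") -> ItemBank:
    """Read an item bank from CSV or JSON; validation runs on read.

    CSV schema: header ``item_id,stem,wording,discrimination,t1,t2,t3`` with
    optional ``occasion`` (per-occasion override rows) and ``dif`` columns.
    The JSON form carries the same field names as a list of records.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        records = payload["items"] if isinstance(payload, dict) else payload
        df = pd.DataFrame.from_records(records)
        if "thresholds" in df.columns:
            thr = pd.DataFrame(
                df.pop("thresholds").tolist(),
                columns=None, index=df.index,
            )
            thr.columns = [f"t{k + 1}" for k in range(thr.shape[1])]
            df = pd.concat([df, thr], axis=1)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    return _bank_from_frame(df, occasion=occasion)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank to CSV or JSON (schema of :func:`read_bank`)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {
                "item_id": it.item_id,
                "stem": it.stem,
                "wording": it.wording,
                "dif": it.dif,
                "discrimination": it.discrimination,
                "thresholds": list(it.thresholds),
            }
            for it in bank
        ]
        path.write_text(json.dumps({"occasion": bank.occasion, "items": records}, indent=1))
        return
    rows = []
    for it in bank:
        row = {
            "item_id": it.item_id,
            "stem": it.stem,
            "wording": it.wording,
            "dif": int(it.dif),
            "discrimination": it.discrimination,
        }
        row.update({f"t{k + 1}": t for k, t in enumerate(it.thresholds)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
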