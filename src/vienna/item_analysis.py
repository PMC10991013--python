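"""Item-level psychometrics: frequencies, difficulty ratio, Wilson's e.

Because VIENNA items differ in the number of doors and one-point doors, raw
item means are not comparable across items.  The difficulty ratio M̄/E — the
empirical mean item score divided by the expected score under uniform random
door choice — puts all items on a common chance-corrected scale (higher =
easier; 1.0 = chance-level performance).

Item discrimination is quantified by the corrected item-total correlation
using Wilson's e, an ordinal pair-based association coefficient appropriate
for variables with heavily tied ranks: of all n(n-1)/2 observation pairs it
counts concordant (C) and discordant (D) pairs and pairs tied on one variable
only (T_x, T_y), and

    e = (C - D) / (C + D + T_x + T_y),

i.e. only pairs tied on *both* variables are excluded from the denominator.
"corrected" means each item is correlated with the rest-score (total minus
that item), not with the full total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import ITEM_TYPE_ORDER, ItemType

__all__ = [
    "ItemStats",
    "item_frequencies",
    "item_mean_variance",
    "difficulty_ratio",
    "item_type_difficulty",
    "wilsons_e",
    "corrected_item_total",
    "item_analysis_table",
]


@dataclass(frozen=True)
class ItemStats:
    """Per-item summary mirroring a psychometric item-report row."""

    item_id: str
    item_type: ItemType
    freq0: int
    freq1: int
    freq2: int
    mean: float
    variance: float
    expected: float
    difficulty_ratio: float
    wilson_e: float


def item_frequencies(scores: Sequence[int]) -> tuple[int, int, int]:
    """Counts of 0, 1 and 2 points over the sample for one item."""
    arr = np.asarray(scores)
    if arr.size == 0:
        raise ValueError("no scores supplied")
    if not np.isin(arr, (0, 1, 2)).all():
        bad = sorted(set(arr.tolist()) - {0, 1, 2})
        raise ValueError(f"scores outside {{0,1,2}}: {bad}")
    return int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum())


def item_mean_variance(freqs: tuple[int, int, int]) -> tuple[float, float]:
    """Mean and sample variance (n-1 denominator) from score frequencies.

    With fewer than two observations the variance is undefined and returned
    as NaN.
    """
    f0, f1, f2 = freqs
    n = f0 + f1 + f2
    if n == 0:
        raise ValueError("empty frequency table")
    mean = (f1 + 2 * f2) / n
    if n < 2:
        return mean, float("nan")
    ss = f1 * (1 - mean) ** 2 + f2 * (2 - mean) ** 2 + f0 * mean**2
    return mean, ss / (n - 1)


def difficulty_ratio(mean: float, expected: float) -> float:
    """Chance-corrected item difficulty M̄/E (full precision retained)."""
    if expected <= 0:
        raise ValueError(f"expected score must be positive, got {expected}")
    return mean / float(expected)


def item_type_difficulty(
    ratios: Mapping[str, float], typology: Mapping[str, ItemType]
) -> dict[ItemType, float]:
    """Arithmetic mean of the member items' difficulty ratios per item type."""
    unknown = set(typology.values()) - set(ItemType)
    if unknown:
        raise ValueError(f"unknown item types: {sorted(unknown)}")
    missing = set(ratios) - set(typology)
    if missing:
        raise ValueError(f"items without a type assignment: {sorted(missing)}")
    out: dict[ItemType, float] = {}
    for itype in ITEM_TYPE_ORDER:
        members = [r for item, r in ratios.items() if typology[item] is itype]
        if members:
            out[itype] = float(np.mean(members))
    return out


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    """Classify all pairs as concordant / discordant / tied (x only, y only, both)."""
    dx = np.sign(x[:, None] - x[None, :]).astype(np.int8)
    dy = np.sign(y[:, None] - y[None, :]).astype(np.int8)
    iu = np.triu_indices(len(x), k=1)
    dx, dy = dx[iu], dy[iu]
    conc = int(((dx * dy) > 0).sum())
    disc = int(((dx * dy) < 0).sum())
    tx = int(((dx == 0) & (dy != 0)).sum())
    ty = int(((dx != 0) & (dy == 0)).sum())
    txy = int(((dx == 0) & (dy == 0)).sum())
    return conc, disc, tx, ty, txy


def wilsons_e(x: Sequence[float], y: Sequence[float]) -> float:
    """Wilson's e between two at-least-ordinal variables.

    Returns NaN when every pair is tied on both variables (denominator 0),
    e.g. for a zero-variance item.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    conc, disc, tx, ty, _ = _pair_counts(xa, ya)
    denom = conc + disc + tx + ty
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def corrected_item_total(scores: pd.DataFrame) -> pd.Series:
    """Wilson's e of each item against its rest-score (total minus the item).

    Parameters
    ----------
    scores:
        participants x items table of item scores.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least two items for a rest-score")
    total = scores.sum(axis=1)
    out = {}
    for item in scores.columns:
        rest = total - scores[item]
        out[item] = wilsons_e(scores[item].to_numpy(), rest.to_numpy())
    return pd.Series(out, name="wilson_e")


def item_analysis_table(
    scores: pd.DataFrame,
    typology: Mapping[str, ItemType],
    expected: Mapping[str, float],
) -> pd.DataFrame:
    """Full per-item report: frequencies, M̄, s², E, M̄/E and Wilson's e.

    ``expected`` supplies the chance-expected score E per item, normally from
    the item configuration (``expected_item_score``).
    """
    e_item_total = corrected_item_total(scores)
    rows = []
    for item in scores.columns:
        f0, f1, f2 = item_frequencies(scores[item].to_numpy())
        mean, var = item_mean_variance((f0, f1, f2))
        rows.append(
            ItemStats(
                item_id=str(item),
                item_type=ItemType(typology[item]),
                freq0=f0,
                freq1=f1,
                freq2=f2,
                mean=mean,
                variance=var,
                expected=float(expected[item]),
                difficulty_ratio=difficulty_ratio(mean, float(expected[item])),
                wilson_e=float(e_item_total[item]),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).set_index("item_id")
    df["item_type"] = [r.item_type.value for r in rows]
    return df
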