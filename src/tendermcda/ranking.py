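"""Financial phase: price-per-point ranking of qualified bids.

The technical committee's scores are combined with the offered prices by
dividing price by total score — the price per point.  Within each active
ingredient, qualified bids are ranked ascending by price per point and the
cheapest-per-point bid is flagged preferred.  Comparisons use the
full-precision quotient (150/70 = 2.142857…, not the displayed 2.14).

Ties are broken by a fixed chain: lower price per point, then higher total
score, then lower price, then lexicographic product id — a strict total
order, so the output is deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from tendermcda.scoring import EvaluationResult


class RankingError(ValueError):
    """Ranking input is malformed."""


def price_per_point(price: float, score: float) -> float:
    """Price divided by total score, at full precision.

    Only qualified bids reach the financial phase, so the score is at least
    the qualification threshold and strictly positive.
    """
    if not price > 0:
        raise RankingError(f"price must be positive, got {price}")
    if not score > 0:
        raise RankingError(f"score must be positive, got {score}")
    return price / score


class RankedBid(BaseModel):
    """One qualified bid's position in its ingredient group."""

    model_config = ConfigDict(frozen=True)

    product_id: str
    active_ingredient: str
    total_score: float
    price: float = Field(gt=0.0)
    price_per_point: float
    rank_within_ingredient: int = Field(ge=1)
    preferred: bool


@dataclass(frozen=True)
class TenderRanking:
    """Full financial-phase report: rankings plus non-competing bids."""

    ranked: tuple[RankedBid, ...]
    not_ranked: tuple[tuple[str, str, str], ...]  # (product_id, ingredient, status)
    no_eligible_supplier: tuple[str, ...]  # ingredients with zero qualified bids

    def preferred_by_ingredient(self) -> dict[str, str]:
        return {
            b.active_ingredient: b.product_id for b in self.ranked if b.preferred
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "active_ingredient": b.active_ingredient,
                "product_id": b.product_id,
                "total_score": b.total_score,
                "price": b.price,
                "price_per_point": b.price_per_point,
                "rank": b.rank_within_ingredient,
                "preferred": b.preferred,
                "status": "qualified",
            }
            for b in self.ranked
        ]
        rows += [
            {
                "active_ingredient": ingredient,
                "product_id": pid,
                "total_score": None,
                "price": None,
                "price_per_point": None,
                "rank": None,
                "preferred": False,
                "status": status,
            }
            for pid, ingredient, status in self.not_ranked
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "active_ingredient",
                "product_id",
                "total_score",
                "price",
                "price_per_point",
                "rank",
                "preferred",
                "status",
            ],
        )


def _sort_key(score: float, price: float, pid: str):
    return (price / score, -score, price, pid)


def rank_tender(
    results: Sequence[EvaluationResult],
    prices: Mapping[str, float],
) -> TenderRanking:
    """Rank qualified bids per active ingredient by ascending price per point.

    Unqualified or excluded bids are omitted from the ranking but reported
    with their status; an ingredient with no qualified bid is flagged
    ``no eligible supplier`` rather than raising.
    """
    seen: set[str] = set()
    for r in results:
        if r.product_id in seen:
            raise RankingError(f"duplicate product id {r.product_id!r}")
        seen.add(r.product_id)
        if r.product_id not in prices:
            raise RankingError(f"no price for product {r.product_id!r}")

    by_ingredient: dict[str, list[EvaluationResult]] = {}
    not_ranked: list[tuple[str, str, str]] = []
    for r in results:
        by_ingredient.setdefault(r.active_ingredient, []).append(r)

    ranked: list[RankedBid] = []
    no_eligible: list[str] = []
    for ingredient in sorted(by_ingredient):
        group = by_ingredient[ingredient]
        qualified = [r for r in group if r.qualified]
        for r in group:
            if not r.qualified:
                status = (
                    "excluded: " + ";".join(r.exclusion_reasons)
                    if r.exclusion_reasons
                    else "below threshold"
                )
                not_ranked.append((r.product_id, ingredient, status))
        if not qualified:
            no_eligible.append(ingredient)
            continue
        qualified.sort(
            key=lambda r: _sort_key(r.total_score, prices[r.product_id], r.product_id)
        )
        for pos, r in enumerate(qualified, start=1):
            price = prices[r.product_id]
            ranked.append(
                RankedBid(
                    product_id=r.product_id,
                    active_ingredient=ingredient,
                    total_score=r.total_score,
                    price=price,
                    price_per_point=price_per_point(price, r.total_score),
                    rank_within_ingredient=pos,
                    preferred=pos == 1,
                )
            )
    return TenderRanking(
        ranked=tuple(ranked),
        not_ranked=tuple(not_ranked),
        no_eligible_supplier=tuple(no_eligible),
    )
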