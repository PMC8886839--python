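"""Technical-phase evaluation of product bids.

Each bid selects one option per non-external criterion and supplies the
externally assessed pharmacovigilance percentage.  The criterion fraction
s_i (0–1) is multiplied by the criterion weight w_i (percentage points) and
the weighted points are summed to a total score S on a 0–100 scale:

    S = sum_i w_i * s_i

A bid qualifies for the financial phase iff it triggers no exclusion option
and S >= threshold (inclusive; qualification is decided at full precision,
never on the rounded display value).  Any selected exclusion-trigger option
disqualifies the bid regardless of its total.
"""

from __future__ import annotations

import io
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from tendermcda.config import Criterion, ToolConfig


class ScoringError(ValueError):
    """A bid cannot be scored against the configuration."""


class ProductBid(BaseModel):
    """One product's submission: per-criterion selections plus price."""

    model_config = ConfigDict(frozen=True)

    product_id: str = Field(min_length=1)
    active_ingredient: str = Field(min_length=1)
    selections: dict[str, str] = Field(default_factory=dict)
    pharmacovigilance_percent: Optional[float] = None
    price: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _percent_in_range(self) -> "ProductBid":
        p = self.pharmacovigilance_percent
        if p is not None and not 0.0 <= p <= 100.0:
            raise ValueError(
                f"pharmacovigilance_percent must be in [0, 100], got {p}"
            )
        return self


class EvaluationResult(BaseModel):
    """Per-criterion breakdown, exclusions, total and qualification flag."""

    model_config = ConfigDict(frozen=True)

    product_id: str
    active_ingredient: str
    fractions: dict[str, float]
    weighted_points: dict[str, float]
    total_score: float
    exclusion_reasons: tuple[str, ...]
    qualified: bool

    @model_validator(mode="after")
    def _consistent(self) -> "EvaluationResult":
        if abs(self.total_score - sum(self.weighted_points.values())) > 1e-9:
            raise ValueError("total_score must equal the sum of weighted points")
        if self.exclusion_reasons and self.qualified:
            raise ValueError("an excluded bid cannot be qualified")
        return self


def validate_bid(bid: ProductBid, config: ToolConfig) -> None:
    """Check that the bid covers the configuration exactly.

    Missing selections are a hard error, never silently scored as zero.
    """
    for criterion in config.criteria:
        if criterion.external_score:
            if bid.pharmacovigilance_percent is None:
                raise ScoringError(
                    f"bid {bid.product_id!r}: external score for "
                    f"{criterion.id!r} is missing"
                )
        else:
            if criterion.id not in bid.selections:
                raise ScoringError(
                    f"bid {bid.product_id!r}: no selection for criterion "
                    f"{criterion.id!r}"
                )
            label = bid.selections[criterion.id]
            try:
                criterion.option(label)
            except KeyError as exc:
                raise ScoringError(str(exc)) from exc
    unknown = set(bid.selections) - {c.id for c in config.criteria}
    if unknown:
        raise ScoringError(
            f"bid {bid.product_id!r}: selections for unknown criteria {sorted(unknown)}"
        )


def score_criterion(bid: ProductBid, criterion: Criterion) -> float:
    """The bid's fraction s_i in [0, 1] on one criterion."""
    if criterion.external_score:
        p = bid.pharmacovigilance_percent
        if p is None:
            raise ScoringError(
                f"bid {bid.product_id!r}: external score for {criterion.id!r} is missing"
            )
        return p / 100.0
    try:
        label = bid.selections[criterion.id]
    except KeyError as exc:
        raise ScoringError(
            f"bid {bid.product_id!r}: no selection for criterion {criterion.id!r}"
        ) from exc
    try:
        return criterion.option(label).score_fraction
    except KeyError as exc:
        raise ScoringError(str(exc)) from exc


def detect_exclusions(bid: ProductBid, config: ToolConfig) -> list[str]:
    """All exclusion reasons the bid triggers, as ``criterion:label`` codes.

    The list is complete — every triggered option is reported, not just the
    first.
    """
    reasons = []
    for criterion in config.by_rank():
        if criterion.external_score:
            continue
        label = bid.selections.get(criterion.id)
        if label is None:
            continue
        try:
            option = criterion.option(label)
        except KeyError as exc:
            raise ScoringError(str(exc)) from exc
        if option.exclusion_trigger:
            reasons.append(f"{criterion.id}:{label}")
    return reasons


def total_score(bid: ProductBid, config: ToolConfig) -> float:
    """Aggregate score S = sum_i w_i * s_i on the 0–100 point scale."""
    return sum(
        criterion.weight * score_criterion(bid, criterion)
        for criterion in config.criteria
    )


def evaluate(bid: ProductBid, config: ToolConfig) -> EvaluationResult:
    """Full evaluation: fractions, weighted points, exclusions, qualification."""
    validate_bid(bid, config)
    fractions = {c.id: score_criterion(bid, c) for c in config.by_rank()}
    weighted = {c.id: c.weight * fractions[c.id] for c in config.by_rank()}
    total = sum(weighted.values())
    reasons = tuple(detect_exclusions(bid, config))
    qualified = not reasons and total >= config.threshold
    return EvaluationResult(
        product_id=bid.product_id,
        active_ingredient=bid.active_ingredient,
        fractions=fractions,
        weighted_points=weighted,
        total_score=total,
        exclusion_reasons=reasons,
        qualified=qualified,
    )


def evaluate_all(
    bids: Iterable[ProductBid], config: ToolConfig
) -> tuple[list[EvaluationResult], list[tuple[str, str]]]:
    """Evaluate every bid; faulty bids become (product_id, error) records.

    A bad row never aborts the run — fault isolation is per product.
    """
    results: list[EvaluationResult] = []
    errors: list[tuple[str, str]] = []
    for bid in bids:
        try:
            results.append(evaluate(bid, config))
        except ScoringError as exc:
            errors.append((bid.product_id, str(exc)))
    return results, errors


# --------------------------------------------------------------------------
# Delimited-table IO
# --------------------------------------------------------------------------

_RESERVED_COLUMNS = ("product_id", "active_ingredient", "price",
                     "pharmacovigilance_percent")


def read_bids(
    source, config: ToolConfig
) -> tuple[list[ProductBid], list[tuple[int, str]]]:
    """Read bids from a CSV (one row per product, one column per criterion).

    Returns (bids, row_errors); a malformed row yields a (row_number,
    message) record and does not abort the remaining rows.
    """
    df = pd.read_csv(source, dtype=str, comment="#")
    missing_cols = [c for c in ("product_id", "active_ingredient", "price")
                    if c not in df.columns]
    if missing_cols:
        raise ScoringError(f"bid table is missing columns {missing_cols}")
    non_external = [c.id for c in config.by_rank() if not c.external_score]
    has_external = any(c.external_score for c in config.criteria)
    bids: list[ProductBid] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            selections = {}
            for cid in non_external:
                if cid not in df.columns or pd.isna(row[cid]):
                    raise ValueError(f"missing selection column or value for {cid!r}")
                selections[cid] = str(row[cid]).strip()
            percent = None
            if has_external:
                if "pharmacovigilance_percent" not in df.columns or pd.isna(
                    row["pharmacovigilance_percent"]
                ):
                    raise ValueError("missing pharmacovigilance_percent")
                percent = float(row["pharmacovigilance_percent"])
            bids.append(
                ProductBid(
                    product_id=str(row["product_id"]).strip(),
                    active_ingredient=str(row["active_ingredient"]).strip(),
                    selections=selections,
                    pharmacovigilance_percent=percent,
                    price=float(row["price"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((rownum, str(exc)))
    return bids, errors


def write_bids(bids: Iterable[ProductBid], config: ToolConfig) -> str:
    """Serialize bids to the CSV layout :func:`read_bids` accepts."""
    non_external = [c.id for c in config.by_rank() if not c.external_score]
    has_external = any(c.external_score for c in config.criteria)
    rows = []
    for bid in bids:
        row: dict[str, object] = {
            "product_id": bid.product_id,
            "active_ingredient": bid.active_ingredient,
        }
        for cid in non_external:
            row[cid] = bid.selections.get(cid, "")
        if has_external:
            row["pharmacovigilance_percent"] = bid.pharmacovigilance_percent
        row["price"] = bid.price
        rows.append(row)
    columns = ["product_id", "active_ingredient", *non_external]
    if has_external:
        columns.append("pharmacovigilance_percent")
    columns.append("price")
    buf = io.StringIO()
    pd.DataFrame(rows, columns=columns).to_csv(buf, index=False)
    return buf.getvalue()


def evaluation_table(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    """Per-product breakdown as a flat table, deterministically ordered."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "product_id": r.product_id,
            "active_ingredient": r.active_ingredient,
        }
        for cid, frac in r.fractions.items():
            row[f"fraction.{cid}"] = frac
            row[f"points.{cid}"] = r.weighted_points[cid]
        row["total_score"] = r.total_score
        row["exclusion_reasons"] = ";".join(r.exclusion_reasons)
        row["qualified"] = r.qualified
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("product_id", kind="mergesort").reset_index(drop=True)
    return df
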