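"""Group elicitation: rankings, option scores, majority decisions, swing weights.

Stakeholder panels vote anonymously on four things: the importance ranking
of the criteria, adjacent-rank importance ratios ("how much more important
is the criterion ranked k than the one ranked k+1?"), per-option scores on
a 0–100% scale, and yes/no decisions on proposed criteria modifications.

Aggregation conventions:

* option scores and importance ratios are aggregated by the **median** of
  the votes, to blunt outliers;
* criterion ranks are aggregated by the **mean** rank, ties broken by the
  median rank and then lexicographic criterion id;
* modification proposals pass by **strict majority** (more than half).

Weights come from the SMART (simple multi-attribute rating technique)
swing-weighting scheme: the lowest-ranked criterion gets a raw weight of 1,
each higher rank multiplies by its elicited adjacent ratio, and the raw
weights are normalized to sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ElicitationError(ValueError):
    """A vote panel is malformed or incomplete for the requested aggregation."""


class VotePanel(BaseModel):
    """Per-participant votes for one elicitation session.

    ``rank_votes[pid]`` maps criterion id -> rank (each participant's ranks
    form a permutation of 1..K).  ``ratio_votes[pid]`` is the ordered list
    of K-1 adjacent-rank importance ratios, position 0 comparing rank 1 to
    rank 2.  ``option_score_votes[pid][cid][label]`` is a 0–100 percentage.
    ``modification_votes[proposal][pid]`` is a yes/no vote.
    """

    model_config = ConfigDict(frozen=True)

    participants: tuple[str, ...]
    rank_votes: dict[str, dict[str, int]] = Field(default_factory=dict)
    ratio_votes: dict[str, tuple[float, ...]] = Field(default_factory=dict)
    option_score_votes: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=dict
    )
    modification_votes: dict[str, dict[str, bool]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _votes_well_formed(self) -> "VotePanel":
        if len(set(self.participants)) != len(self.participants):
            raise ValueError("participants: duplicate participant ids")
        known = set(self.participants)
        for pid, ranks in self.rank_votes.items():
            if pid not in known:
                raise ValueError(f"rank_votes: unknown participant {pid!r}")
            k = len(ranks)
            if sorted(ranks.values()) != list(range(1, k + 1)):
                raise ValueError(
                    f"rank_votes[{pid!r}]: ranks must be a permutation of 1..{k}, "
                    f"got {sorted(ranks.values())}"
                )
        for pid, ratios in self.ratio_votes.items():
            if pid not in known:
                raise ValueError(f"ratio_votes: unknown participant {pid!r}")
            bad = [r for r in ratios if not r >= 1.0]
            if bad:
                raise ValueError(
                    f"ratio_votes[{pid!r}]: ratios must be >= 1, got {bad}"
                )
        for pid, per_crit in self.option_score_votes.items():
            if pid not in known:
                raise ValueError(f"option_score_votes: unknown participant {pid!r}")
            for cid, scores in per_crit.items():
                bad_scores = {
                    lbl: v for lbl, v in scores.items() if not 0.0 <= v <= 100.0
                }
                if bad_scores:
                    raise ValueError(
                        f"option_score_votes[{pid!r}][{cid!r}]: scores must be "
                        f"in [0, 100], got {bad_scores}"
                    )
        return self


class WeightVector(BaseModel):
    """Normalized criterion weights in percentage points (sum = 100)."""

    model_config = ConfigDict(frozen=True)

    weights: dict[str, float]
    provenance: Literal["elicited", "published", "manual"] = "elicited"

    @model_validator(mode="after")
    def _normalized(self) -> "WeightVector":
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"weights sum to {total}, expected 100")
        return self

    def ordered(self) -> tuple[tuple[str, float], ...]:
        """(id, weight) pairs in descending weight order."""
        return tuple(sorted(self.weights.items(), key=lambda kv: (-kv[1], kv[0])))


# --------------------------------------------------------------------------
# Aggregation primitives
# --------------------------------------------------------------------------

def aggregate_option_scores(panel: VotePanel) -> dict[str, dict[str, float]]:
    """Median option score per (criterion, option), as fractions in [0, 1].

    The even-n median is the arithmetic midpoint of the two central votes.
    """
    collected: dict[str, dict[str, list[float]]] = {}
    for per_crit in panel.option_score_votes.values():
        for cid, scores in per_crit.items():
            for label, value in scores.items():
                collected.setdefault(cid, {}).setdefault(label, []).append(value)
    if not collected:
        raise ElicitationError("panel contains no option-score votes")
    return {
        cid: {
            label: float(np.median(votes)) / 100.0
            for label, votes in sorted(labels.items())
        }
        for cid, labels in sorted(collected.items())
    }


def aggregate_ranking(panel: VotePanel) -> list[str]:
    """Criteria ordered by ascending mean rank, relabeled 1..K by position.

    Ties on the mean are broken by the median rank, then by criterion id —
    a deterministic, auditable order.
    """
    if not panel.rank_votes:
        raise ElicitationError("panel contains no rank votes")
    criteria_sets = [frozenset(v) for v in panel.rank_votes.values()]
    if len(set(criteria_sets)) != 1:
        raise ElicitationError("rank votes cover different criteria sets")
    per_criterion: dict[str, list[int]] = {cid: [] for cid in criteria_sets[0]}
    for votes in panel.rank_votes.values():
        for cid, rank in votes.items():
            per_criterion[cid].append(rank)
    return sorted(
        per_criterion,
        key=lambda cid: (
            float(np.mean(per_criterion[cid])),
            float(np.median(per_criterion[cid])),
            cid,
        ),
    )


def majority_pass(votes: Sequence[bool]) -> bool:
    """True iff strictly more than half the votes are yes."""
    if not votes:
        raise ElicitationError("majority_pass: empty vote list")
    return sum(bool(v) for v in votes) > len(votes) / 2


def aggregate_ratio_votes(
    panel: VotePanel,
    aggregator: Callable[[Sequence[float]], float] = np.median,
) -> list[float]:
    """Aggregate (default: median) the adjacent-rank ratio votes per pair.

    Every participant who voted must supply all K-1 ratios; position k
    compares rank k+1 to rank k+2.
    """
    if not panel.ratio_votes:
        raise ElicitationError("panel contains no ratio votes")
    lengths = {len(v) for v in panel.ratio_votes.values()}
    if len(lengths) != 1:
        raise ElicitationError(
            f"ratio votes have inconsistent lengths {sorted(lengths)}; "
            "every voter must cover every adjacent pair"
        )
    (n_pairs,) = lengths
    if n_pairs == 0:
        raise ElicitationError("ratio votes are empty")
    matrix = np.array([list(v) for v in panel.ratio_votes.values()], dtype=float)
    return [float(aggregator(matrix[:, k])) for k in range(n_pairs)]


def swing_weights(
    adjacent_ratios: Sequence[float],
    criterion_ids: Optional[Sequence[str]] = None,
    provenance: Literal["elicited", "published", "manual"] = "elicited",
) -> WeightVector:
    """SMART swing weights from adjacent-rank importance ratios.

    ``adjacent_ratios[k]`` states how much more important the criterion
    ranked k+1 is than the one ranked k+2 (all >= 1).  The lowest rank gets
    raw weight 1; each higher rank multiplies by its ratio; raw weights are
    normalized to sum to 100.  Weights are therefore non-increasing in rank.
    """
    ratios = [float(r) for r in adjacent_ratios]
    bad = [r for r in ratios if not r >= 1.0]
    if bad:
        raise ElicitationError(f"swing_weights: ratios must be >= 1, got {bad}")
    k = len(ratios) + 1
    if criterion_ids is None:
        criterion_ids = [f"rank_{i}" for i in range(1, k + 1)]
    if len(criterion_ids) != k:
        raise ElicitationError(
            f"swing_weights: {len(ratios)} ratios imply {k} criteria, "
            f"got {len(criterion_ids)} ids"
        )
    raw = np.ones(k)
    for i in range(k - 2, -1, -1):
        raw[i] = ratios[i] * raw[i + 1]
    weights = raw / raw.sum() * 100.0
    # keep the invariant exact against accumulated floating error
    weights[-1] += 100.0 - weights.sum()
    return WeightVector(
        weights={cid: float(w) for cid, w in zip(criterion_ids, weights)},
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElicitationResult:
    """Audit trail of a weight elicitation: every intermediate quantity."""

    ranking: tuple[str, ...]
    pair_medians: tuple[float, ...]
    raw_weights: tuple[float, ...]
    weights: WeightVector
    option_scores: dict[str, dict[str, float]] = field(default_factory=dict)

    def audit_records(self) -> list[dict]:
        records = []
        for i, cid in enumerate(self.ranking):
            records.append(
                {
                    "criterion": cid,
                    "rank": i + 1,
                    "ratio_to_next": self.pair_medians[i]
                    if i < len(self.pair_medians)
                    else None,
                    "raw_weight": self.raw_weights[i],
                    "weight": self.weights.weights[cid],
                }
            )
        return records


def elicit_weights(
    panel: VotePanel,
    ratio_aggregator: Callable[[Sequence[float]], float] = np.median,
) -> ElicitationResult:
    """Run the complete elicitation: ranking, ratio medians, swing weights.

    Option-score medians are included in the audit trail when the panel
    carries option-score votes.
    """
    ranking = aggregate_ranking(panel)
    medians = aggregate_ratio_votes(panel, aggregator=ratio_aggregator)
    if len(medians) != len(ranking) - 1:
        raise ElicitationError(
            f"panel has {len(medians)} adjacent-pair ratios but "
            f"{len(ranking)} ranked criteria ({len(ranking) - 1} pairs needed)"
        )
    wv = swing_weights(medians, criterion_ids=ranking)
    raw = np.ones(len(ranking))
    for i in range(len(ranking) - 2, -1, -1):
        raw[i] = medians[i] * raw[i + 1]
    scores: dict[str, dict[str, float]] = {}
    if panel.option_score_votes:
        scores = aggregate_option_scores(panel)
    return ElicitationResult(
        ranking=tuple(ranking),
        pair_medians=tuple(medians),
        raw_weights=tuple(float(r) for r in raw),
        weights=wv,
        option_scores=scores,
    )


# --------------------------------------------------------------------------
# Long-format table IO (participant, vote_type, item, value)
# --------------------------------------------------------------------------

def panel_to_frame(panel: VotePanel):
    """Serialize a panel to a long-format table.

    ``vote_type`` is one of rank / ratio / option_score / modification;
    ``item`` is the criterion id, the 1-based adjacent-pair index, the
    ``criterion/label`` pair, or the proposal key respectively.
    """
    import pandas as pd

    rows = []
    for pid in panel.participants:
        for cid, rank in sorted(panel.rank_votes.get(pid, {}).items()):
            rows.append((pid, "rank", cid, float(rank)))
        for k, ratio in enumerate(panel.ratio_votes.get(pid, ()), start=1):
            rows.append((pid, "ratio", str(k), float(ratio)))
        for cid, scores in sorted(panel.option_score_votes.get(pid, {}).items()):
            for label, value in sorted(scores.items()):
                rows.append((pid, "option_score", f"{cid}/{label}", float(value)))
    for proposal, votes in sorted(panel.modification_votes.items()):
        for pid, vote in sorted(votes.items()):
            rows.append((pid, "modification", proposal, float(bool(vote))))
    return pd.DataFrame(rows, columns=["participant", "vote_type", "item", "value"])


def panel_from_frame(df) -> VotePanel:
    """Parse a long-format vote table (inverse of :func:`panel_to_frame`)."""
    required = {"participant", "vote_type", "item", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ElicitationError(f"vote table is missing columns {sorted(missing)}")
    participants = tuple(dict.fromkeys(str(p) for p in df["participant"]))
    rank_votes: dict[str, dict[str, int]] = {}
    ratio_lists: dict[str, dict[int, float]] = {}
    option_votes: dict[str, dict[str, dict[str, float]]] = {}
    mod_votes: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        pid, kind, item = str(row["participant"]), str(row["vote_type"]), str(row["item"])
        value = float(row["value"])
        if kind == "rank":
            rank_votes.setdefault(pid, {})[item] = int(value)
        elif kind == "ratio":
            ratio_lists.setdefault(pid, {})[int(item)] = value
        elif kind == "option_score":
            cid, _, label = item.partition("/")
            if not label:
                raise ElicitationError(
                    f"option_score item {item!r} must be 'criterion/label'"
                )
            option_votes.setdefault(pid, {}).setdefault(cid, {})[label] = value
        elif kind == "modification":
            mod_votes.setdefault(item, {})[pid] = bool(value)
        else:
            raise ElicitationError(f"unknown vote_type {kind!r}")
    ratio_votes: dict[str, tuple[float, ...]] = {}
    for pid, by_pair in ratio_lists.items():
        expected = list(range(1, len(by_pair) + 1))
        if sorted(by_pair) != expected:
            missing_pairs = sorted(set(expected) - set(by_pair))
            raise ElicitationError(
                f"ratio votes for {pid!r} are missing adjacent pair(s) "
                f"{missing_pairs or sorted(by_pair)}"
            )
        ratio_votes[pid] = tuple(by_pair[k] for k in expected)
    return VotePanel(
        participants=participants,
        rank_votes=rank_votes,
        ratio_votes=ratio_votes,
        option_score_votes=option_votes,
        modification_votes=mod_votes,
    )


def weights_from_ranked(ranked_weights: Mapping[str, float]) -> list[float]:
    """Adjacent quotients of a weight map taken in descending-weight order.

    The inverse of :func:`swing_weights` for a noiseless panel: feeding the
    returned ratios back through swing weighting recovers the weights.
    """
    ordered = sorted(ranked_weights.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [w for _, w in ordered]
    if any(w <= 0 for w in values):
        raise ElicitationError("all weights must be positive to form quotients")
    return [values[i] / values[i + 1] for i in range(len(values) - 1)]
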