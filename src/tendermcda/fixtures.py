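"""Synthetic bids, configs and vote panels with known ground truth.

Every generator is a pure function of a :class:`FixtureSpec` (plus a config
where needed): the same spec, including its seed, always produces the same
data.  The vote-panel generator emulates a stakeholder workshop around a
known generating weight vector, so elicitation can be tested by parameter
recovery:

* ratio votes: each participant reports the true adjacent quotients of the
  generating weights, perturbed by multiplicative log-normal noise with
  scale ``vote_noise`` and truncated to >= 1;
* rank votes: the true ranking with independent adjacent swaps, each pair
  swapped with probability ``vote_noise`` in one left-to-right pass;
* option-score votes: the configured option percentages with additive
  Gaussian jitter of standard deviation ``100 * vote_noise``, rounded to
  integers and clipped to [0, 100].

With ``vote_noise = 0`` every participant votes the truth and the
elicitation pipeline recovers the generating weights exactly.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from tendermcda.config import Criterion, ScoringOption, ToolConfig
from tendermcda.elicitation import ElicitationError, VotePanel, weights_from_ranked
from tendermcda.scoring import ProductBid

#: Default panel size: the workshops hosted thirty-five voting experts.
DEFAULT_PARTICIPANTS = 35


class FixtureSpec(BaseModel):
    """Parameters of one synthetic dataset."""

    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    n_products: int = Field(default=10, ge=0)
    n_participants: int = Field(default=DEFAULT_PARTICIPANTS, ge=1)
    n_criteria: int = Field(default=7, ge=2)
    true_weights: Optional[dict[str, float]] = None
    vote_noise: float = Field(default=0.0, ge=0.0)
    exclusion_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    price_range: tuple[float, float] = (50.0, 500.0)
    products_per_ingredient: int = Field(default=3, ge=1)

    @model_validator(mode="after")
    def _consistent(self) -> "FixtureSpec":
        lo, hi = self.price_range
        if not 0 < lo <= hi:
            raise ValueError(f"price_range must be 0 < lo <= hi, got {self.price_range}")
        if self.true_weights is not None:
            if len(self.true_weights) != self.n_criteria:
                raise ValueError(
                    f"true_weights has {len(self.true_weights)} entries, "
                    f"n_criteria is {self.n_criteria}"
                )
        return self

    def resolved_weights(self) -> dict[str, float]:
        """The generating weights; a geometric ladder when none are given."""
        if self.true_weights is not None:
            if any(w <= 0 for w in self.true_weights.values()):
                raise ElicitationError(
                    "true_weights must be strictly positive (adjacent "
                    "quotients are undefined at zero)"
                )
            return dict(self.true_weights)
        raw = 1.2 ** np.arange(self.n_criteria - 1, -1, -1)
        weights = raw / raw.sum() * 100.0
        return {f"crit_{i + 1}": float(w) for i, w in enumerate(weights)}


def generate_bids(spec: FixtureSpec, config: ToolConfig) -> list[ProductBid]:
    """Random valid bids; a fraction ``exclusion_rate`` trigger an exclusion.

    Products are grouped into active ingredients of size
    ``products_per_ingredient`` so ranking fixtures exercise per-ingredient
    grouping.
    """
    rng = np.random.default_rng(spec.seed)
    non_external = [c for c in config.by_rank() if not c.external_score]
    has_external = any(c.external_score for c in config.criteria)
    with_triggers = [
        c for c in non_external if any(o.exclusion_trigger for o in c.options)
    ]
    bids = []
    for i in range(spec.n_products):
        excluded = bool(with_triggers) and rng.random() < spec.exclusion_rate
        trigger_on = (
            with_triggers[rng.integers(len(with_triggers))].id if excluded else None
        )
        selections = {}
        for criterion in non_external:
            if criterion.id == trigger_on:
                pool = [o for o in criterion.options if o.exclusion_trigger]
            else:
                pool = [o for o in criterion.options if not o.exclusion_trigger]
            selections[criterion.id] = pool[rng.integers(len(pool))].label
        lo, hi = spec.price_range
        bids.append(
            ProductBid(
                product_id=f"product_{i + 1:03d}",
                active_ingredient=f"ingredient_{i // spec.products_per_ingredient + 1}",
                selections=selections,
                pharmacovigilance_percent=(
                    round(float(rng.uniform(0, 100)), 1) if has_external else None
                ),
                price=round(float(rng.uniform(lo, hi)), 2),
            )
        )
    return bids


def generate_vote_panel(
    spec: FixtureSpec, config: Optional[ToolConfig] = None
) -> VotePanel:
    """A synthetic workshop panel generated from known weights.

    When a config is supplied, option-score votes are generated around the
    configured option fractions as well.
    """
    rng = np.random.default_rng(spec.seed)
    weights = spec.resolved_weights()
    true_ratios = np.array(weights_from_ranked(weights))
    ranking = [cid for cid, _ in sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))]
    k = len(ranking)
    participants = tuple(f"p{i + 1:02d}" for i in range(spec.n_participants))

    rank_votes: dict[str, dict[str, int]] = {}
    ratio_votes: dict[str, tuple[float, ...]] = {}
    option_votes: dict[str, dict[str, dict[str, float]]] = {}
    for pid in participants:
        noisy = true_ratios * np.exp(
            rng.normal(0.0, spec.vote_noise, size=true_ratios.shape)
        )
        ratio_votes[pid] = tuple(float(max(r, 1.0)) for r in noisy)

        order = list(ranking)
        for i in range(k - 1):
            if rng.random() < spec.vote_noise:
                order[i], order[i + 1] = order[i + 1], order[i]
        rank_votes[pid] = {cid: pos + 1 for pos, cid in enumerate(order)}

        if config is not None:
            per_crit: dict[str, dict[str, float]] = {}
            for criterion in config.by_rank():
                if criterion.external_score:
                    continue
                per_crit[criterion.id] = {
                    o.label: float(
                        np.clip(
                            round(
                                o.score_fraction * 100
                                + rng.normal(0.0, 100.0 * spec.vote_noise)
                            ),
                            0,
                            100,
                        )
                    )
                    for o in criterion.options
                }
            option_votes[pid] = per_crit

    return VotePanel(
        participants=participants,
        rank_votes=rank_votes,
        ratio_votes=ratio_votes,
        option_score_votes=option_votes,
    )


def generate_config(
    seed: int, n_criteria: int = 5, max_options: int = 4
) -> ToolConfig:
    """A small random but valid config, for randomized property tests."""
    if n_criteria < 1:
        raise ValueError("n_criteria must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.5, 2.0, size=n_criteria)
    weights = raw / raw.sum() * 100.0
    weights[-1] += 100.0 - weights.sum()
    order = rng.permutation(n_criteria)
    criteria = []
    for i in range(n_criteria):
        n_opts = int(rng.integers(2, max_options + 1))
        fractions = np.sort(rng.uniform(0, 1, size=n_opts))
        fractions[0] = 0.0
        fractions[-1] = 1.0
        trigger_first = bool(rng.random() < 0.3)
        options = tuple(
            ScoringOption(
                label=f"c{i + 1}_opt{j + 1}",
                score_fraction=float(f),
                exclusion_trigger=trigger_first and j == 0,
            )
            for j, f in enumerate(fractions)
        )
        criteria.append(
            Criterion(
                id=f"c{i + 1}",
                name=f"criterion {i + 1}",
                rank=int(order[i]) + 1,
                weight=float(weights[i]),
                options=options,
            )
        )
    return ToolConfig(
        criteria=tuple(criteria),
        threshold=float(rng.uniform(40, 80)),
        weight_tolerance=0.01,
    )
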