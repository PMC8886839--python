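"""Tool configuration: criteria, scoring functions, weights, and threshold.

A :class:`ToolConfig` is the complete description of the technical phase of
the tender: an ordered list of criteria, each with a weight (percentage
points summing to 100), a rank (1 = most important) and an ordered
categorical scoring function mapping option labels to fractions in [0, 1].
Options may carry an ``exclusion_trigger`` flag: selecting such an option
disqualifies a product regardless of its other scores.

One criterion — pharmacovigilance services — is scored externally: the
national drug authority supplies a percentage fulfillment, so the criterion
carries no option list (``external_score = True``).

Configurations are serialized to a versioned YAML schema via
:func:`save_config` / :func:`load_config`; the committee-driven evolution of
the criteria list (exclude / merge / add / rename) is modeled by
:func:`apply_modification`.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration failed schema or invariant validation."""


class ScoringOption(BaseModel):
    """One level of a criterion's categorical scoring function."""

    model_config = ConfigDict(frozen=True)

    label: str
    score_fraction: float = Field(ge=0.0, le=1.0)
    exclusion_trigger: bool = False

    @model_validator(mode="after")
    def _trigger_scores_zero(self) -> "ScoringOption":
        if self.exclusion_trigger and self.score_fraction != 0.0:
            raise ValueError(
                f"option {self.label!r}: an exclusion trigger must have "
                f"score_fraction 0, got {self.score_fraction}"
            )
        return self


class Criterion(BaseModel):
    """A tender-evaluation attribute with rank, weight and scoring function.

    ``weight`` is in percentage points of the 100-point aggregate scale.
    ``external_score`` marks a criterion whose fraction is supplied with the
    bid (the pharmacovigilance percentage) rather than chosen from options.
    """

    model_config = ConfigDict(frozen=True)

    id: str = Field(min_length=1, pattern=r"^[A-Za-z0-9_\-]+$")
    name: str
    rank: int = Field(ge=1)
    weight: float = Field(ge=0.0)
    options: tuple[ScoringOption, ...] = ()
    external_score: bool = False

    @model_validator(mode="after")
    def _options_consistent(self) -> "Criterion":
        if self.external_score:
            if self.options:
                raise ValueError(
                    f"criterion {self.id!r}: external_score criteria carry no options"
                )
        else:
            if len(self.options) < 2:
                raise ValueError(
                    f"criterion {self.id!r}: needs at least 2 scoring options, "
                    f"got {len(self.options)}"
                )
            labels = [o.label for o in self.options]
            if len(set(labels)) != len(labels):
                dupes = sorted({l for l in labels if labels.count(l) > 1})
                raise ValueError(
                    f"criterion {self.id!r}: duplicate option labels {dupes}"
                )
        return self

    def option(self, label: str) -> ScoringOption:
        for opt in self.options:
            if opt.label == label:
                return opt
        raise KeyError(
            f"criterion {self.id!r} has no option {label!r}; "
            f"known: {[o.label for o in self.options]}"
        )


class ToolConfig(BaseModel):
    """Complete technical-phase configuration.

    ``weights_stale`` marks a configuration whose criteria list changed after
    weights were elicited; stale weights are exempt from the sum-to-100 check
    until re-elicited or manually revalidated.
    """

    model_config = ConfigDict(frozen=True)

    schema_version: int = SCHEMA_VERSION
    criteria: tuple[Criterion, ...]
    threshold: float = Field(gt=0.0, le=100.0)
    weight_tolerance: float = Field(default=0.005, gt=0.0)
    weights_stale: bool = False

    @model_validator(mode="after")
    def _registry_invariants(self) -> "ToolConfig":
        if not self.criteria:
            raise ValueError("criteria: configuration must contain at least one criterion")
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"criteria: duplicate criterion ids {dupes}")
        ranks = sorted(c.rank for c in self.criteria)
        if ranks != list(range(1, len(self.criteria) + 1)):
            raise ValueError(
                f"criteria: ranks must be a permutation of 1..{len(self.criteria)}, "
                f"got {sorted(c.rank for c in self.criteria)}"
            )
        if not self.weights_stale:
            total = sum(c.weight for c in self.criteria)
            if abs(total - 100.0) > self.weight_tolerance:
                raise ValueError(
                    f"criteria: weights sum to {total:.4f}, expected 100 "
                    f"within ±{self.weight_tolerance}"
                )
        return self

    def by_id(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(f"no criterion with id {criterion_id!r}")

    def by_rank(self) -> tuple[Criterion, ...]:
        return tuple(sorted(self.criteria, key=lambda c: c.rank))

    @property
    def weights(self) -> dict[str, float]:
        return {c.id: c.weight for c in self.criteria}


class ModificationProposal(BaseModel):
    """A committee-proposed change to the criteria list."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["exclude", "merge", "add", "rename"]
    target_ids: tuple[str, ...] = ()
    replacement: Optional[Criterion] = None
    note: str = ""

    @model_validator(mode="after")
    def _shape(self) -> "ModificationProposal":
        if self.kind == "exclude" and not self.target_ids:
            raise ValueError("exclude: at least one target id required")
        if self.kind == "merge":
            if len(self.target_ids) < 2:
                raise ValueError("merge: at least two target ids required")
            if self.replacement is None:
                raise ValueError("merge: replacement criterion required")
        if self.kind == "rename":
            if len(self.target_ids) != 1:
                raise ValueError("rename: exactly one target id required")
            if self.replacement is None:
                raise ValueError("rename: replacement criterion required")
        if self.kind == "add":
            if self.replacement is None:
                raise ValueError("add: replacement criterion required")
            if self.target_ids:
                raise ValueError("add: target_ids must be empty")
        return self


# --------------------------------------------------------------------------
# Published default configuration
# --------------------------------------------------------------------------

def _opt(label: str, fraction: float, trigger: bool = False) -> ScoringOption:
    return ScoringOption(label=label, score_fraction=fraction, exclusion_trigger=trigger)


# The three hard exclusion triggers: a product not marketed in its country of
# origin, lacking a GMP certificate, or with supply reliability below 25%
# (three-quarters or more of past orders late or incomplete) is disqualified
# outright.  Intermediate ladder levels beyond the documented endpoints are
# deliberately left to the config editor; the macroeconomic-benefit middle
# level defaults to the midpoint of its 0–100% scale.
_DEFAULT_OPTIONS: dict[str, tuple[ScoringOption, ...]] = {
    "reference_country_use": (
        _opt("not marketed in country of origin", 0.0, trigger=True),
        _opt("marketed in country of origin and used in reference countries", 1.0),
    ),
    "reference_equivalence": (
        _opt("equivalence with reference product not demonstrated", 0.0),
        _opt("equivalence with reference product demonstrated", 1.0),
    ),
    "manufacturing_quality": (
        _opt("no GMP certificate", 0.0, trigger=True),
        _opt("GMP certificate held", 1.0),
    ),
    "supply_reliability": (
        _opt("supply reliability below 25%", 0.0, trigger=True),
        _opt("supply reliability 25% or above", 1.0),
    ),
    "local_use": (
        _opt("no previous use in local settings", 0.0),
        _opt("previous use in local settings", 1.0),
    ),
    "macroeconomic_benefit": (
        _opt("no manufacturing activity in Egypt", 0.0),
        _opt("local packaging only in Egypt", 0.5),
        _opt("full manufacturing in Egypt", 1.0),
    ),
}

#: (id, display name, weight) in rank order — the published weight vector.
_DEFAULT_CRITERIA: tuple[tuple[str, str, float], ...] = (
    ("reference_country_use", "use in reference countries", 23.49),
    ("reference_equivalence", "equivalence with the reference product", 18.79),
    ("manufacturing_quality", "manufacturing quality", 15.53),
    ("pharmacovigilance", "pharmacovigilance services", 12.94),
    ("supply_reliability", "supply reliability", 10.78),
    ("local_use", "previous use in local settings", 9.80),
    ("macroeconomic_benefit", "macroeconomic benefit", 8.67),
)

DEFAULT_THRESHOLD = 65.0


def default_config() -> ToolConfig:
    """The published seven-criterion configuration.

    Weights (percentage points, rank order): 23.49, 18.79, 15.53, 12.94,
    10.78, 9.80, 8.67 — summing to 100.00.  Threshold: 65 points.
    Pharmacovigilance services is externally scored.
    """
    criteria = []
    for rank, (cid, name, weight) in enumerate(_DEFAULT_CRITERIA, start=1):
        external = cid == "pharmacovigilance"
        criteria.append(
            Criterion(
                id=cid,
                name=name,
                rank=rank,
                weight=weight,
                options=() if external else _DEFAULT_OPTIONS[cid],
                external_score=external,
            )
        )
    return ToolConfig(criteria=tuple(criteria), threshold=DEFAULT_THRESHOLD)


_GENERIC_OPTIONS = (
    _opt("criterion not fulfilled", 0.0),
    _opt("criterion fully fulfilled", 1.0),
)

#: The pre-workshop primary list: the six criteria that survived unchanged,
#: the two manufacturing-quality parents later merged, and the five criteria
#: the stakeholders voted to drop.
_PRIMARY_CRITERIA: tuple[tuple[str, str], ...] = (
    ("reference_country_use", "use in reference countries"),
    ("reference_equivalence", "equivalence with the reference product"),
    ("api_quality", "active pharmaceutical ingredient manufacturing quality"),
    ("finished_product_quality", "finished product manufacturing quality"),
    ("pharmacovigilance", "pharmacovigilance services"),
    ("supply_reliability", "supply reliability"),
    ("local_use", "previous use in local settings"),
    ("macroeconomic_benefit", "macroeconomic benefit"),
    ("refund_replacement", "refund or replacement of expired products"),
    ("expiry_date", "expiry date"),
    ("ease_of_use", "ease of use"),
    ("storage_conditions", "storage conditions"),
    ("production_capacity", "production capacity and financial ability of the company"),
)


def primary_criteria_list() -> ToolConfig:
    """The 13-criterion pre-workshop list (unweighted, weights_stale)."""
    criteria = []
    for rank, (cid, name) in enumerate(_PRIMARY_CRITERIA, start=1):
        external = cid == "pharmacovigilance"
        options: tuple[ScoringOption, ...]
        if external:
            options = ()
        else:
            options = _DEFAULT_OPTIONS.get(cid, _GENERIC_OPTIONS)
        criteria.append(
            Criterion(
                id=cid,
                name=name,
                rank=rank,
                weight=0.0,
                options=options,
                external_score=external,
            )
        )
    return ToolConfig(
        criteria=tuple(criteria), threshold=DEFAULT_THRESHOLD, weights_stale=True
    )


def workshop_modifications() -> tuple[ModificationProposal, ...]:
    """The six documented committee modifications reducing 13 criteria to 7.

    One exclusion of a service made mandatory by tender requirements, one
    merge of the two manufacturing-quality criteria, three exclusions of
    non-differentiating criteria, and one exclusion of a criterion already
    reflected in supply reliability.
    """
    merged = Criterion(
        id="manufacturing_quality",
        name="manufacturing quality",
        rank=3,
        weight=0.0,
        options=_DEFAULT_OPTIONS["manufacturing_quality"],
    )
    return (
        ModificationProposal(
            kind="exclude",
            target_ids=("refund_replacement",),
            note="mandatory for tender requirements, not differentiating",
        ),
        ModificationProposal(
            kind="merge",
            target_ids=("api_quality", "finished_product_quality"),
            replacement=merged,
            note="merged to avoid redundancy",
        ),
        ModificationProposal(kind="exclude", target_ids=("expiry_date",)),
        ModificationProposal(kind="exclude", target_ids=("ease_of_use",)),
        ModificationProposal(kind="exclude", target_ids=("storage_conditions",)),
        ModificationProposal(
            kind="exclude",
            target_ids=("production_capacity",),
            note="already reflected in supply reliability",
        ),
    )


# --------------------------------------------------------------------------
# Modification engine
# --------------------------------------------------------------------------

def apply_modification(config: ToolConfig, proposal: ModificationProposal) -> ToolConfig:
    """Apply one committee modification and compact ranks to 1..K'.

    Weights are never renormalized here: structural changes mark the config
    ``weights_stale`` because weighting is elicited only after the criteria
    list is fixed.  ``rename`` keeps the target's rank and weight.
    """
    known = {c.id for c in config.criteria}
    missing = [t for t in proposal.target_ids if t not in known]
    if missing:
        raise ConfigError(f"{proposal.kind}: unknown criterion ids {missing}")

    ordered = list(config.by_rank())

    if proposal.kind == "exclude":
        ordered = [c for c in ordered if c.id not in proposal.target_ids]
    elif proposal.kind == "merge":
        assert proposal.replacement is not None
        ordered = [c for c in ordered if c.id not in proposal.target_ids]
        pos = min(max(proposal.replacement.rank, 1), len(ordered) + 1) - 1
        ordered.insert(pos, proposal.replacement)
    elif proposal.kind == "add":
        assert proposal.replacement is not None
        if proposal.replacement.id in known:
            raise ConfigError(f"add: criterion id {proposal.replacement.id!r} already exists")
        pos = min(max(proposal.replacement.rank, 1), len(ordered) + 1) - 1
        ordered.insert(pos, proposal.replacement)
    elif proposal.kind == "rename":
        assert proposal.replacement is not None
        (target,) = proposal.target_ids
        ordered = [
            c.model_copy(update={"id": proposal.replacement.id,
                                 "name": proposal.replacement.name})
            if c.id == target else c
            for c in ordered
        ]

    if not ordered:
        raise ConfigError(f"{proposal.kind}: modification would empty the criteria list")

    compacted = tuple(
        c.model_copy(update={"rank": k}) for k, c in enumerate(ordered, start=1)
    )
    stale = config.weights_stale or proposal.kind in ("exclude", "merge", "add")
    try:
        return config.model_copy(update={"criteria": compacted, "weights_stale": stale})
    except ValueError as exc:  # pragma: no cover - revalidation failure
        raise ConfigError(str(exc)) from exc


# --------------------------------------------------------------------------
# Serialization (versioned YAML, deterministic)
# --------------------------------------------------------------------------

def save_config(config: ToolConfig) -> str:
    """Serialize to canonical YAML: stable field order, byte-deterministic."""
    doc = {
        "schema_version": config.schema_version,
        "threshold": config.threshold,
        "weight_tolerance": config.weight_tolerance,
        "weights_stale": config.weights_stale,
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "rank": c.rank,
                "weight": c.weight,
                "external_score": c.external_score,
                "options": [
                    {
                        "label": o.label,
                        "score_fraction": o.score_fraction,
                        "exclusion_trigger": o.exclusion_trigger,
                    }
                    for o in c.options
                ],
            }
            for c in config.by_rank()
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=100)


def load_config(source: str) -> ToolConfig:
    """Parse and validate a YAML configuration.

    Raises :class:`ConfigError` naming the offending field path on schema or
    invariant violations.
    """
    try:
        doc = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"
        )
    try:
        criteria = tuple(
            Criterion(
                id=c["id"],
                name=c["name"],
                rank=c["rank"],
                weight=c["weight"],
                external_score=c.get("external_score", False),
                options=tuple(
                    ScoringOption(
                        label=o["label"],
                        score_fraction=o["score_fraction"],
                        exclusion_trigger=o.get("exclusion_trigger", False),
                    )
                    for o in c.get("options", [])
                ),
            )
            for c in doc.get("criteria", [])
        )
        return ToolConfig(
            schema_version=version,
            criteria=criteria,
            threshold=doc.get("threshold", DEFAULT_THRESHOLD),
            weight_tolerance=doc.get("weight_tolerance", 0.005),
            weights_stale=doc.get("weights_stale", False),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required field {exc.args[0]!r}") from exc
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def validate_config(config: ToolConfig) -> list[str]:
    """Itemized advisory checks beyond the hard model invariants."""
    issues: list[str] = []
    if config.weights_stale:
        issues.append(
            "weights are marked stale (criteria changed after elicitation); "
            "re-elicit or revalidate before scoring"
        )
    total = sum(c.weight for c in config.criteria)
    if abs(total - 100.0) > config.weight_tolerance:
        issues.append(
            f"weights sum to {total:.4f}, expected 100 within ±{config.weight_tolerance}"
        )
    for c in config.criteria:
        if not c.external_score and not any(o.score_fraction == 1.0 for o in c.options):
            issues.append(
                f"criterion {c.id!r}: no option awards the full fraction 1.0"
            )
    return issues


# --------------------------------------------------------------------------
# Display rounding
# --------------------------------------------------------------------------

def display_weights(weights: dict[str, float], decimals: int = 2) -> dict[str, float]:
    """Round weights for display so the printed set sums exactly to 100.

    Largest-remainder method: floor every weight at the display precision,
    then distribute the leftover display units to the entries with the
    largest remainders (ties by larger weight, then id).
    """
    scale = 10 ** decimals
    units = {k: w * scale for k, w in weights.items()}
    floors = {k: math.floor(u + 1e-9) for k, u in units.items()}
    leftover = round(100 * scale - sum(floors.values()))
    order = sorted(
        weights,
        key=lambda k: (-(units[k] - floors[k]), -weights[k], k),
    )
    out = dict(floors)
    if leftover >= 0:
        for k in order[:leftover]:
            out[k] += 1
    else:  # weights summed a hair above 100: take units from smallest remainders
        for k in reversed(order[len(order) + leftover:]):
            out[k] -= 1
    return {k: out[k] / scale for k in weights}
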