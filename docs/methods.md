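# Methods

## The decision model

`tendermcda` implements a weighted additive multi-criteria decision analysis
(MCDA) model for a two-phase pharmaceutical tender. In the **technical
phase**, each product bid is scored on K non-price criteria. Criterion *i*
has a weight *wᵢ* (percentage points, Σwᵢ = 100) and an ordered categorical
scoring function: the bid's selected option maps to a fraction *sᵢ* ∈ [0, 1],
and the aggregate score on the 0–100 point scale is

    S = Σᵢ wᵢ · sᵢ

A bid qualifies for the **financial phase** iff it selects no
exclusion-trigger option and S ≥ T, the qualification threshold (default
T = 65; the comparison is inclusive and made at full precision — a 64.996
never qualifies by virtue of printing as 65.00). Exclusion dominates
unconditionally: a single trigger (product not marketed in its country of
origin, no GMP certificate, supply reliability below 25%) disqualifies a bid
regardless of its total.

In the financial phase, qualified bids for the same active ingredient are
ranked by **price per point**, P/S, ascending; the lowest price per point is
the preferred option. Price never enters the technical score — the two
phases are institutionally separate, and price per point is the bridge
between them.

### Default configuration

The default configuration carries seven criteria with the weights elicited
in the stakeholder workshops (rank order): use in reference countries 23.49,
equivalence with the reference product 18.79, manufacturing quality 15.53,
pharmacovigilance services 12.94, supply reliability 10.78, previous use in
local settings 9.80, macroeconomic benefit 8.67. One criterion —
pharmacovigilance services — is *externally scored*: the national drug
authority supplies a percentage fulfillment with the bid, mapped linearly to
the fraction (no nonlinearity is documented, so none is modeled).

The default option lists carry only the documented levels: the three
exclusion triggers, the three macroeconomic-benefit levels (no manufacturing
activity / local packaging only / full manufacturing), and a
full-fulfillment option per criterion. Intermediate ladder levels are config
data meant to be edited per tender, not code. The macroeconomic-benefit
middle level defaults to 0.5 — the midpoint of a scale whose endpoints (0%
and 100%) are fixed by the elicitation prompt; no published value pins the
middle, and the midpoint is the neutral choice.

## Weight elicitation

Weights come from SMART swing weighting over adjacent ranks. Stakeholders
first rank the K criteria, then state, for each adjacent pair, how much more
important the criterion ranked k is than the one ranked k+1 (a multiplier
rₖ ≥ 1; the higher-ranked criterion is always the numerator). The raw weight
of rank K is 1, each higher rank multiplies by its ratio, and the raw
weights are normalized to sum to 100. Ratios ≥ 1 guarantee weights
non-increasing in rank, and normalization makes the result invariant to any
common scaling of the raw weights.

Group aggregation follows two distinct conventions, both deliberate:
**median** for option-score and ratio votes (robust to outlier votes; the
even-n median is the midpoint of the two central values), **mean** for rank
votes. Rank ties are broken by the median rank, then lexicographic criterion
id — an arbitrary but deterministic and auditable rule. Whether the original
panel aggregated ratio votes by median or otherwise is not documented, so
the aggregator is a pluggable strategy (`aggregate_ratio_votes(...,
aggregator=)`) with median as default. Ratio votes are modeled as
multipliers rather than point allocations; this is a documented assumption.

Modification proposals to the criteria list pass by strict majority (> n/2;
exactly half fails). Structural modifications (exclude / merge / add)
compact ranks to 1..K′ and mark the configuration's weights *stale* rather
than renormalizing them, because weighting is elicited only after the
criteria list is fixed; a rename changes no structure and keeps weights
fresh.

## Synthetic data

The fixture module emulates the study conditions: panels of 35 voting
participants (the workshop attendance) around a known generating weight
vector, and bid tables grouped into active ingredients. The noise model is
explicit so recovery tests mean something:

* ratio votes — true adjacent quotients times log-normal noise
  (`exp(N(0, σ))`, σ = `vote_noise`), truncated to ≥ 1;
* rank votes — the true ranking with each adjacent pair swapped with
  probability `vote_noise` in one left-to-right pass;
* option-score votes — configured percentages plus N(0, 100·σ) jitter,
  rounded to integers and clipped to [0, 100];
* bids — a bid contains an exclusion trigger with probability
  `exclusion_rate` (one trigger on one randomly chosen trigger-bearing
  criterion), otherwise only non-trigger options; prices are uniform on the
  configured range.

At zero noise every participant votes the truth and the elicitation
pipeline recovers the generating weights exactly (a fixed point of
swing weighting, since the ratios are the adjacent weight quotients). A
one-time calibration (200 replicates, 35 voters, σ = 0.05) found the
recovered weights within 1 point of truth in 100% of replicates; the test
suite freezes the ≥ 95% acceptance rate at 60 replicates. Recovery error is
checked to be non-decreasing on a noise grid averaged over seeds.

What the generator does **not** emulate: strategic or correlated voting,
participant attrition, heteroscedastic expertise, or real bid dossiers.
Passing recovery tests therefore demonstrate correctness of the aggregation
arithmetic under an idealized honest panel, not robustness to real committee
dynamics.

## Numerical and design choices

* All comparisons (qualification, ranking) happen at full precision; a
  single display rule (two decimals, half-away-from-zero) is applied only at
  the rendering edge. The displayed 2.14 EGP per point is the rounding of
  150/70 = 2.142857…
* Displayed weight sets use largest-remainder rounding so the printed
  weights sum to exactly 100.00.
* Ranking tie-break chain: lower price per point, then higher total score,
  then lower price, then product id — a strict total order, so output
  ordering is reproducible across runs. Equal price per point is not
  documented behavior; favoring the higher score prefers quality at equal
  value-for-money.
* Missing bid selections are a hard error, never imputed as zero: silent
  zero-scoring could disqualify a bid through a data-entry gap.
* Split awards are out of scope: exactly one preferred option is flagged
  per ingredient, with the full ranking emitted so a committee can deviate.
* The configuration is a versioned YAML schema (spreadsheet front-ends are
  not reviewable or diffable); serialization is byte-deterministic with a
  round-trip identity property.
* Supply reliability is an input option selection, not a computation: the
  historical order-fulfillment percentage is assessed upstream of the tool.

## Problem sizes

The test suite and the acceptance script run the pipeline at desk scale:
7-criterion configurations, panels of 35 voters, bid tables up to ~400 rows,
50–60 elicitation replicates for the recovery-rate estimates, and
randomized property checks at K ≤ 6 criteria with ≤ 4 options. The whole
suite completes in a few seconds.

## Limitations

* The published scoring table's intermediate option levels are not encoded;
  defaults cover the documented endpoints and triggers only.
* The tool reproduces the published weight vector through the swing-weight
  pipeline, but the raw workshop votes are unpublished, so elicitation is
  validated by synthetic parameter recovery rather than against real votes.
* Currency is a label carried through, never converted; price comparability
  across bids (per comparable unit) is the caller's responsibility.
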