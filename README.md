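# tendermcda

A multi-criteria decision analysis (MCDA) engine for national tenders of
off-patent (generic) medicines run in two institutionally separate phases: a
**technical phase** that scores each product bid on non-price criteria, and
a **financial phase** that ranks the qualified bids by value for money. It
is written for procurement authorities, technical tender committees, and
health-economics analysts who need tender scoring that is configurable,
auditable, and reproducible — every report embeds a manifest of the exact
inputs that produced it.

## The model

Each of K criteria has a weight *wᵢ* (percentage points, Σwᵢ = 100) and a
categorical scoring function mapping the bid's selected option to a
fraction *sᵢ* ∈ [0, 1]. The technical score on a 0–100 point scale is

    S = Σᵢ wᵢ · sᵢ

A bid **qualifies** iff it triggers no exclusion option and S ≥ T (default
threshold T = 65, inclusive, decided at full precision). Exclusion triggers
— not marketed in the country of origin, no GMP certificate, supply
reliability below 25% — disqualify a bid regardless of its total. In the
financial phase, qualified bids for the same active ingredient are ranked
by **price per point** P/S ascending; the lowest price per point is the
preferred option.

The default configuration carries the seven criteria and weights elicited
in stakeholder workshops: use in reference countries 23.49, equivalence
with the reference product 18.79, manufacturing quality 15.53,
pharmacovigilance services 12.94 (externally scored as a percentage from
the drug authority), supply reliability 10.78, previous use in local
settings 9.80, macroeconomic benefit 8.67.

Criterion weights are elicited from stakeholder vote panels by SMART swing
weighting: criteria are ranked (mean of rank votes), each adjacent pair
gets an importance ratio rₖ ≥ 1 (median of ratio votes), raw weights are
the cumulative products from the bottom rank up, normalized to sum to 100.
Criteria-list modifications pass by strict majority. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Two generics of the same active ingredient; one scores 80 points and costs
160, the other scores 70 and costs 150:

```python
import tendermcda as t
from tendermcda.scoring import ProductBid, evaluate

config = t.default_config()

common = {
    "reference_country_use": "marketed in country of origin and used in reference countries",
    "reference_equivalence": "equivalence with reference product demonstrated",
    "manufacturing_quality": "GMP certificate held",
    "supply_reliability": "supply reliability 25% or above",
    "local_use": "no previous use in local settings",
    "macroeconomic_benefit": "no manufacturing activity in Egypt",
}
bid_a = ProductBid(product_id="gen_a", active_ingredient="oxaliplatin",
                   selections=common, pharmacovigilance_percent=88.18, price=160.0)
bid_b = ProductBid(product_id="gen_b", active_ingredient="oxaliplatin",
                   selections=common, pharmacovigilance_percent=10.90, price=150.0)

results = [evaluate(b, config) for b in (bid_a, bid_b)]
for r in results:
    print(f"{r.product_id}: total {r.total_score:.2f}  qualified={r.qualified}")

ranking = t.rank_tender(results, {"gen_a": 160.0, "gen_b": 150.0})
print(ranking.to_frame().to_string(index=False))
```

prints

```
gen_a: total 80.00  qualified=True
gen_b: total 70.00  qualified=True
active_ingredient product_id  total_score  price  price_per_point  rank  preferred    status
      oxaliplatin      gen_a    80.000492  160.0         1.999988     1       True qualified
      oxaliplatin      gen_b    70.000460  150.0         2.142843     2      False qualified
```

Both bids clear the 65-point threshold. `gen_a` costs ~2.00 per point
against ~2.14 for `gen_b`, so `gen_a` is flagged preferred: the slightly
more expensive product buys more quality per unit price.

## Command line

The same workflow is available as subcommands mirroring the tender phases:

```sh
tendermcda simulate --out-dir demo --seed 5 --n-products 6   # synthetic fixtures
tendermcda validate-config --config demo/config.yaml
tendermcda elicit  --votes demo/votes.csv --out demo/weights.json
tendermcda score   --config demo/config.yaml --bids demo/bids.csv --out demo/scores.csv
tendermcda rank    --scores demo/scores.csv --out demo/ranking.csv
```

Configs are versioned YAML; bids, votes, and reports are UTF-8 CSV (votes
in long format: participant, vote_type, item, value). Logs go to stderr,
data to files, and every report embeds a run manifest (tool version, input
checksums, timestamp, command).

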