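import pytest

from tendermcda.config import default_config


@pytest.fixture(scope="session")
def config():
    """The published seven-criterion configuration."""
    return default_config()


@pytest.fixture(scope="session")
def published_weights():
    return {
        "reference_country_use": 23.49,
        "reference_equivalence": 18.79,
        "manufacturing_quality": 15.53,
        "pharmacovigilance": 12.94,
        "supply_reliability": 10.78,
        "local_use": 9.80,
        "macroeconomic_benefit": 8.67,
    }


def maximal_bid(config, product_id="prod_max", ingredient="ing_a", price=100.0,
                pv=100.0, **overrides):
    """A bid choosing the highest-fraction non-trigger option everywhere."""
    from tendermcda.scoring import ProductBid

    selections = {}
    for c in config.by_rank():
        if c.external_score:
            continue
        best = max(
            (o for o in c.options if not o.exclusion_trigger),
            key=lambda o: o.score_fraction,
        )
        selections[c.id] = best.label
    selections.update(overrides)
    return ProductBid(
        product_id=product_id,
        active_ingredient=ingredient,
        selections=selections,
        pharmacovigilance_percent=pv,
        price=price,
    )


def minimal_bid(config, product_id="prod_min", ingredient="ing_a", price=100.0):
    """A bid choosing the lowest-fraction non-trigger option everywhere."""
    from tendermcda.scoring import ProductBid

    selections = {}
    for c in config.by_rank():
        if c.external_score:
            continue
        worst = min(
            (o for o in c.options if not o.exclusion_trigger),
            key=lambda o: o.score_fraction,
        )
        selections[c.id] = worst.label
    return ProductBid(
        product_id=product_id,
        active_ingredient=ingredient,
        selections=selections,
        pharmacovigilance_percent=0.0,
        price=price,
    )
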