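import numpy as np
import pytest

from countergrad.core_data import ReplicateSummary, SnailRecord


def make_summary(
    population="N",
    treatment="heat",
    n=10,
    alive=5,
    species="saxatilis",
    block="A",
    alive_24h=None,
):
    a24 = alive if alive_24h is None else alive_24h
    return ReplicateSummary(
        species=species,
        population=population,
        treatment=treatment,
        block=block,
        n_start=n,
        n_alive_24h=a24,
        n_alive_48h=alive,
        prop_surviving=alive / n,
    )


def make_record(i=0, species="littorea", population="N", treatment="control",
                block="A", weight=0.3, alive_24h=1, alive_48h=1):
    return SnailRecord(
        snail_id=f"s{i}", species=species, population=population,
        treatment=treatment, block=block, wet_weight_g=weight,
        alive_24h=alive_24h, alive_48h=alive_48h,
    )


@pytest.fixture
def four_group_summaries():
    """The 2x2 hand-worked configuration: group means 0.5/0.9/0.1/0.5."""
    return [
        make_summary("N", "cold", 10, 5),
        make_summary("N", "heat", 10, 9),
        make_summary("S", "cold", 10, 1),
        make_summary("S", "heat", 10, 5),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)
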