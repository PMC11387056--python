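import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from localadapt import Cohort, PlantRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    i,
    site="Italy",
    soil="Italy",
    ecotype="Italy",
    survived=True,
    fruits=5,
    seeds=None,
    edge=False,
):
    return PlantRecord(
        plant_id=f"p{i}",
        site=site,
        soil=soil,
        ecotype=ecotype,
        survived=survived,
        fruits=fruits,
        seeds_per_fruit=seeds,
        edge=edge,
    )


@pytest.fixture
def four_plant_cell():
    """The hand-computable cell: two dead, (10, 20) and (5, unmeasured)."""
    return Cohort.from_records(
        [
            make_record(0, survived=False, fruits=0),
            make_record(1, survived=False, fruits=0),
            make_record(2, survived=True, fruits=10, seeds=20),
            make_record(3, survived=True, fruits=5, seeds=None),
        ]
    )


def two_site_cohort(values=None):
    """A small fully crossed cohort with every required cell occupied.

    ``values`` optionally maps (site, soil, ecotype) -> list of
    (survived, fruits, seeds) tuples; the default places two survivors
    with measured seeds in every cell.
    """
    sites = ("Italy", "Sweden")
    rows = []
    i = 0
    for site in sites:
        for soil in sites:
            for eco in sites:
                cell = (site, soil, eco)
                plants = (
                    values[cell]
                    if values is not None
                    else [(True, 4, 8), (True, 6, 10)]
                )
                for survived, fruits, seeds in plants:
                    rows.append(
                        make_record(
                            i, site=site, soil=soil, ecotype=eco,
                            survived=survived, fruits=fruits, seeds=seeds,
                        )
                    )
                    i += 1
    return Cohort.from_records(rows)


@pytest.fixture
def balanced_cohort():
    return two_site_cohort()
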