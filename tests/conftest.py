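import numpy as np
import pandas as pd
import pytest

from seedweb.io import Dataset


def make_dataset(rearing_rows, emergence_rows, traps_rows=None, traits=None):
    rearing = pd.DataFrame(
        rearing_rows,
        columns=[
            "sample_id",
            "plant_species",
            "date",
            "site",
            "maturity",
            "n_seeds",
            "n_fruits",
            "n_seeds_dissected",
            "n_seeds_predated",
        ],
    )
    emergences = pd.DataFrame(
        emergence_rows,
        columns=[
            "sample_id",
            "insect_species",
            "insect_order",
            "insect_family",
            "life_stage",
            "count",
            "is_seed_predator",
        ],
    )
    traps = None
    if traps_rows is not None:
        traps = pd.DataFrame(
            traps_rows,
            columns=[
                "plant_species",
                "seeds_observed",
                "trap_area_m2",
                "seeds_per_fruit",
                "multiseed_excluded",
            ],
        )
    return Dataset(rearing, emergences, traps, traits)


@pytest.fixture
def tiny_dataset():
    """Three plants, two predators; plant Cecropia absent from traps."""
    rearing = [
        ("s1", "Virola sp1", "2011-01-01", "island", "mature", 250, 0, 250, 20),
        ("s2", "Virola sp1", "2011-02-01", "island", "mature", 100, 0, 100, 10),
        ("s3", "Ficus sp2", "2011-01-05", "island", "mature", 199, 0, 199, 6),
        ("s4", "Cecropia sp3", "2011-03-01", "island", "immature", 300, 0, 300, 3),
    ]
    emergences = [
        ("s1", "weevil1", "Coleoptera", "Curculionidae", "adult", 12, True),
        ("s2", "weevil1", "Coleoptera", "Curculionidae", "adult", 8, True),
        ("s1", "moth1", "Lepidoptera", "Tortricidae", "larva", 10, True),
        ("s3", "weevil2", "Coleoptera", "Curculionidae", "adult", 6, True),
        ("s4", "weevil1", "Coleoptera", "Curculionidae", "adult", 3, True),
        ("s3", "parasitoid1", "Hymenoptera", "Eurytomidae", "adult", 2, False),
    ]
    traps = [
        ("Virola sp1", 500, 100.0, 1.0, False),
        ("Ficus sp2", 80, 100.0, 2.0, False),
    ]
    return make_dataset(rearing, emergences, traps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
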