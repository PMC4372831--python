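import numpy as np
import pytest

from frugnet.community import (
    BirdSpecies,
    CommunityDataset,
    InteractionRecord,
    PlantSpecies,
)
from frugnet.nutrients import FruitNutrients, sugars_from_composition


def make_plant(name="plum", diameter=7.5, sd=0.5, seeds=2.0, phenophase=((0, 365),),
               abundance=50.0, rh=70.0, proteins=5.0, lipids=3.0, fibre=10.0):
    return PlantSpecies(
        name=name,
        fruit_diameter_mean=diameter,
        fruit_diameter_sd=sd,
        seeds_per_fruit=seeds,
        nutrients=sugars_from_composition(
            FruitNutrients(rh, proteins, lipids, fibre)
        ),
        phenophase=list(phenophase),
        relative_fruit_abundance=abundance,
    )


def make_bird(name="robin", gape_min=8.0, gape_max=10.0, phenophase=((0, 730),),
              abundance=3.0):
    return BirdSpecies(
        name=name,
        gape_min=gape_min,
        gape_max=gape_max,
        phenophase=list(phenophase),
        abundance=abundance,
    )


@pytest.fixture
def toy_dataset():
    """2 plants x 2 birds with hand-set records (4 possible pairs)."""
    plants = [
        make_plant("plum", diameter=7.5, sd=0.5, seeds=2.0, abundance=60.0,
                   phenophase=((0, 200),)),
        make_plant("sloe", diameter=9.0, sd=1.0, seeds=1.0, abundance=40.0,
                   phenophase=((100, 400),)),
    ]
    birds = [
        make_bird("robin", gape_max=10.0, phenophase=((0, 730),)),
        make_bird("warbler", gape_min=6.0, gape_max=7.5, phenophase=((150, 300),)),
    ]
    records = [
        InteractionRecord(1, "plum", "robin", 40.0),
        InteractionRecord(1, "sloe", "robin", 3.0),
        InteractionRecord(2, "sloe", "robin", 5.0),
        InteractionRecord(2, "sloe", "warbler", 2.0),
    ]
    return CommunityDataset(plants=plants, birds=birds, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
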