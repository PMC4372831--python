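"""Delimited-text readers and writers for community data.

File schemas (CSV, UTF-8, header row, decimal point):

``plants.csv``
    name, fruit_diameter_mean_mm, fruit_diameter_sd_mm, seeds_per_fruit,
    rh_pct, proteins_pct, lipids_pct, fibre_pct, phenophase_intervals,
    relative_fruit_abundance_pct

``birds.csv``
    name, gape_min_mm, gape_max_mm, phenophase_intervals, abundance_ind_per_m2

``interactions.csv``
    session_id, plant, bird, seeds

Phenophase intervals are encoded as semicolon-separated ``start-end`` day
pairs, e.g. ``"0-60;400-520"`` (0-based, half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd

from .community import (
    BirdSpecies,
    CommunityDataset,
    CommunityValidationError,
    InteractionRecord,
    PlantSpecies,
)
from .intervals import format_intervals, parse_intervals
from .nutrients import FruitNutrients, sugars_from_composition

PathLike = Union[str, Path]

PLANT_COLUMNS = [
    "name",
    "fruit_diameter_mean_mm",
    "fruit_diameter_sd_mm",
    "seeds_per_fruit",
    "rh_pct",
    "proteins_pct",
    "lipids_pct",
    "fibre_pct",
    "phenophase_intervals",
    "relative_fruit_abundance_pct",
]
BIRD_COLUMNS = [
    "name",
    "gape_min_mm",
    "gape_max_mm",
    "phenophase_intervals",
    "abundance_ind_per_m2",
]
RECORD_COLUMNS = ["session_id", "plant", "bird", "seeds"]


def _require_columns(df: pd.DataFrame, required, label: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CommunityValidationError(f"{label}: missing column(s) {missing}")


def load_community(
    plant_path: PathLike,
    bird_path: PathLike,
    records_path: PathLike,
    study_length: float = 730.0,
) -> CommunityDataset:
    """Read and validate the three community tables into a dataset.

    Validation errors name the offending row and field.
    """
    plants_df = pd.read_csv(plant_path)
    birds_df = pd.read_csv(bird_path)
    records_df = pd.read_csv(records_path)
    _require_columns(plants_df, PLANT_COLUMNS, "plants file")
    _require_columns(birds_df, BIRD_COLUMNS, "birds file")
    _require_columns(records_df, RECORD_COLUMNS, "interactions file")

    plants = []
    for i, row in plants_df.iterrows():
        try:
            nutrients = sugars_from_composition(
                FruitNutrients(
                    relative_humidity=float(row["rh_pct"]),
                    proteins=float(row["proteins_pct"]),
                    lipids=float(row["lipids_pct"]),
                    fibre=float(row["fibre_pct"]),
                )
            )
            plants.append(
                PlantSpecies(
                    name=str(row["name"]),
                    fruit_diameter_mean=float(row["fruit_diameter_mean_mm"]),
                    fruit_diameter_sd=float(row["fruit_diameter_sd_mm"]),
                    seeds_per_fruit=float(row["seeds_per_fruit"]),
                    nutrients=nutrients,
                    phenophase=parse_intervals(str(row["phenophase_intervals"])),
                    relative_fruit_abundance=float(row["relative_fruit_abundance_pct"]),
                )
            )
        except (ValueError, CommunityValidationError) as exc:
            raise CommunityValidationError(f"plants file row {i}: {exc}") from exc

    birds = []
    for i, row in birds_df.iterrows():
        try:
            birds.append(
                BirdSpecies(
                    name=str(row["name"]),
                    gape_min=float(row["gape_min_mm"]),
                    gape_max=float(row["gape_max_mm"]),
                    phenophase=parse_intervals(str(row["phenophase_intervals"])),
                    abundance=float(row["abundance_ind_per_m2"]),
                )
            )
        except (ValueError, CommunityValidationError) as exc:
            raise CommunityValidationError(f"birds file row {i}: {exc}") from exc

    records = []
    for i, row in records_df.iterrows():
        try:
            records.append(
                InteractionRecord(
                    session_id=int(row["session_id"]),
                    plant=str(row["plant"]),
                    bird=str(row["bird"]),
                    seeds=float(row["seeds"]),
                )
            )
        except (ValueError, CommunityValidationError) as exc:
            raise CommunityValidationError(f"interactions file row {i}: {exc}") from exc

    return CommunityDataset(
        plants=plants, birds=birds, records=records, study_length=study_length
    )


def write_community(
    dataset: CommunityDataset,
    plant_path: PathLike,
    bird_path: PathLike,
    records_path: PathLike,
) -> None:
    """Write a dataset back to the three CSV schemas (round-trips with
    :func:`load_community`)."""
    pd.DataFrame(
        [
            {
                "name": p.name,
                "fruit_diameter_mean_mm": p.fruit_diameter_mean,
                "fruit_diameter_sd_mm": p.fruit_diameter_sd,
                "seeds_per_fruit": p.seeds_per_fruit,
                "rh_pct": p.nutrients.relative_humidity,
                "proteins_pct": p.nutrients.proteins,
                "lipids_pct": p.nutrients.lipids,
                "fibre_pct": p.nutrients.fibre,
                "phenophase_intervals": format_intervals(p.phenophase),
                "relative_fruit_abundance_pct": p.relative_fruit_abundance,
            }
            for p in dataset.plants
        ],
        columns=PLANT_COLUMNS,
    ).to_csv(plant_path, index=False)
    pd.DataFrame(
        [
            {
                "name": b.name,
                "gape_min_mm": b.gape_min,
                "gape_max_mm": b.gape_max,
                "phenophase_intervals": format_intervals(b.phenophase),
                "abundance_ind_per_m2": b.abundance,
            }
            for b in dataset.birds
        ],
        columns=BIRD_COLUMNS,
    ).to_csv(bird_path, index=False)
    pd.DataFrame(
        [
            {
                "session_id": r.session_id,
                "plant": r.plant,
                "bird": r.bird,
                "seeds": r.seeds,
            }
            for r in dataset.records
        ],
        columns=RECORD_COLUMNS,
    ).to_csv(records_path, index=False)
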