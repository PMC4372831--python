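"""Pairwise predictors of plant-frugivore interaction frequency.

For every plant-bird pair the analysis uses eight explanatory variables:

* ``size_overlap`` (S, percent) — fraction of the fruit-diameter range
  (mean +/- SD) at or below the bird's maximum gape width; a pair whose fruit
  is entirely too large gets the conventional placeholder ``1e-5`` so the
  column stays strictly positive (it doubles as the variance covariate).
* ``temporal_overlap`` (T, percent) — days both phenophases coincide,
  relative to the whole study period.
* ``abundance_product`` (A) — plant share of the community fruit crop (as a
  proportion) times bird density (individuals per m^2).
* ``fibre``, ``proteins``, ``sugars``, ``lipids`` (percent) — fruit nutrient
  composition, copied from the plant.
* ``bird_identity`` — categorical bird species factor.

The response is ``ln(F + offset)`` where F is the interaction frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .community import CommunityDataset
from .nutrients import FruitNutrients, sugars_from_composition  # noqa: F401  (re-export)
from .webs import QuantitativeWeb

#: Placeholder for pairs whose fruit cannot be swallowed at all; keeps the
#: size-overlap column strictly positive.
SIZE_OVERLAP_FLOOR = 1e-5

PREDICTOR_COLUMNS = [
    "plant",
    "bird",
    "response",
    "size_overlap",
    "temporal_overlap",
    "abundance_product",
    "fibre",
    "proteins",
    "sugars",
    "lipids",
    "bird_identity",
]


@dataclass(frozen=True)
class CaptureCalibration:
    """Linear calibration from mist-net capture rate to bird density.

    ``density = intercept + slope * (100 * capture_rate)`` with density in
    individuals per m^2 and capture rate in captures per unit netting effort
    (net-metres x hours).  Defaults are the study-site regression
    coefficients.
    """

    intercept: float = 2.15
    slope: float = 4.117


def size_overlap(fruit_min: float, fruit_max: float, gape_max: float) -> float:
    """Percentage of the fruit-diameter range swallowable by the bird.

    For a fruit range [7.0, 8.0] mm a bird with 10.0 mm maximum gape overlaps
    100 %, one with 7.5 mm overlaps 50 %, and one with 6.5 mm cannot swallow
    any fruit and gets the ``1e-5`` placeholder.  A zero-width fruit range is
    treated as the SD -> 0 limit of the rule: 100 if the gape admits the
    fruit, the placeholder otherwise.
    """
    if fruit_min > fruit_max:
        raise ValueError(f"fruit_min {fruit_min} > fruit_max {fruit_max}")
    if fruit_max == fruit_min:
        return 100.0 if gape_max >= fruit_min else SIZE_OVERLAP_FLOOR
    raw = 100.0 * min(1.0, max(0.0, (gape_max - fruit_min) / (fruit_max - fruit_min)))
    return raw if raw > 0.0 else SIZE_OVERLAP_FLOOR


def temporal_overlap(joint_presence: float, study_length: float) -> float:
    """Joint presence days as a percentage of the study period."""
    if study_length <= 0:
        raise ValueError("study_length must be positive")
    if joint_presence < 0 or joint_presence > study_length:
        raise ValueError(
            f"joint_presence {joint_presence} outside [0, {study_length}]"
        )
    return 100.0 * joint_presence / study_length


def pair_temporal_overlap(
    plant_phenophase: Sequence, bird_phenophase: Sequence, study_length: float
) -> float:
    """Temporal overlap of two species from their phenophase interval sets."""
    return temporal_overlap(
        iv.overlap_days(plant_phenophase, bird_phenophase), study_length
    )


def bird_abundance_from_capture_rate(
    capture_rate: float, cal: CaptureCalibration = CaptureCalibration()
) -> float:
    """Convert a mist-net capture rate to density (individuals per m^2)."""
    if capture_rate < 0:
        raise ValueError(f"capture_rate {capture_rate} < 0")
    return cal.intercept + cal.slope * (100.0 * capture_rate)


def relative_fruit_abundance(counts: Sequence[float]) -> np.ndarray:
    """Per-species share (percent) of the community-wide cumulative fruit crop."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("fruit counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all fruit counts are zero")
    return 100.0 * counts / total


def build_predictor_table(
    dataset: CommunityDataset,
    web: Optional[QuantitativeWeb] = None,
    log_offset: float = 1.0,
) -> pd.DataFrame:
    """One row per plant-bird pair with the response and all eight predictors.

    Rows are in plant-major order matching the web layout (row i, column j of
    the matrix is table row ``i * n_birds + j``).  If ``web`` is None the
    response column is NaN (useful when only the design is needed).  The log
    offset used is recorded in ``DataFrame.attrs["log_offset"]``.
    """
    if web is not None:
        if list(web.row_names) != dataset.plant_names or list(
            web.col_names
        ) != dataset.bird_names:
            raise ValueError("web species names/order do not match the dataset")
    rows = []
    for i, plant in enumerate(dataset.plants):
        fruit_lo, fruit_hi = plant.fruit_range
        for j, bird in enumerate(dataset.birds):
            if web is not None:
                response = float(np.log(web.matrix[i, j] + log_offset))
            else:
                response = np.nan
            rows.append(
                {
                    "plant": plant.name,
                    "bird": bird.name,
                    "response": response,
                    "size_overlap": size_overlap(fruit_lo, fruit_hi, bird.gape_max),
                    "temporal_overlap": pair_temporal_overlap(
                        plant.phenophase, bird.phenophase, dataset.study_length
                    ),
                    "abundance_product": (plant.relative_fruit_abundance / 100.0)
                    * bird.abundance,
                    "fibre": plant.nutrients.fibre,
                    "proteins": plant.nutrients.proteins,
                    "sugars": plant.nutrients.sugars,
                    "lipids": plant.nutrients.lipids,
                    "bird_identity": bird.name,
                }
            )
    table = pd.DataFrame(rows, columns=PREDICTOR_COLUMNS)
    table["bird_identity"] = table["bird_identity"].astype("category")
    table.attrs["log_offset"] = log_offset
    return table
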