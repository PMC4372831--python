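"""Domain types for one plant-frugivore study system.

A :class:`CommunityDataset` bundles the plant and bird trait tables, the
phenology windows, the abundances and the long-format seed records for one
site, and provides the two derived quantities the downstream analysis needs:
the quantitative interaction matrix (seeds dispersed divided by seeds per
fruit, i.e. estimated fruit-visit equivalents) and the link accumulation
curve used to check sampling completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from . import intervals as iv
from .nutrients import FruitNutrients
from .webs import QuantitativeWeb


class CommunityValidationError(ValueError):
    """Raised when community inputs violate the schema or an invariant."""


@dataclass
class PlantSpecies:
    name: str
    fruit_diameter_mean: float  # mm
    fruit_diameter_sd: float  # mm
    seeds_per_fruit: float  # mean count per fruit
    nutrients: FruitNutrients
    phenophase: List[Tuple[float, float]] = field(default_factory=list)
    relative_fruit_abundance: float = 0.0  # percent of community fruit crop

    def __post_init__(self) -> None:
        if self.fruit_diameter_sd < 0:
            raise CommunityValidationError(
                f"plant {self.name!r}: fruit_diameter_sd={self.fruit_diameter_sd} < 0"
            )
        if self.fruit_diameter_mean <= 0:
            raise CommunityValidationError(
                f"plant {self.name!r}: fruit_diameter_mean must be positive"
            )
        if self.seeds_per_fruit <= 0:
            raise CommunityValidationError(
                f"plant {self.name!r}: seeds_per_fruit must be positive"
            )
        if self.relative_fruit_abundance < 0:
            raise CommunityValidationError(
                f"plant {self.name!r}: relative_fruit_abundance < 0"
            )
        self.phenophase = iv.normalize(self.phenophase)

    @property
    def fruit_range(self) -> Tuple[float, float]:
        """Fruit diameter range mean +/- 1 SD, lower bound clamped at 0 mm."""
        lo = max(self.fruit_diameter_mean - self.fruit_diameter_sd, 0.0)
        hi = self.fruit_diameter_mean + self.fruit_diameter_sd
        return lo, hi


@dataclass
class BirdSpecies:
    name: str
    gape_min: float  # mm
    gape_max: float  # mm
    phenophase: List[Tuple[float, float]] = field(default_factory=list)
    abundance: float = 0.0  # individuals per m^2

    def __post_init__(self) -> None:
        if self.gape_min > self.gape_max:
            raise CommunityValidationError(
                f"bird {self.name!r}: gape_min {self.gape_min} > gape_max {self.gape_max}"
            )
        if self.abundance < 0:
            raise CommunityValidationError(f"bird {self.name!r}: abundance < 0")
        self.phenophase = iv.normalize(self.phenophase)


@dataclass
class InteractionRecord:
    """One mist-netting session's seed count for one plant-bird pair."""

    session_id: int
    plant: str
    bird: str
    seeds: float

    def __post_init__(self) -> None:
        if self.seeds < 0:
            raise CommunityValidationError(
                f"record (session {self.session_id}, {self.plant} x {self.bird}): "
                f"seeds={self.seeds} < 0"
            )


@dataclass
class CommunityDataset:
    plants: List[PlantSpecies]
    birds: List[BirdSpecies]
    records: List[InteractionRecord] = field(default_factory=list)
    study_length: float = 730.0  # days
    sessions: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.study_length <= 0:
            raise CommunityValidationError("study_length must be positive")
        names = [p.name for p in self.plants] + [b.name for b in self.birds]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CommunityValidationError(f"duplicate species names: {sorted(dupes)}")
        plant_names = {p.name for p in self.plants}
        bird_names = {b.name for b in self.birds}
        for i, rec in enumerate(self.records):
            if rec.plant not in plant_names:
                raise CommunityValidationError(
                    f"record {i}: unknown plant {rec.plant!r}"
                )
            if rec.bird not in bird_names:
                raise CommunityValidationError(f"record {i}: unknown bird {rec.bird!r}")
        for sp in list(self.plants) + list(self.birds):
            for start, end in sp.phenophase:
                if start < 0 or end > self.study_length:
                    raise CommunityValidationError(
                        f"species {sp.name!r}: phenophase interval ({start}, {end}) "
                        f"outside [0, {self.study_length}]"
                    )
        if not self.sessions:
            self.sessions = sorted({rec.session_id for rec in self.records})
        abund = [p.relative_fruit_abundance for p in self.plants]
        if abund and sum(abund) > 0 and abs(sum(abund) - 100.0) > 1e-6:
            raise CommunityValidationError(
                f"relative fruit abundances sum to {sum(abund)}, expected 100"
            )

    @property
    def plant_names(self) -> List[str]:
        return [p.name for p in self.plants]

    @property
    def bird_names(self) -> List[str]:
        return [b.name for b in self.birds]

    def plant(self, name: str) -> PlantSpecies:
        for p in self.plants:
            if p.name == name:
                return p
        raise KeyError(name)

    def bird(self, name: str) -> BirdSpecies:
        for b in self.birds:
            if b.name == name:
                return b
        raise KeyError(name)


def build_interaction_matrix(dataset: CommunityDataset) -> QuantitativeWeb:
    """Interaction-frequency matrix F (plants x birds).

    ``F[i, j]`` is the total number of seeds of plant *i* recovered from bird
    *j*'s faeces divided by the plant's mean seeds per fruit — an estimate of
    the number of fruit-handling visits.  Unobserved pairs are explicit zero
    cells, so the matrix always has plants x birds entries.
    """
    plant_index = {p.name: i for i, p in enumerate(dataset.plants)}
    bird_index = {b.name: j for j, b in enumerate(dataset.birds)}
    seeds = np.zeros((len(dataset.plants), len(dataset.birds)))
    for rec in dataset.records:
        seeds[plant_index[rec.plant], bird_index[rec.bird]] += rec.seeds
    spf = np.array([p.seeds_per_fruit for p in dataset.plants])
    matrix = seeds / spf[:, None]
    return QuantitativeWeb(matrix, dataset.plant_names, dataset.bird_names)


def accumulation_curve(
    dataset: CommunityDataset, tail_sessions: int = 10
) -> Tuple[np.ndarray, float]:
    """Link accumulation curve and its final slope.

    Returns the cumulative number of distinct plant-bird links observed after
    each session (in session order) and the ordinary least-squares slope of
    that curve over the last ``tail_sessions`` sessions (links per session).
    A shallow final slope indicates the interaction sampling has saturated.
    """
    if tail_sessions < 2:
        raise ValueError("tail_sessions must be >= 2")
    if len(dataset.sessions) < tail_sessions:
        raise ValueError(
            f"only {len(dataset.sessions)} sessions, need >= tail_sessions={tail_sessions}"
        )
    seen: set = set()
    cumulative = []
    by_session: dict = {}
    for rec in dataset.records:
        if rec.seeds > 0:
            by_session.setdefault(rec.session_id, set()).add((rec.plant, rec.bird))
    for sid in dataset.sessions:
        seen |= by_session.get(sid, set())
        cumulative.append(len(seen))
    cumulative = np.array(cumulative, dtype=float)
    tail = cumulative[-tail_sessions:]
    x = np.arange(tail_sessions, dtype=float)
    slope = float(np.polyfit(x, tail, 1)[0])
    return cumulative, slope
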