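"""Synthetic plant-frugivore communities with known generating structure.

The generator emulates a small insular seed-dispersal community — by default
nine fleshy-fruited plant species and four passerine dispersers sampled over
a two-year (730-day) study — whose log interaction frequencies follow the
same linear model the analysis fits:

    y_p = x_p' beta_true + eps_p,   eps_p ~ Normal(0, sigma2 * v_p),

with v_p the pair's size overlap, F_p = max(exp(y_p) - offset, 0) and
integer seed counts drawn as Poisson(F_p * seeds_per_fruit) and split across
mist-netting sessions.  Every generated dataset carries a
:class:`SyntheticTruth` sidecar with the generating coefficients and the
noiseless responses, so estimator-recovery tests can close the loop.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .community import BirdSpecies, CommunityDataset, InteractionRecord, PlantSpecies
from .model import ModelSpec, design_matrix
from .nutrients import FruitNutrients, sugars_from_composition
from .predictors import CaptureCalibration, build_predictor_table

#: Generating model: the trait-plus-abundance specification.
GENERATING_SPEC = ModelSpec(
    "size+temporal+abundance+bird",
    ("size_overlap", "temporal_overlap", "abundance_product", "bird_identity"),
)


@dataclass
class CommunityConfig:
    """Defaults sized to the study system the analysis assumes.

    Trait laws are loose caricatures of a Mediterranean scrubland community:
    fruit diameters of a few mm to ~1 cm, gape widths spanning part of that
    range (so size overlap varies over (0, 100]), seasonal fruiting windows
    inside a 730-day study, and bird densities on the scale produced by the
    capture-rate calibration.
    """

    n_plants: int = 9
    n_birds: int = 4
    study_length: float = 730.0
    n_sessions: int = 54
    # fruit diameter (mm): log-normal on the underlying mean
    fruit_diameter_log_mean: float = 1.9  # exp(1.9) ~ 6.7 mm
    fruit_diameter_log_sd: float = 0.45
    fruit_sd_fraction: Tuple[float, float] = (0.10, 0.30)
    seeds_per_fruit_range: Tuple[float, float] = (1.0, 12.0)
    # proximate composition (percent of fruit mass)
    rh_range: Tuple[float, float] = (55.0, 85.0)
    proteins_range: Tuple[float, float] = (1.0, 8.0)
    lipids_range: Tuple[float, float] = (0.5, 10.0)
    fibre_range: Tuple[float, float] = (4.0, 20.0)
    # phenophases: plants fruit seasonally, birds are resident or wintering
    plant_window_range: Tuple[float, float] = (90.0, 330.0)
    bird_resident_prob: float = 0.5
    bird_window_range: Tuple[float, float] = (150.0, 450.0)
    # gape widths (mm): anchored just above the largest fruit's lower diameter
    # bound, so every fruit is at least partially swallowable by every bird
    # (strictly positive size overlap) while the largest fruit is only
    # fractionally so (per-bird size-overlap variation)
    gape_overlap_fraction: Tuple[float, float] = (0.05, 0.6)
    gape_spread_range: Tuple[float, float] = (0.5, 2.0)
    capture_rate_range: Tuple[float, float] = (0.0, 0.02)
    calibration: CaptureCalibration = field(default_factory=CaptureCalibration)
    # community validity: keep every pair physically possible (no size-overlap
    # placeholder rows, whose ~zero assumed variance is incompatible with the
    # Poisson discretisation of seed counts) and make each bird's size-overlap
    # column vary across plants so identity-interaction designs stay full rank
    min_size_overlap: float = 1.0  # percent
    min_size_overlap_spread: float = 5.0  # percent, per bird across plants
    max_community_draws: int = 200
    # generating model
    true_beta: Optional[Dict[str, float]] = None
    sigma2: float = 0.004
    log_offset: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 2 or self.n_birds < 2:
            raise ValueError("need at least 2 plants and 2 birds")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.true_beta is None:
            self.true_beta = default_true_beta(self.n_birds)


def default_true_beta(n_birds: int) -> Dict[str, float]:
    """Generating coefficients on the design-column scale.

    Keyed by patsy column names of :data:`GENERATING_SPEC` (treatment coding,
    alphabetically first bird as reference).  Sized so that a fully matched,
    co-occurring, abundant pair reaches interaction frequencies of a few
    dozen visits while mismatched pairs stay near zero.
    """
    beta = {
        "Intercept": -1.0,
        "size_overlap": 0.022,
        "temporal_overlap": 0.010,
        "abundance_product": 0.25,
    }
    offsets = [0.4, -0.4, 0.8, 0.2, -0.2, 0.6, -0.6, 0.3]
    for k in range(1, n_birds):
        beta[f"bird_{k + 1}"] = offsets[(k - 1) % len(offsets)]
    return beta


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated dataset."""

    config: CommunityConfig
    true_beta: pd.Series
    predictor_table: Optional[pd.DataFrame] = None
    noiseless_response: Optional[np.ndarray] = None
    expected_frequency: Optional[np.ndarray] = None

    def to_json(self, path) -> None:
        payload = {
            "true_beta": self.true_beta.to_dict(),
            "sigma2": self.config.sigma2,
            "log_offset": self.config.log_offset,
            "seed": self.config.seed,
            "n_plants": self.config.n_plants,
            "n_birds": self.config.n_birds,
        }
        if self.noiseless_response is not None:
            payload["noiseless_response"] = list(map(float, self.noiseless_response))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _sample_nutrients(rng: np.random.Generator, config: CommunityConfig) -> FruitNutrients:
    for _ in range(100):
        candidate = FruitNutrients(
            relative_humidity=rng.uniform(*config.rh_range),
            proteins=rng.uniform(*config.proteins_range),
            lipids=rng.uniform(*config.lipids_range),
            fibre=rng.uniform(*config.fibre_range),
        )
        total = (
            candidate.relative_humidity
            + candidate.proteins
            + candidate.lipids
            + candidate.fibre
        )
        if total <= 100.0:
            return sugars_from_composition(candidate)
    raise RuntimeError("could not sample a feasible fruit composition")


def _sample_window(
    rng: np.random.Generator, length_range: Tuple[float, float], study_length: float
) -> List[Tuple[float, float]]:
    length = min(rng.uniform(*length_range), study_length)
    start = rng.uniform(0.0, study_length - length)
    return [(round(start), round(start + length))]


def generate_community(
    config: CommunityConfig,
) -> Tuple[CommunityDataset, SyntheticTruth]:
    """Draw species tables (traits, phenophases, abundances); no records yet.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(config.max_community_draws):
        dataset = _draw_community(rng, config)
        if _community_valid(dataset, config):
            break
    else:
        raise RuntimeError(
            f"no valid community within {config.max_community_draws} draws; "
            "relax min_size_overlap or the trait laws"
        )
    truth = SyntheticTruth(config=config, true_beta=pd.Series(dict(config.true_beta)))
    return dataset, truth


def _community_valid(dataset: CommunityDataset, config: CommunityConfig) -> bool:
    from .predictors import size_overlap

    from .predictors import pair_temporal_overlap

    for bird in dataset.birds:
        overlaps = np.array(
            [size_overlap(*p.fruit_range, bird.gape_max) for p in dataset.plants]
        )
        if overlaps.min() < config.min_size_overlap:
            return False
        if np.ptp(overlaps) < config.min_size_overlap_spread:
            return False
        temporal = np.array(
            [
                pair_temporal_overlap(
                    p.phenophase, bird.phenophase, config.study_length
                )
                for p in dataset.plants
            ]
        )
        if np.ptp(temporal) < 1.0:
            return False
    return True


def _draw_community(rng: np.random.Generator, config: CommunityConfig) -> CommunityDataset:
    fruit_shares = rng.dirichlet(np.full(config.n_plants, 2.0)) * 100.0
    fruit_shares = fruit_shares / fruit_shares.sum() * 100.0
    plants = []
    for i in range(config.n_plants):
        diameter = float(
            np.exp(rng.normal(config.fruit_diameter_log_mean, config.fruit_diameter_log_sd))
        )
        plants.append(
            PlantSpecies(
                name=f"plant_{i + 1}",
                fruit_diameter_mean=diameter,
                fruit_diameter_sd=diameter * rng.uniform(*config.fruit_sd_fraction),
                seeds_per_fruit=float(
                    np.round(rng.uniform(*config.seeds_per_fruit_range), 1)
                ),
                nutrients=_sample_nutrients(rng, config),
                phenophase=_sample_window(
                    rng, config.plant_window_range, config.study_length
                ),
                relative_fruit_abundance=float(fruit_shares[i]),
            )
        )
    anchor_plant = max(plants, key=lambda p: p.fruit_range[0])
    anchor_lo, anchor_hi = anchor_plant.fruit_range
    birds = []
    for j in range(config.n_birds):
        gape_max = anchor_lo + rng.uniform(*config.gape_overlap_fraction) * (
            anchor_hi - anchor_lo
        )
        capture_rate = rng.uniform(*config.capture_rate_range)
        if rng.random() < config.bird_resident_prob:
            phenophase = [(0.0, config.study_length)]
        else:
            phenophase = _sample_window(
                rng, config.bird_window_range, config.study_length
            )
        birds.append(
            BirdSpecies(
                name=f"bird_{j + 1}",
                gape_min=gape_max - rng.uniform(*config.gape_spread_range),
                gape_max=gape_max,
                phenophase=phenophase,
                abundance=config.calibration.intercept
                + config.calibration.slope * 100.0 * capture_rate,
            )
        )
    return CommunityDataset(
        plants=plants, birds=birds, records=[], study_length=config.study_length,
        sessions=list(range(1, config.n_sessions + 1)),
    )


def _truth_design(table: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """Design matrix of the generating spec with columns mapped to beta keys."""
    X = design_matrix(table, GENERATING_SPEC)
    columns = []
    for col in X.columns:
        if col.startswith("C(bird_identity)"):
            columns.append(col.split("[T.")[1].rstrip("]"))
        else:
            columns.append(col)
    beta = truth.true_beta
    missing = [c for c in columns if c not in beta.index]
    if missing:
        raise ValueError(f"true_beta missing design columns: {missing}")
    return X.to_numpy() @ beta.loc[columns].to_numpy()


def generate_interactions(
    dataset: CommunityDataset, truth: SyntheticTruth
) -> Tuple[CommunityDataset, SyntheticTruth]:
    """Fill the dataset's records from the generating model.

    Uses ``config.seed + 1`` so the community draw and the interaction draw
    are independent streams; stores the noiseless response and the expected
    frequencies in the returned truth.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1)
    table = build_predictor_table(dataset, web=None, log_offset=config.log_offset)
    mean_response = _truth_design(table, truth)
    v = table["size_overlap"].to_numpy(dtype=float)
    noise = rng.normal(0.0, np.sqrt(config.sigma2 * v))
    y = mean_response + noise
    frequency = np.clip(np.exp(y) - config.log_offset, 0.0, None)

    spf = {p.name: p.seeds_per_fruit for p in dataset.plants}
    records: List[InteractionRecord] = []
    session_ids = dataset.sessions or list(range(1, config.n_sessions + 1))
    for row, freq in zip(table.itertuples(index=False), frequency):
        total_seeds = rng.poisson(freq * spf[row.plant])
        if total_seeds == 0:
            continue
        split = rng.multinomial(total_seeds, np.full(len(session_ids), 1.0 / len(session_ids)))
        for sid, count in zip(session_ids, split):
            if count > 0:
                records.append(
                    InteractionRecord(
                        session_id=int(sid), plant=row.plant, bird=row.bird,
                        seeds=float(count),
                    )
                )
    dataset = CommunityDataset(
        plants=dataset.plants, birds=dataset.birds, records=records,
        study_length=dataset.study_length, sessions=list(session_ids),
    )
    truth = dataclasses.replace(
        truth,
        predictor_table=table,
        noiseless_response=mean_response,
        expected_frequency=frequency,
    )
    return dataset, truth


def generate_dataset(config: CommunityConfig) -> Tuple[CommunityDataset, SyntheticTruth]:
    """Convenience: community plus interaction records in one call."""
    dataset, truth = generate_community(config)
    return generate_interactions(dataset, truth)


def toy_example_fixture() -> Dict[str, object]:
    """The worked-example inputs used throughout the documentation and tests.

    A fruit with diameter range 7.0-8.0 mm; one bird with gape 9.0-10.0 mm
    (full size overlap) and one with 6.0-7.5 mm (half overlap); a plant
    fruiting for 60 days and a bird present 60 days with 30 days shared in a
    730-day study; and the default capture-rate calibration.
    """
    return {
        "fruit_range": (7.0, 8.0),
        "gape_ranges": [(9.0, 10.0), (6.0, 7.5)],
        "plant_phenophase": [(0.0, 60.0)],
        "bird_phenophase": [(30.0, 90.0)],
        "study_length": 730.0,
        "calibration": CaptureCalibration(),
    }
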