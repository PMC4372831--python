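"""Probability-matrix Monte-Carlo prediction of network parameters.

The expected interaction matrix from the best statistical model is
normalised into a probability matrix; randomized webs are drawn by a single
multinomial allocation of a fixed number of interaction events over cells;
each draw's six network parameters are summarised by their mean and
percentile 95 % interval; and the observed parameters are judged by whether
they fall inside that interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, MetricConfig, compute_all_metrics
from .webs import QuantitativeWeb

logger = logging.getLogger(__name__)

RETRY_BOUND = 1000


@dataclass
class ProbabilityMatrix:
    """Cell probabilities for one interaction event (sums to 1)."""

    matrix: np.ndarray
    row_names: List[str] = field(default_factory=list)
    col_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(self.matrix < 0):
            raise ValueError("probability matrix has negative cells")
        if abs(self.matrix.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {self.matrix.sum()}, expected 1")
        if not self.row_names:
            self.row_names = [f"plant_{i + 1}" for i in range(self.matrix.shape[0])]
        if not self.col_names:
            self.col_names = [f"bird_{j + 1}" for j in range(self.matrix.shape[1])]


def make_probability_matrix(predicted: QuantitativeWeb) -> ProbabilityMatrix:
    """Normalise a predicted web by its grand total."""
    total = predicted.matrix.sum()
    if total <= 0:
        raise ValueError("predicted web has zero total; cannot normalise")
    return ProbabilityMatrix(
        predicted.matrix / total, list(predicted.row_names), list(predicted.col_names)
    )


def sample_web(
    p: ProbabilityMatrix,
    n_interactions: int,
    rng_seed: Optional[int] = None,
    require_all_species: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> QuantitativeWeb:
    """One randomized web: a multinomial draw of events over cells.

    With ``require_all_species`` the draw is repeated (up to a bounded number
    of retries) until every row and column has at least one event.
    """
    if n_interactions < 1:
        raise ValueError("n_interactions must be >= 1")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    probs = p.matrix.ravel()
    if require_all_species:
        if np.any(p.matrix.sum(axis=1) == 0) or np.any(p.matrix.sum(axis=0) == 0):
            raise ValueError(
                "require_all_species unsatisfiable: a row or column has zero probability"
            )
    for _ in range(RETRY_BOUND):
        counts = rng.multinomial(n_interactions, probs).reshape(p.matrix.shape)
        if not require_all_species:
            break
        if np.all(counts.sum(axis=1) > 0) and np.all(counts.sum(axis=0) > 0):
            break
    else:
        raise RuntimeError(
            f"no draw with all species connected within {RETRY_BOUND} retries"
        )
    return QuantitativeWeb(
        counts.astype(float), list(p.row_names), list(p.col_names)
    )


@dataclass
class SimulatedParameters:
    """Per-metric summaries of the randomized webs."""

    means: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    n_replicates: int
    seed: Optional[int]
    n_interactions: int
    failures: Dict[str, int] = field(default_factory=dict)


@dataclass
class MetricComparison:
    metric: str
    observed: float
    simulated_mean: float
    ci_low: float
    ci_high: float
    inside_ci: bool


@dataclass
class NullModelResult:
    """Observed vs simulated network parameters, one row per metric."""

    comparisons: List[MetricComparison]
    n_replicates: int
    seed: Optional[int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": c.metric,
                    "observed": c.observed,
                    "simulated_mean": c.simulated_mean,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "inside_ci": c.inside_ci,
                }
                for c in self.comparisons
            ]
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_network_parameters(
    p: ProbabilityMatrix,
    n_interactions: int,
    n_replicates: int = 1000,
    rng_seed: Optional[int] = None,
    metric_config: MetricConfig = MetricConfig(win_replicates=200),
    require_all_species: bool = False,
    ci_level: float = 0.95,
) -> SimulatedParameters:
    """Draw randomized webs and summarise each metric's distribution.

    Metrics that fail on a degenerate draw (e.g. an all-zero or single-line
    web) are skipped for that draw and counted; more than 10 % failures for
    any metric aborts with an error.  Fully reproducible for a fixed seed.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(rng_seed)
    values: Dict[str, List[float]] = {name: [] for name in METRIC_NAMES}
    failures: Dict[str, int] = {name: 0 for name in METRIC_NAMES}
    for _ in range(n_replicates):
        web = sample_web(
            p, n_interactions, require_all_species=require_all_species, rng=rng
        )
        for name in METRIC_NAMES:
            try:
                metric_value = _single_metric(web, name, metric_config, rng)
                if np.isnan(metric_value):
                    raise ValueError("metric evaluated to NaN")
                values[name].append(metric_value)
            except (ValueError, ZeroDivisionError) as exc:
                failures[name] += 1
                logger.debug("metric %s failed on a draw: %s", name, exc)
    alpha = (1.0 - ci_level) / 2.0
    means, lo, hi = {}, {}, {}
    for name in METRIC_NAMES:
        if failures[name] > 0.1 * n_replicates:
            raise RuntimeError(
                f"metric {name!r} failed on {failures[name]}/{n_replicates} draws"
            )
        arr = np.asarray(values[name])
        means[name] = float(arr.mean())
        lo[name] = float(np.percentile(arr, 100.0 * alpha))
        hi[name] = float(np.percentile(arr, 100.0 * (1.0 - alpha)))
    return SimulatedParameters(
        means=means,
        ci_low=lo,
        ci_high=hi,
        n_replicates=n_replicates,
        seed=rng_seed,
        n_interactions=n_interactions,
        failures=failures,
    )


def _single_metric(
    web: QuantitativeWeb, name: str, config: MetricConfig, rng: np.random.Generator
) -> float:
    """Evaluate one metric on a draw, silencing degenerate-draw warnings."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _single_metric_raw(web, name, config, rng)


def _single_metric_raw(
    web: QuantitativeWeb, name: str, config: MetricConfig, rng: np.random.Generator
) -> float:
    from . import metrics as m

    if name == "connectance":
        return m.connectance(web)
    if name == "nodf":
        return m.nodf(web)
    if name == "weighted_nestedness":
        return m.weighted_nestedness(web, replicates=config.win_replicates, rng=rng)
    if name == "interaction_evenness":
        return m.interaction_evenness(web, denominator=config.evenness_denominator)
    asym_plants, asym_birds = m.guild_asymmetry(web)
    return asym_birds if name == "asymmetry_birds" else asym_plants


def compare_observed(
    observed: Dict[str, float], simulated: SimulatedParameters
) -> NullModelResult:
    """Attach inside-CI verdicts to the simulated summaries."""
    missing = set(observed) ^ set(simulated.means)
    if missing:
        raise ValueError(f"metric sets differ: {sorted(missing)}")
    comparisons = []
    for name in METRIC_NAMES:
        obs = observed[name]
        lo, hi = simulated.ci_low[name], simulated.ci_high[name]
        comparisons.append(
            MetricComparison(
                metric=name,
                observed=obs,
                simulated_mean=simulated.means[name],
                ci_low=lo,
                ci_high=hi,
                inside_ci=bool(lo <= obs <= hi),
            )
        )
    return NullModelResult(
        comparisons=comparisons,
        n_replicates=simulated.n_replicates,
        seed=simulated.seed,
    )


def default_n_interactions(observed: QuantitativeWeb) -> int:
    """Event total for the randomizations: the observed web's rounded sum."""
    return max(1, int(round(observed.matrix.sum())))
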