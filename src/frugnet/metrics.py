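"""Aggregate statistics of quantitative bipartite webs, from first principles.

Six parameters characterise a plants x birds interaction matrix:

* **connectance** — realized links / possible links.
* **NODF** — binary nestedness by Overlap and Decreasing Fill: for every
  ordered pair of rows (and columns) whose fills strictly decrease, the
  percentage of the emptier line's links shared with the fuller line; the
  statistic is the mean over all row pairs and column pairs (pairs with
  equal fill contribute zero).
* **weighted nestedness** — a quantitative estimator: pack the matrix by
  descending marginal totals, measure the interaction-weighted mean distance
  of filled cells from the generalist corner, and normalise so random webs
  with the same dimensions and fill score ~0 and the maximally packed
  arrangement of the same weights scores 1.
* **interaction evenness** — Shannon entropy of cell proportions divided by
  ``ln(cells)`` (or ``ln(links)`` under the alternative convention).
* **interaction asymmetry** for each guild — from mutual dependences
  ``d_ij = a_ij / row_total_i`` (plant on bird) and ``d'_ji = a_ij /
  col_total_j`` (bird on plant): per realized link the normalised difference
  ``(d_ij - d'_ji) / max(d_ij, d'_ji)``, averaged to species (sign flipped
  for the bird perspective) and then averaged over the guild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .webs import QuantitativeWeb

MatrixLike = Union[QuantitativeWeb, np.ndarray]

METRIC_NAMES = [
    "connectance",
    "nodf",
    "weighted_nestedness",
    "interaction_evenness",
    "asymmetry_birds",
    "asymmetry_plants",
]


def _as_matrix(web: MatrixLike) -> np.ndarray:
    matrix = web.matrix if isinstance(web, QuantitativeWeb) else np.asarray(web, float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("web must be a non-empty 2-D matrix")
    if np.any(matrix < 0):
        raise ValueError("web has negative cells")
    return matrix


def connectance(web: MatrixLike) -> float:
    """Proportion of realized interactions among all plant-bird pairs."""
    matrix = _as_matrix(web)
    return float(np.count_nonzero(matrix > 0) / matrix.size)


def nodf(web: MatrixLike) -> float:
    """Binary NODF on the web binarized at cell > 0, in [0, 100].

    The decreasing-fill condition makes the statistic invariant to row and
    column order, so no resorting is performed.
    """
    matrix = _as_matrix(web)
    binary = (matrix > 0).astype(int)
    if binary.sum() == 0:
        raise ValueError("all-zero matrix has no nestedness")
    n_rows, n_cols = binary.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")

    def axis_contributions(mat: np.ndarray) -> Tuple[float, int]:
        fills = mat.sum(axis=1)
        shared = mat @ mat.T
        total = 0.0
        n = mat.shape[0]
        for i in range(n):
            for j in range(n):
                if i < j:
                    hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
                    if fills[hi] > fills[lo] and fills[lo] > 0:
                        total += 100.0 * shared[hi, lo] / fills[lo]
        return total, n * (n - 1) // 2

    row_sum, row_pairs = axis_contributions(binary)
    col_sum, col_pairs = axis_contributions(binary.T)
    return float((row_sum + col_sum) / (row_pairs + col_pairs))


def _corner_distances(n_rows: int, n_cols: int) -> np.ndarray:
    i = np.arange(n_rows)[:, None]
    j = np.arange(n_cols)[None, :]
    return np.sqrt(i**2 + j**2)


def _pack(matrix: np.ndarray) -> np.ndarray:
    """Reorder rows and columns by descending marginal totals (stable)."""
    row_order = np.argsort(-matrix.sum(axis=1), kind="stable")
    col_order = np.argsort(-matrix.sum(axis=0), kind="stable")
    return matrix[np.ix_(row_order, col_order)]


def _weighted_corner_distance(weights: np.ndarray, distances: np.ndarray) -> float:
    return float(np.sum(weights * distances) / np.sum(weights))


def weighted_nestedness(
    web: MatrixLike,
    replicates: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Weighted-interaction nestedness estimator, ~0 for random, 1 for packed.

    The matrix is packed by descending marginal totals and scored by the
    interaction-weighted mean Euclidean distance of its filled cells from the
    generalist-generalist corner.  The score is normalised between the
    Monte-Carlo expectation over ``replicates`` random webs with the same
    dimensions and fill (same positive weights scattered over uniformly
    chosen cells) and the maximally nested arrangement (largest weights in
    the cells closest to the corner).  Values near 0 mean no more nested than
    random; 1 means maximally nested; moderately anti-nested webs can go
    negative.
    """
    matrix = _as_matrix(web)
    n_rows, n_cols = matrix.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("weighted nestedness needs at least 2 rows and 2 columns")
    if matrix.sum() <= 0:
        raise ValueError("web has no interactions")
    if rng is None:
        rng = np.random.default_rng(seed)

    packed = _pack(matrix)
    distances = _corner_distances(n_rows, n_cols)
    filled = packed > 0
    d_obs = _weighted_corner_distance(packed[filled], distances[filled])

    weights = np.sort(matrix[matrix > 0])[::-1]
    n_links = weights.size
    flat_d = np.sort(distances.ravel(), kind="stable")
    d_max = _weighted_corner_distance(weights, flat_d[:n_links])

    # Monte-Carlo baseline: each replicate scatters the observed weights over
    # n_links uniformly chosen cells, then is packed and scored exactly like
    # the observed web (packing the replicate is essential: an unpacked
    # baseline would make random webs score systematically above zero).
    n_cells = n_rows * n_cols
    keys = rng.random((replicates, n_cells))
    positions = np.argpartition(keys, n_links - 1, axis=1)[:, :n_links]
    perm = rng.permuted(np.tile(weights, (replicates, 1)), axis=1)
    rows_idx, cols_idx = positions // n_cols, positions % n_cols
    webs = np.zeros((replicates, n_rows, n_cols))
    rep_idx = np.repeat(np.arange(replicates)[:, None], n_links, axis=1)
    webs[rep_idx, rows_idx, cols_idx] = perm
    row_rank = np.argsort(
        np.argsort(-webs.sum(axis=2), axis=1, kind="stable"), axis=1, kind="stable"
    )
    col_rank = np.argsort(
        np.argsort(-webs.sum(axis=1), axis=1, kind="stable"), axis=1, kind="stable"
    )
    rr = np.take_along_axis(row_rank, rows_idx, axis=1)
    cc = np.take_along_axis(col_rank, cols_idx, axis=1)
    rep_d = np.sqrt(rr.astype(float) ** 2 + cc.astype(float) ** 2)
    d_rnd = float(np.mean(np.sum(perm * rep_d, axis=1) / weights.sum()))

    denom = d_rnd - d_max
    if abs(denom) < 1e-12:
        warnings.warn(
            "weighted nestedness undefined: random and packed scores coincide"
        )
        return float("nan")
    return float((d_rnd - d_obs) / denom)


def interaction_evenness(web: MatrixLike, denominator: str = "cells") -> float:
    """Shannon evenness of interaction proportions, in [0, 1].

    ``denominator="cells"`` divides the entropy by ``ln(rows*cols)``;
    ``"links"`` divides by ``ln(#positive cells)`` (both conventions are in
    use in the networks literature).
    """
    matrix = _as_matrix(web)
    total = matrix.sum()
    if total <= 0:
        raise ValueError("web has no interactions")
    p = matrix[matrix > 0] / total
    entropy = float(-(p * np.log(p)).sum())
    if denominator == "cells":
        log_div = np.log(matrix.size)
    elif denominator == "links":
        log_div = np.log(p.size)
    else:
        raise ValueError(f"unknown evenness denominator {denominator!r}")
    if log_div == 0:
        return 1.0
    return entropy / log_div


def guild_asymmetry(web: MatrixLike) -> Tuple[float, float]:
    """Dependence-based interaction asymmetry, returned as (plants, birds).

    Species with no realized links are excluded with a warning.  Positive
    plant-side values mean plants depend on their birds more than the birds
    depend on them.
    """
    matrix = _as_matrix(web)
    row_tot = matrix.sum(axis=1)
    col_tot = matrix.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        warnings.warn(
            "species without realized links excluded from asymmetry"
        )

    plant_vals = []
    for i in range(matrix.shape[0]):
        if row_tot[i] == 0:
            continue
        link_vals = []
        for j in range(matrix.shape[1]):
            a = matrix[i, j]
            if a <= 0:
                continue
            d_plant = a / row_tot[i]
            d_bird = a / col_tot[j]
            link_vals.append((d_plant - d_bird) / max(d_plant, d_bird))
        plant_vals.append(np.mean(link_vals))

    bird_vals = []
    for j in range(matrix.shape[1]):
        if col_tot[j] == 0:
            continue
        link_vals = []
        for i in range(matrix.shape[0]):
            a = matrix[i, j]
            if a <= 0:
                continue
            d_plant = a / row_tot[i]
            d_bird = a / col_tot[j]
            link_vals.append((d_bird - d_plant) / max(d_plant, d_bird))
        bird_vals.append(np.mean(link_vals))

    return float(np.mean(plant_vals)), float(np.mean(bird_vals))


@dataclass
class MetricConfig:
    """Conventions and costs for the six-parameter metric battery."""

    evenness_denominator: str = "cells"
    win_replicates: int = 1000


def compute_all_metrics(
    web: MatrixLike,
    config: MetricConfig = MetricConfig(),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """All six network parameters as an ordered dict keyed by METRIC_NAMES."""
    asym_plants, asym_birds = guild_asymmetry(web)
    return {
        "connectance": connectance(web),
        "nodf": nodf(web),
        "weighted_nestedness": weighted_nestedness(
            web, replicates=config.win_replicates, seed=seed, rng=rng
        ),
        "interaction_evenness": interaction_evenness(
            web, denominator=config.evenness_denominator
        ),
        "asymmetry_birds": asym_birds,
        "asymmetry_plants": asym_plants,
    }


def metrics_report(metrics: Dict[str, float]) -> pd.DataFrame:
    """One row per metric (name, value) — the observed-value column."""
    return pd.DataFrame(
        {"metric": list(metrics.keys()), "value": list(metrics.values())}
    )
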