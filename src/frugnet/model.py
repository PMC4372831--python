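"""Heteroscedastic least-squares modelling of log interaction frequency.

The response ``y_p = ln(F_p + offset)`` for pair *p* is modelled as

    y_p = x_p' beta + eps_p,      eps_p ~ Normal(0, sigma^2 * v_p)

where the variance covariate ``v_p`` is a strictly positive column of the
predictor table (by default ``size_overlap``, whose ``1e-5`` placeholder
guarantees positivity).  Estimation is by maximum likelihood: beta comes from
weighted least squares with weights ``1/v_p`` and ``sigma^2_hat`` is the
weighted residual sum of squares over *n*.  The exact Gaussian log-likelihood
(including the ``sum(ln v_p)`` Jacobian term) feeds AIC = -2*ll + 2*k with
*k* counting the variance scale as one parameter, so models with different
fixed effects are comparable.

Candidate models are ranked by AIC; Akaike weights
``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` quantify relative support,
and per-variable importance is an averaged weight sum:
the summed weight of models containing the variable divided by the number of
such models (the candidate set is deliberately unbalanced across variables).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

#: Explanatory variables a model term may reference.
VARIABLES = (
    "size_overlap",
    "temporal_overlap",
    "abundance_product",
    "fibre",
    "proteins",
    "sugars",
    "lipids",
    "bird_identity",
)

CATEGORICAL = {"bird_identity"}

MAX_TERMS = 5


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: a name and a list of design terms.

    Terms are main effects (``"size_overlap"``) or pairwise statistical
    interactions (``"fibre:bird_identity"``).  At most :data:`MAX_TERMS`
    terms per model, a guard against overfitting on small pair tables.
    """

    name: str
    terms: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) > MAX_TERMS:
            raise ValueError(
                f"model {self.name!r}: {len(self.terms)} terms exceeds the "
                f"{MAX_TERMS}-term cap"
            )
        for term in self.terms:
            for part in term.split(":"):
                if part not in VARIABLES:
                    raise ValueError(
                        f"model {self.name!r}: unknown variable {part!r} in term {term!r}"
                    )
            if term.count(":") > 1:
                raise ValueError(
                    f"model {self.name!r}: only pairwise interactions supported ({term!r})"
                )

    @property
    def variables(self) -> Tuple[str, ...]:
        """Distinct variables appearing in the terms (interaction parents count)."""
        seen: List[str] = []
        for term in self.terms:
            for part in term.split(":"):
                if part not in seen:
                    seen.append(part)
        return tuple(seen)

    def formula_rhs(self) -> str:
        """Patsy right-hand side; categorical variables wrapped in ``C()``."""

        def wrap(v: str) -> str:
            return f"C({v})" if v in CATEGORICAL else v

        if not self.terms:
            return "1"
        return "1 + " + " + ".join(
            ":".join(wrap(p) for p in term.split(":")) for term in self.terms
        )


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.Series
    sigma2: float
    log_likelihood: float
    aic: float
    n_parameters: int
    fitted: np.ndarray
    variance_covariate: str = "size_overlap"

    @property
    def n_obs(self) -> int:
        return len(self.fitted)

    def wald_intervals(self, X: np.ndarray, v: np.ndarray, level: float = 0.95):
        """Wald confidence intervals for beta from the ML covariance
        ``sigma2 * (X' W X)^-1`` with W = diag(1/v)."""
        cov = self.sigma2 * np.linalg.inv(X.T @ (X / v[:, None]))
        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.coefficients.to_numpy()
        return est - z * se, est + z * se


@dataclass
class ModelSet:
    fits: List[FitResult]
    akaike_weights: np.ndarray

    def __post_init__(self) -> None:
        self.akaike_weights = np.asarray(self.akaike_weights, dtype=float)
        if len(self.akaike_weights) != len(self.fits):
            raise ValueError("one weight per fit required")
        if abs(self.akaike_weights.sum() - 1.0) > 1e-9:
            raise ValueError("Akaike weights must sum to 1")

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def to_dataframe(self) -> pd.DataFrame:
        aics = np.array([f.aic for f in self.fits])
        return pd.DataFrame(
            {
                "model": [f.spec.name for f in self.fits],
                "aic": aics,
                "delta_aic": aics - aics.min(),
                "weight": self.akaike_weights,
                "n_parameters": [f.n_parameters for f in self.fits],
            }
        )


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Build the design matrix for a spec from the predictor table."""
    return patsy.dmatrix(spec.formula_rhs(), table, return_type="dataframe")


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) normalised; invariant to adding a constant to all AICs."""
    aics = np.asarray(aics, dtype=float)
    rel = np.exp(-(aics - aics.min()) / 2.0)
    return rel / rel.sum()


def fit_gls_fixed_variance(
    table: pd.DataFrame,
    spec: ModelSpec,
    variance_covariate: str = "size_overlap",
) -> FitResult:
    """Maximum-likelihood fit with variance proportional to a covariate.

    Equivalent to weighted least squares with weights ``1/v``; the reported
    log-likelihood is the exact Gaussian one, and AIC counts the variance
    scale as a parameter (k = #coefficients + 1).
    """
    v = table[variance_covariate].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError(
            f"variance covariate {variance_covariate!r} must be strictly positive"
        )
    y = table["response"].to_numpy(dtype=float)
    X = design_matrix(table, spec)
    Xmat = X.to_numpy()
    rank = np.linalg.matrix_rank(Xmat)
    if rank < Xmat.shape[1]:
        _, _, vh = np.linalg.svd(Xmat)
        null_vec = np.abs(vh[-1])
        involved = [
            c for c, coef in zip(X.columns, null_vec) if coef > 1e-8 * null_vec.max()
        ]
        raise np.linalg.LinAlgError(
            f"model {spec.name!r}: design matrix is rank deficient "
            f"(rank {rank} < {Xmat.shape[1]}); collinear columns: {involved}"
        )
    res = sm.WLS(y, Xmat, weights=1.0 / v).fit()
    n = len(y)
    resid = y - res.fittedvalues
    wrss = float(np.sum(resid**2 / v))
    sigma2 = wrss / n
    log_lik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * float(
        np.sum(np.log(v))
    )
    k = Xmat.shape[1] + 1
    aic = -2.0 * log_lik + 2.0 * k
    return FitResult(
        spec=spec,
        coefficients=pd.Series(res.params, index=list(X.columns)),
        sigma2=sigma2,
        log_likelihood=log_lik,
        aic=aic,
        n_parameters=k,
        fitted=np.asarray(res.fittedvalues),
        variance_covariate=variance_covariate,
    )


def rank_models(
    table: pd.DataFrame,
    specs: Sequence[ModelSpec],
    variance_covariate: str = "size_overlap",
) -> ModelSet:
    """Fit every spec and rank by AIC (ties: fewer parameters, then name)."""
    fits = []
    for spec in specs:
        try:
            fits.append(fit_gls_fixed_variance(table, spec, variance_covariate))
        except Exception as exc:
            raise RuntimeError(f"fit failed for model {spec.name!r}: {exc}") from exc
    fits.sort(key=lambda f: (f.aic, f.n_parameters, f.spec.name))
    return ModelSet(fits=fits, akaike_weights=akaike_weights([f.aic for f in fits]))


def variable_importance(model_set: ModelSet) -> pd.DataFrame:
    """Averaged Akaike-weight importance per explanatory variable.

    For each variable: the number of candidate models containing it (as a
    main effect or inside an interaction), the summed weight of those models,
    and the average (summed weight / model count).  Sorted by decreasing
    averaged weight.
    """
    import warnings

    rows: Dict[str, Dict[str, float]] = {}
    for fit, w in zip(model_set.fits, model_set.akaike_weights):
        for var in fit.spec.variables:
            entry = rows.setdefault(var, {"n_models": 0, "summed_weight": 0.0})
            entry["n_models"] += 1
            entry["summed_weight"] += float(w)
    missing = [v for v in VARIABLES if v not in rows]
    if rows and missing:
        warnings.warn(f"variables absent from every model omitted: {missing}")
    table = pd.DataFrame(
        [
            {
                "variable": var,
                "n_models": int(entry["n_models"]),
                "summed_weight": entry["summed_weight"],
                "averaged_weight": entry["summed_weight"] / entry["n_models"],
            }
            for var, entry in rows.items()
        ]
    )
    return table.sort_values(
        ["averaged_weight", "variable"], ascending=[False, True]
    ).reset_index(drop=True)


def default_model_set() -> List[ModelSpec]:
    """The default 24-model candidate list.

    The set contains an intercept-only null model and covers each variable in
    a fixed number of models (size overlap 3, temporal overlap 7, abundance 7,
    bird identity 14, each nutrient 5), reflecting a natural-history-driven
    rather than balanced design: bird identity is allowed to interact with
    most variable blocks, size overlap enters only alone, with bird identity,
    and in the full trait-plus-abundance model, and nutrients are split into
    a non-energetic (fibre, proteins) and a highly energetic (sugars, lipids)
    block wherever the five-term cap forbids using all four together.
    """
    S, T, A, B = "size_overlap", "temporal_overlap", "abundance_product", "bird_identity"
    Fi, Pr, Su, Li = "fibre", "proteins", "sugars", "lipids"
    specs = [
        ModelSpec("null", ()),
        # single-variable models
        ModelSpec("size", (S,)),
        ModelSpec("temporal", (T,)),
        ModelSpec("abundance", (A,)),
        ModelSpec("fibre", (Fi,)),
        ModelSpec("proteins", (Pr,)),
        ModelSpec("sugars", (Su,)),
        ModelSpec("lipids", (Li,)),
        ModelSpec("bird", (B,)),
        # abundance-hypothesis combinations
        ModelSpec("temporal+abundance", (T, A)),
        ModelSpec("energetic", (Su, Li)),
        # bird identity with matching / abundance variables
        ModelSpec("size*bird", (S, B, f"{S}:{B}")),
        ModelSpec("temporal+bird", (T, B)),
        ModelSpec("temporal*bird", (T, B, f"{T}:{B}")),
        ModelSpec("abundance+bird", (A, B)),
        ModelSpec("abundance*bird", (A, B, f"{A}:{B}")),
        # the trait-plus-abundance model and its nutrient-block variants
        ModelSpec("size+temporal+abundance+bird", (S, T, A, B)),
        ModelSpec("nonenergetic+temporal+abundance+bird", (Fi, Pr, T, A, B)),
        ModelSpec("energetic+temporal+abundance+bird", (Su, Li, T, A, B)),
        # nutrient blocks with bird identity
        ModelSpec("nonenergetic+bird", (Fi, Pr, B)),
        ModelSpec("nonenergetic*bird", (Fi, Pr, B, f"{Fi}:{B}", f"{Pr}:{B}")),
        ModelSpec("fibre*bird+proteins", (Fi, Pr, B, f"{Fi}:{B}")),
        ModelSpec("energetic+bird", (Su, Li, B)),
        ModelSpec("energetic*bird", (Su, Li, B, f"{Su}:{B}", f"{Li}:{B}")),
    ]
    assert len(specs) == 24
    return specs


def predict_interaction_matrix(
    fit: FitResult, table: pd.DataFrame, log_offset: float = 1.0
):
    """Back-transform fitted responses to an expected interaction matrix.

    ``F_hat = max(exp(y_hat) - offset, 0)`` per pair, assembled plants x birds
    in the table's pair order.  No smearing correction is applied: downstream
    the matrix is normalised into a probability matrix, so only relative
    magnitudes matter.
    """
    from .webs import QuantitativeWeb

    values = np.clip(np.exp(fit.fitted) - log_offset, 0.0, None)
    frame = table[["plant", "bird"]].copy()
    frame["value"] = values
    plants = list(dict.fromkeys(frame["plant"]))
    birds = list(dict.fromkeys(frame["bird"]))
    pivot = frame.pivot(index="plant", columns="bird", values="value")
    pivot = pivot.loc[plants, birds]
    return QuantitativeWeb(pivot.to_numpy(), plants, birds)


def per_species_linear_fit(
    table: pd.DataFrame, x: str, bird: str
) -> Tuple[float, float, float]:
    """OLS of response vs one predictor restricted to one bird's rows.

    Returns (slope, intercept, r_squared) — the simple descriptive per-bird
    fits used to visualise how each disperser responds to a fruit trait.
    """
    rows = table[table["bird"] == bird]
    if len(rows) < 3:
        raise ValueError(f"bird {bird!r}: need >= 3 rows, have {len(rows)}")
    xv = rows[x].to_numpy(dtype=float)
    yv = rows["response"].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise ValueError(f"bird {bird!r}: predictor {x!r} has zero variance")
    if np.ptp(yv) == 0:
        # flat response: zero slope, no variance explained
        return 0.0, float(yv[0]), 0.0
    res = stats.linregress(xv, yv)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
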