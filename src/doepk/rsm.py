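"""Second-order response-surface modelling and multi-response optimization.

The workhorse is :class:`QuadraticSurface`, a scikit-learn style regressor
fitting the full second-order polynomial in coded factor levels

    y = b0 + sum_i bi*xi + sum_{i<j} bij*xi*xj + sum_i bii*xi**2

by ordinary least squares (1 + 2k + k(k-1)/2 coefficients for k factors).
Models are always fit on coded units, which keeps linear terms orthogonal to
quadratic terms on a face-centred CCD.  ANOVA with a lack-of-fit test against
centre-point pure error assesses adequacy, and Derringer-Suich desirability
combines several fitted responses into a single optimization objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .designs import FactorDefinition, coded_to_actual

__all__ = [
    "QuadraticSurface",
    "SingularFitError",
    "fit_quadratic",
    "anova_lack_of_fit",
    "surface_grid",
    "DesirabilityGoal",
    "individual_desirability",
    "overall_desirability",
    "optimize_desirability",
]


class SingularFitError(ValueError):
    """Raised when the quadratic model matrix is rank deficient."""


def quadratic_term_names(k: int) -> list[str]:
    """Coefficient names b0, b1..bk, bij (i<j), bii for k factors."""
    names = ["b0"] + [f"b{i + 1}" for i in range(k)]
    names += [f"b{i + 1}{j + 1}" for i, j in combinations(range(k), 2)]
    names += [f"b{i + 1}{i + 1}" for i in range(k)]
    return names


def _design_matrix(X: np.ndarray) -> np.ndarray:
    """Expand coded points to [1, xi, xi*xj (i<j), xi^2] columns."""
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in combinations(range(k), 2)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


class QuadraticSurface(BaseEstimator, RegressorMixin):
    """Full second-order polynomial response surface fitted by OLS.

    Parameters
    ----------
    response_name : str
        Label for the modelled response (used in reports).

    Attributes
    ----------
    coef_ : ndarray of shape (n_terms,)
        Fitted coefficients ordered intercept, linear, interaction, quadratic.
    coef_names_ : list of str
        Names b0, b1, ..., b12, ..., b11, ... matching ``coef_``.
    bse_ : ndarray
        Per-coefficient standard errors.
    resid_std_ : float
        Residual standard deviation (root MSE).
    r_squared_ : float
        Coefficient of determination of the fit.
    n_factors_ : int
        Number of coded factors k.
    """

    def __init__(self, response_name: str = "y"):
        self.response_name = response_name

    def fit(self, X, y) -> "QuadraticSurface":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_runs, n_factors)")
        y = np.asarray(y, dtype=float).ravel()
        n, k = X.shape
        names = quadratic_term_names(k)
        M = _design_matrix(X)
        if n < M.shape[1]:
            raise SingularFitError(
                f"{n} runs cannot identify {M.shape[1]} coefficients"
            )
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            aliased = _aliased_terms(M, names)
            raise SingularFitError(
                f"rank-deficient model matrix; aliased terms: {aliased}"
            )
        res = sm.OLS(y, M).fit()
        self.n_factors_ = k
        self.coef_names_ = names
        self.coef_ = np.asarray(res.params)
        self.bse_ = np.asarray(res.bse)
        self.resid_std_ = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0
        self.r_squared_ = float(res.rsquared)
        self._sm_results_ = res
        self._X_fit_ = X
        self._y_fit_ = y
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_factors_:
            raise ValueError(
                f"expected {self.n_factors_} factors, got {X.shape[1]}"
            )
        return _design_matrix(X) @ self.coef_

    def coefficients(self) -> pd.Series:
        """Named coefficient vector."""
        check_is_fitted(self, "coef_")
        return pd.Series(self.coef_, index=self.coef_names_, name=self.response_name)


def _aliased_terms(M: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    kept: list[int] = []
    for j in range(M.shape[1]):
        trial = M[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def fit_quadratic(
    design: pd.DataFrame, response: pd.DataFrame | pd.Series, response_name: str | None = None
) -> QuadraticSurface:
    """Fit a :class:`QuadraticSurface` from a design table and response column.

    ``design`` uses the layout produced by :func:`doepk.designs.generate_fccd`;
    every column other than ``exp_no``/``run_order``/``point_type`` is a coded
    factor.
    """
    factor_cols = [
        c for c in design.columns if c not in ("exp_no", "run_order", "point_type")
    ]
    X = design[factor_cols].to_numpy(dtype=float)
    if isinstance(response, pd.DataFrame):
        if response_name is None:
            raise ValueError("response_name required with a response table")
        y = response[response_name].to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        response_name = response_name or getattr(response, "name", "y") or "y"
    return QuadraticSurface(response_name=response_name).fit(X, y)


class PureErrorUnavailable(ValueError):
    """Raised when no replicated runs exist to estimate pure error."""


def anova_lack_of_fit(model: QuadraticSurface) -> pd.DataFrame:
    """ANOVA table with lack-of-fit partitioned against replicate pure error.

    Residual sum of squares is split into lack-of-fit (model inadequacy at
    distinct design points) and pure error (within-replicate scatter, from
    the centre points on a standard CCD).  F_lof = MS_lof / MS_pe with
    (df_lof, df_pe) degrees of freedom; a large F flags an inadequate model.

    Returns a DataFrame indexed by source (model, residual, lack_of_fit,
    pure_error, total) with columns ss, df, ms, F, p.
    """
    check_is_fitted(model, "coef_")
    X, y = model._X_fit_, model._y_fit_
    yhat = model.predict(X)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(np.sum((y - yhat) ** 2))
    ss_model = ss_total - ss_resid
    n, p = len(y), len(model.coef_)
    df_model, df_resid = p - 1, n - p

    # pure error: group replicated design points
    groups: dict[tuple, list[float]] = {}
    for row, yi in zip(X, y):
        groups.setdefault(tuple(np.round(row, 12)), []).append(yi)
    replicated = {k: v for k, v in groups.items() if len(v) > 1}
    if not replicated:
        raise PureErrorUnavailable(
            "no replicated runs: pure error (and lack of fit) cannot be estimated"
        )
    ss_pe = float(
        sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in replicated.values())
    )
    df_pe = sum(len(v) - 1 for v in replicated.values())
    ss_lof = ss_resid - ss_pe
    df_lof = df_resid - df_pe

    rows = {
        "model": [ss_model, df_model],
        "residual": [ss_resid, df_resid],
        "lack_of_fit": [ss_lof, df_lof],
        "pure_error": [ss_pe, df_pe],
        "total": [ss_total, n - 1],
    }
    table = pd.DataFrame(rows, index=["ss", "df"]).T
    table["ms"] = np.where(table["df"] > 0, table["ss"] / table["df"], np.nan)
    table["F"] = np.nan
    table["p"] = np.nan
    if df_resid > 0:
        ms_resid = ss_resid / df_resid
        if ms_resid > 0:
            f_model = (ss_model / df_model) / ms_resid
            table.loc["model", "F"] = f_model
            table.loc["model", "p"] = stats.f.sf(f_model, df_model, df_resid)
    if df_lof > 0 and df_pe > 0 and ss_pe > 0:
        f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        table.loc["lack_of_fit", "F"] = f_lof
        table.loc["lack_of_fit", "p"] = stats.f.sf(f_lof, df_lof, df_pe)
    return table


def surface_grid(
    model: QuadraticSurface,
    ranges: list[tuple[float, float]] | None = None,
    resolution: int = 41,
) -> pd.DataFrame:
    """Predictions on a regular coded grid, long format for surface plots.

    Only two-factor models are gridded (the usual 3-D plot).  Returns columns
    x1, x2, prediction.
    """
    check_is_fitted(model, "coef_")
    if model.n_factors_ != 2:
        raise ValueError("surface grids are defined for two-factor models")
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    if ranges is None:
        ranges = [(-1.0, 1.0), (-1.0, 1.0)]
    ax1 = np.linspace(*ranges[0], resolution)
    ax2 = np.linspace(*ranges[1], resolution)
    g1, g2 = np.meshgrid(ax1, ax2, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    return pd.DataFrame(
        {"x1": pts[:, 0], "x2": pts[:, 1], "prediction": model.predict(pts)}
    )


@dataclass(frozen=True)
class DesirabilityGoal:
    """A Derringer-Suich goal for one response.

    direction 'minimize': d = 1 below ``low``, 0 above ``high``, linear ramp
    between.  'maximize': mirrored.  'target': two linear ramps peaking at
    ``target``.  ``weight`` is the goal's relative importance in the overall
    geometric mean; weights are normalized, so scaling all of them by the
    same positive constant leaves D unchanged.
    """

    response_name: str
    direction: str  # minimize | maximize | target
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize", "target"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not self.low < self.high:
            raise ValueError("goal bounds require low < high")
        if self.direction == "target":
            if self.target is None or not (self.low < self.target < self.high):
                raise ValueError("target goals need low < target < high")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def individual_desirability(value: np.ndarray | float, goal: DesirabilityGoal) -> np.ndarray:
    """d(value) in [0, 1] for a single goal (vectorized)."""
    v = np.asarray(value, dtype=float)
    lo, hi = goal.low, goal.high
    if goal.direction == "minimize":
        d = (hi - v) / (hi - lo)
    elif goal.direction == "maximize":
        d = (v - lo) / (hi - lo)
    else:
        t = goal.target
        d = np.where(v <= t, (v - lo) / (t - lo), (hi - v) / (hi - t))
    return np.clip(d, 0.0, 1.0)


def overall_desirability(d_values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted geometric mean of per-response desirabilities.

    Zero anywhere forces the overall D to zero (a hard veto), the defining
    property of the geometric-mean combiner.
    """
    d = np.asarray(d_values, dtype=float)
    w = np.ones(d.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    out = np.exp(np.tensordot(w, logd, axes=(0, 0)))
    return np.where(np.any(d == 0, axis=0), 0.0, out)


@dataclass
class OptimizationResult:
    coded: np.ndarray
    actual: dict[str, float] = field(default_factory=dict)
    desirability: float = 0.0
    predictions: dict[str, float] = field(default_factory=dict)
    all_zero: bool = False


def optimize_desirability(
    models: list[QuadraticSurface],
    goals: list[DesirabilityGoal],
    resolution: int = 201,
    factors: list[FactorDefinition] | None = None,
) -> OptimizationResult:
    """Grid-search the coded square for the maximum overall desirability.

    Each goal must reference the ``response_name`` of one fitted model.  A
    dense resolution x resolution grid over [-1, 1]^2 is evaluated exactly;
    with 2 coded factors this is cheap and auditable against brute force.
    When ``factors`` are supplied the optimum is also reported in actual
    units.  If D = 0 everywhere the result flags ``all_zero`` rather than
    raising.
    """
    if not goals:
        raise ValueError("at least one desirability goal is required")
    by_name = {m.response_name: m for m in models}
    for g in goals:
        if g.response_name not in by_name:
            raise ValueError(f"no fitted model for response {g.response_name!r}")
    k = models[0].n_factors_
    if k != 2:
        raise ValueError("grid optimization implemented for two coded factors")

    ax = np.linspace(-1.0, 1.0, resolution)
    g1, g2 = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])

    preds = {g.response_name: by_name[g.response_name].predict(pts) for g in goals}
    d_stack = np.vstack(
        [individual_desirability(preds[g.response_name], g) for g in goals]
    )
    D = overall_desirability(d_stack, weights=np.array([g.weight for g in goals]))
    best = int(np.argmax(D))
    coded_best = pts[best]

    result = OptimizationResult(
        coded=coded_best,
        desirability=float(D[best]),
        predictions={
            name: float(by_name[name].predict(coded_best[None, :])[0])
            for name in by_name
        },
        all_zero=bool(np.all(D == 0.0)),
    )
    if factors is not None:
        result.actual = {
            f.symbol: coded_to_actual(f, c) for f, c in zip(factors, coded_best)
        }
    return result
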