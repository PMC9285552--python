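"""Statistical layer: equation development and evaluation.

Four pieces of machinery sit here:

``fit_equation``
    Ordinary least squares development of CH4 / MCF prediction
    equations on a cow panel, reporting adjusted R2, the regression
    root mean square error sqrt(SSE/(n - p - 1)), coefficient standard
    errors and variance inflation factors.

``fit_time_model``
    The repeated-measures linear mixed model for per-visit responses
    (CH4/CO2 ratio, corrected concentrations, eructation rate): fixed
    effects of time after eating, time x diet, and diet (high-fibre
    diet as reference level), random intercepts for Latin-square group
    and cow within group, fitted by REML.

``regress_through_origin`` / ``evaluate_predictions``
    Through-origin regressions of predicted on observed emissions, the
    standard agreement summary for method comparison.

``residual_dim_diagnostic``
    Regression of residuals (observed - predicted) on days in milk
    with a pointwise 95% prediction band, flagging early-lactation
    bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .formulas import EquationSpec

__all__ = [
    "EquationFit",
    "MixedFit",
    "OriginRegression",
    "DimDiagnostic",
    "CollinearityError",
    "fit_equation",
    "fit_time_model",
    "regress_through_origin",
    "residual_dim_diagnostic",
    "evaluate_predictions",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient (perfectly collinear covariates)."""


@dataclass
class EquationFit:
    """An estimated prediction equation plus fit diagnostics."""

    spec: EquationSpec
    n: int
    adj_r2: float
    rmse: float
    vif: dict[str, float]
    residuals: np.ndarray


@dataclass
class MixedFit:
    """Fitted repeated-measures mixed model for a per-visit response.

    ``fixed`` is a tidy table with index terms ``intercept``, ``time``,
    ``time:<diet>`` and ``diet:<diet>`` (non-reference levels only) and
    columns ``coef``, ``se``, ``p``. ``variance_components`` holds the
    square, cow-within-square and residual variances.
    """

    response: str
    fixed: pd.DataFrame
    variance_components: dict[str, float]
    diets: tuple[str, ...]
    reference_diet: str
    n: int
    converged: bool
    boundary: bool = False
    method: str = "reml"
    aic: float | None = None

    def coef(self, term: str) -> float:
        return float(self.fixed.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.fixed.loc[term, "se"])

    def time_slope(self, diet: str) -> float:
        """Slope of the response on time after eating for one diet
        (common slope plus the diet interaction; reference diet gets
        the common slope alone)."""
        if diet not in self.diets:
            raise ValueError(f"unknown diet {diet!r}; fitted levels: {self.diets}")
        slope = self.coef("time")
        term = f"time:{diet}"
        if term in self.fixed.index:
            slope += self.coef(term)
        return slope


@dataclass(frozen=True)
class OriginRegression:
    """Through-origin linear fit y = b x."""

    slope: float
    adj_r2: float
    rmse: float
    n: int


@dataclass
class DimDiagnostic:
    """Residual-vs-days-in-milk regression with a 95% prediction band."""

    slope: float
    intercept: float
    p_value: float
    adj_r2: float
    rmse: float
    n: int
    dim: np.ndarray
    residuals: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    outside: np.ndarray  # boolean mask of points beyond the band


def _vif(X: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors by auxiliary regressions of each
    covariate on the others (with intercept)."""
    out: dict[str, float] = {}
    n, p = X.shape
    for j, name in enumerate(names):
        if p == 1:
            out[name] = 1.0
            continue
        others = np.delete(X, j, axis=1)
        aux = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = min(aux.rsquared, 1.0 - 1e-12)
        out[name] = 1.0 / (1.0 - r2)
    return out


def fit_equation(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
    response_kind: str | None = None,
    name: str = "fitted",
) -> EquationFit:
    """Develop a linear prediction equation by ordinary least squares.

    ``data`` is a cow panel with one column per covariate (keys
    ``LW``, ``DMI``, ``ECM``, ``CH4CO2``) and the response column.
    Adjusted R2 uses 1 - (1 - R2)(n - 1)/(n - p - 1) and the RMSE is
    the regression root mean square error sqrt(SSE/(n - p - 1)).
    """
    cols = list(covariates) + [response]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"panel is missing column(s) {missing}")
    sub = data[cols]
    if sub.isna().any().any():
        raise ValueError("panel contains missing values in used columns")
    n = len(sub)
    p = len(covariates)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    X = sub[list(covariates)].to_numpy(float)
    y = sub[response].to_numpy(float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    rmse = float(np.sqrt(res.ssr / (n - p - 1)))
    if response_kind is None:
        response_kind = "MCF_J_per_100J" if response.upper().startswith("MCF") else "CH4_L_per_day"
    spec = EquationSpec(
        name=name,
        response=response_kind,
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        coefficients={c: float(b) for c, b in zip(covariates, res.params[1:])},
        coefficient_se={c: float(s) for c, s in zip(covariates, res.bse[1:])},
        adj_r2=float(min(max(res.rsquared_adj, 1e-12), 1.0)),
        rmse=max(rmse, np.finfo(float).tiny),
    )
    return EquationFit(
        spec=spec,
        n=n,
        adj_r2=float(res.rsquared_adj),
        rmse=rmse,
        vif=_vif(X, covariates),
        residuals=np.asarray(res.resid),
    )


_TIME_MODEL_COLS = ("square", "cow_id", "diet", "time")


def _tidy_fixed(params, bses, pvalues, ref: str) -> pd.DataFrame:
    rows = {}
    for raw in params.index:
        if raw == "Intercept":
            term = "intercept"
        elif raw == "time":
            term = "time"
        elif raw.startswith("time:"):
            term = "time:" + raw.split("[T.")[1].rstrip("]")
        elif "[T." in raw:
            term = "diet:" + raw.split("[T.")[1].rstrip("]")
        else:  # pragma: no cover - unexpected patsy term
            term = raw
        rows[term] = (float(params[raw]), float(bses[raw]), float(pvalues[raw]))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["coef", "se", "p"])


def fit_time_model(
    visits: pd.DataFrame,
    response: str = "ratio",
    reference_diet: str = "HF",
    random_effects: bool = True,
) -> MixedFit:
    """Fit the repeated-measures time-after-eating model.

    ``visits`` needs columns ``square``, ``cow_id``, ``diet``,
    ``time`` (hours after last eating) and the response. Fixed
    effects: time, time x diet, diet (``reference_diet`` as reference
    level); random intercepts for square and cow within square,
    estimated by REML. With a single diet level the model reduces to
    intercept + time. ``random_effects=False`` drops the random
    intercepts and fits the same fixed design by OLS (the
    zero-variance-component limit of the mixed model).

    A fit whose cow or square variance collapses to (numerically)
    zero is returned with ``boundary=True`` rather than raised.
    """
    needed = [c for c in _TIME_MODEL_COLS if c not in visits.columns]
    if needed:
        raise ValueError(f"visit table is missing column(s) {needed}")
    if response not in visits.columns:
        raise ValueError(f"visit table has no response column {response!r}")
    df = visits.dropna(subset=[*_TIME_MODEL_COLS, response]).copy()
    df["cow_id"] = df["cow_id"].astype(str)
    df["square"] = df["square"].astype(str)
    diets = tuple(sorted(df["diet"].unique()))
    multi_diet = len(diets) > 1
    if multi_diet:
        if reference_diet not in diets:
            raise ValueError(f"reference diet {reference_diet!r} absent from data")
        rhs = f"time + time:C(diet, Treatment('{reference_diet}')) + C(diet, Treatment('{reference_diet}'))"
    else:
        rhs = "time"
    formula = f"{response} ~ {rhs}"

    if not random_effects:
        res = smf.ols(formula, data=df).fit()
        fixed = _tidy_fixed(res.params, res.bse, res.pvalues, reference_diet)
        resid_var = float(res.ssr / res.df_resid)
        return MixedFit(
            response=response,
            fixed=fixed,
            variance_components={"square": 0.0, "cow": 0.0, "residual": resid_var},
            diets=diets,
            reference_diet=reference_diet if multi_diet else diets[0],
            n=len(df),
            converged=True,
            boundary=False,
            method="ols",
            aic=float(res.aic),
        )

    model = smf.mixedlm(
        formula,
        data=df,
        groups=df["square"],
        re_formula="1",
        vc_formula={"cow": "0 + C(cow_id)"},
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    fixed = _tidy_fixed(res.params[res.fe_params.index], res.bse[res.fe_params.index], res.pvalues[res.fe_params.index], reference_diet)
    var_square = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re is not None else 0.0
    var_cow = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    # a component this far below the residual variance is numerically on
    # the boundary of the parameter space (singular fit)
    boundary = var_square < 1e-4 * var_resid or var_cow < 1e-4 * var_resid
    return MixedFit(
        response=response,
        fixed=fixed,
        variance_components={"square": var_square, "cow": var_cow, "residual": var_resid},
        diets=diets,
        reference_diet=reference_diet if multi_diet else diets[0],
        n=len(df),
        converged=bool(res.converged),
        boundary=boundary,
        method="reml",
        aic=float(res.aic) if res.aic is not None else None,
    )


def select_time_model(
    visits: pd.DataFrame,
    response: str = "ratio",
    reference_diet: str = "HF",
) -> MixedFit:
    """Choose the within-cow covariance structure by AIC.

    Two candidates are expressible with random intercepts: the full
    model (square + cow intercepts; the cow intercept induces compound
    symmetry within cow) and the square-only model (independent
    residuals within cow). Both are fitted by ML-comparable AIC and
    the winner is refitted by REML conventions.
    """
    full = fit_time_model(visits, response, reference_diet, random_effects=True)
    plain = fit_time_model(visits, response, reference_diet, random_effects=False)
    if full.aic is not None and plain.aic is not None and plain.aic < full.aic:
        return plain
    return full


def regress_through_origin(x, y) -> OriginRegression:
    """Least-squares line through the origin, slope = sum(xy)/sum(x^2).

    ``rmse`` is sqrt(SSE/(n - 1)) (one estimated parameter) and
    ``adj_r2`` is the uncentered adjusted R2 conventional for
    no-intercept fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("sum of squares of x must be positive")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    n = len(x)
    sse = float(resid @ resid)
    syy = float(y @ y)
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * n / (n - 1) if n > 1 else r2
    rmse = float(np.sqrt(sse / (n - 1))) if n > 1 else 0.0
    return OriginRegression(slope=slope, adj_r2=float(adj_r2), rmse=rmse, n=n)


def residual_dim_diagnostic(observed, predicted, dim, alpha: float = 0.05) -> DimDiagnostic:
    """Regress residuals (observed - predicted) on days in milk.

    Returns the OLS line, fit statistics, the pointwise
    ``1 - alpha`` prediction band at the observed DIM values, and the
    mask of residuals falling outside the band. A positive slope with
    early-lactation points below the band signals overestimation of
    young-lactation cows by a fixed-HPU prediction.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    dim = np.asarray(dim, dtype=float)
    if not (len(observed) == len(predicted) == len(dim)):
        raise ValueError("observed, predicted and dim must have equal length")
    n = len(observed)
    if n <= 3:
        raise ValueError("need more than 3 points for the diagnostic")
    resid = observed - predicted
    X = sm.add_constant(dim)
    res = sm.OLS(resid, X).fit()
    pred = res.get_prediction(X).summary_frame(alpha=alpha)
    lower = pred["obs_ci_lower"].to_numpy()
    upper = pred["obs_ci_upper"].to_numpy()
    outside = (resid < lower) | (resid > upper)
    return DimDiagnostic(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        adj_r2=float(res.rsquared_adj),
        rmse=float(np.sqrt(res.ssr / (n - 2))),
        n=n,
        dim=dim,
        residuals=resid,
        lower=lower,
        upper=upper,
        outside=outside,
    )


def evaluate_predictions(
    observed,
    predictions: Mapping[str, np.ndarray] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Through-origin agreement table of predictions vs observations.

    ``predictions`` is either a mapping label -> predicted vector or a
    single vector with ``labels`` giving its name. Each row reports
    the through-origin slope (a slope of 1 means unbiased proportional
    agreement), adjusted R2, RMSE and n.
    """
    observed = np.asarray(observed, dtype=float)
    if not isinstance(predictions, Mapping):
        label = labels[0] if labels else "predicted"
        predictions = {label: np.asarray(predictions, dtype=float)}
    rows = []
    for label, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        if pred.shape != observed.shape:
            raise ValueError(f"prediction {label!r} length mismatch")
        fit = regress_through_origin(observed, pred)
        rows.append(
            {"method": label, "slope": fit.slope, "adj_r2": fit.adj_r2, "rmse": fit.rmse, "n": fit.n}
        )
    return pd.DataFrame(rows).set_index("method")
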