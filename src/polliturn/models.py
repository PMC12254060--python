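"""Regression layer: effort regressions, collinearity screening, contrasts, seasonal LMMs.

Two families of models are fit to the turnover tables:

* multiple linear regressions of mean dissimilarity on ordinal day and the
  number of pooled plots (each as linear + quadratic terms, optionally with
  their interaction), with a generalized variance-inflation-factor screen,
  AIC-based choice between linear-only and quadratic candidates, and
  Tukey-adjusted pairwise contrasts between plot-count levels;

* linear mixed models of the full-effort weekly turnover series with
  ordinal day (linear + quadratic, centered) as fixed effects and year as
  a random intercept, estimated by REML.

Quadratic terms use orthogonalized (centered) polynomial coding, which
leaves fitted values and AIC unchanged but decouples the degree-1/degree-2
collinearity that raw polynomials suffer from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

Response = Literal["beta_wn", "beta_os", "beta_st"]


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (no constant column), as R's ``poly()``.

    Columns are mutually orthogonal, orthogonal to the intercept, and
    scaled to unit norm.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(x)) <= degree:
        raise ValueError("x has too few distinct values for the requested degree")
    raw = np.vander(x - x.mean(), degree + 1, increasing=True)
    q, _ = np.linalg.qr(raw)
    basis = q[:, 1:]
    # sign convention: each column positively correlated with x^k
    for k in range(degree):
        if np.dot(basis[:, k], raw[:, k + 1]) < 0:
            basis[:, k] = -basis[:, k]
    return basis


@dataclass(frozen=True)
class RegressionSpec:
    """Design of one effort regression."""

    response: Response = "beta_wn"
    day_degree: int = 2
    plots_degree: int = 2
    include_interaction: bool = False
    orthogonal: bool = True  # False: raw (uncentered) polynomial scales

    def __post_init__(self) -> None:
        if self.day_degree not in (1, 2) or self.plots_degree not in (1, 2):
            raise ValueError("polynomial degrees must be 1 or 2")


@dataclass
class ModelFit:
    """An OLS fit plus the term structure needed for gVIF and contrasts."""

    spec: RegressionSpec
    result: object  # statsmodels RegressionResults
    data: pd.DataFrame  # observations the design was built from
    term_columns: dict[str, list[int]]  # term -> design-column indices (excl. intercept)
    design: np.ndarray  # full design matrix incl. intercept

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def nobs(self) -> int:
        return int(self.result.nobs)

    def gvif_table(self) -> pd.DataFrame:
        return gvif(self.design[:, 1:], self.term_columns)


def _build_design(
    data: pd.DataFrame, spec: RegressionSpec
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    day = data["day_mid"].to_numpy(dtype=float)
    npl = data["n_plots"].to_numpy(dtype=float)

    def poly_cols(x: np.ndarray, degree: int, name: str) -> tuple[np.ndarray, list[str]]:
        if spec.orthogonal:
            cols = orthogonal_poly(x, degree)
        else:
            cols = np.column_stack([x**k for k in range(1, degree + 1)])
        names = [name if k == 1 else f"{name}^{k}" for k in range(1, degree + 1)]
        return cols, names

    day_cols, day_names = poly_cols(day, spec.day_degree, "day")
    plot_cols, plot_names = poly_cols(npl, spec.plots_degree, "n_plots")

    blocks = [np.ones((len(data), 1)), day_cols, plot_cols]
    names = ["const"] + day_names + plot_names
    terms: dict[str, list[int]] = {
        "day": list(range(0, spec.day_degree)),
        "n_plots": list(range(spec.day_degree, spec.day_degree + spec.plots_degree)),
    }
    if spec.include_interaction:
        inter = (day_cols[:, 0] * plot_cols[:, 0]).reshape(-1, 1)
        blocks.append(inter)
        names.append("day:n_plots")
        terms["day:n_plots"] = [spec.day_degree + spec.plots_degree]
    X = np.hstack(blocks)
    return X, names, terms


def fit_effort_regression(aggregates: pd.DataFrame, spec: RegressionSpec) -> ModelFit:
    """OLS of a mean dissimilarity component on ordinal day and plot count.

    ``aggregates`` must carry columns ``day_mid``, ``n_plots`` and the
    response.  A rank-deficient design is a hard error naming the aliased
    columns.
    """
    data = aggregates.reset_index(drop=True)
    n_params = 1 + spec.day_degree + spec.plots_degree + int(spec.include_interaction)
    if len(data) < n_params + 2:
        raise ValueError(f"need at least {n_params + 2} observations, have {len(data)}")
    X, names, terms = _build_design(data, spec)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    y = data[spec.response].to_numpy(dtype=float)
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    return ModelFit(spec=spec, result=res, data=data, term_columns=terms, design=X)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def gvif(predictors: np.ndarray, term_columns: dict[str, list[int]]) -> pd.DataFrame:
    """Generalized VIF per term via determinant ratios of the predictor
    correlation matrix, with the dimension-adjusted gVIF^(1/(2 Df))."""
    R = np.corrcoef(predictors, rowvar=False)
    R = np.atleast_2d(R)
    det_R = np.linalg.det(R)
    if abs(det_R) < 1e-300:
        raise ValueError("singular predictor correlation matrix")
    rows = []
    all_idx = set(range(predictors.shape[1]))
    for term, cols in term_columns.items():
        others = sorted(all_idx - set(cols))
        det_a = np.linalg.det(R[np.ix_(cols, cols)])
        det_b = np.linalg.det(R[np.ix_(others, others)]) if others else 1.0
        g = det_a * det_b / det_R
        df = len(cols)
        rows.append({"term": term, "df": df, "gvif": g, "gvif_adj": g ** (1.0 / (2 * df))})
    return pd.DataFrame(rows)


@dataclass
class GvifDecision:
    """Outcome of the collinearity screen."""

    before: pd.DataFrame
    threshold: float
    drop_interaction: bool
    refit: ModelFit | None = None
    after: pd.DataFrame | None = None


def gvif_screen(fit: ModelFit, threshold: float = 5.0) -> GvifDecision:
    """Screen a fit for collinearity on the dimension-adjusted gVIF scale.

    When any term's gVIF^(1/(2 Df)) exceeds the threshold and the model
    has an interaction term, the screen recommends dropping the
    interaction, refits, and reports the gVIF table of the refit.
    """
    if len(fit.term_columns) < 2:
        return GvifDecision(before=fit.gvif_table(), threshold=threshold, drop_interaction=False)
    table = fit.gvif_table()
    exceeded = bool((table["gvif_adj"] > threshold).any())
    drop = exceeded and fit.spec.include_interaction
    decision = GvifDecision(before=table, threshold=threshold, drop_interaction=drop)
    if drop:
        new_spec = RegressionSpec(
            response=fit.spec.response,
            day_degree=fit.spec.day_degree,
            plots_degree=fit.spec.plots_degree,
            include_interaction=False,
            orthogonal=True,
        )
        decision.refit = fit_effort_regression(fit.data, new_spec)
        decision.after = decision.refit.gvif_table()
    return decision


def compare_aic(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Rank fits of the same observations by AIC (ascending; delta to best)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    y0 = fits[0].result.model.endog
    for f in fits[1:]:
        y = f.result.model.endog
        if len(y) != len(y0) or not np.allclose(y, y0):
            raise ValueError("fits do not share identical response observations")
    rows = [
        {
            "spec": f"{f.spec.response}~day^{f.spec.day_degree}+plots^{f.spec.plots_degree}"
            + ("+day:plots" if f.spec.include_interaction else ""),
            "aic": f.aic,
            "fit": f,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


def plot_count_contrasts(fit: ModelFit) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts between plot-count levels.

    The continuous model is refit internally with plot count as a
    categorical factor (day terms retained); estimated marginal means are
    evaluated at the mean ordinal day, so level differences reduce to
    factor-coefficient differences.  Adjusted p-values use the studentized
    range with as many groups as levels.
    """
    data = fit.data
    levels = np.sort(data["n_plots"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 plot-count levels for contrasts")
    day = data["day_mid"].to_numpy(dtype=float)
    day_cols = orthogonal_poly(day, fit.spec.day_degree)
    dummies = np.column_stack([(data["n_plots"] == lv).to_numpy(float) for lv in levels[1:]])
    X = np.hstack([np.ones((len(data), 1)), day_cols, dummies])
    names = (
        ["const"]
        + [f"day^{k}" for k in range(1, fit.spec.day_degree + 1)]
        + [f"n_plots[{int(lv)}]" for lv in levels[1:]]
    )
    res = sm.OLS(data[fit.spec.response].to_numpy(float), pd.DataFrame(X, columns=names)).fit()
    k = len(levels)
    df_resid = res.df_resid
    cov = res.cov_params().to_numpy()
    params = res.params.to_numpy()

    def level_vec(i: int) -> np.ndarray:
        v = np.zeros(X.shape[1])
        if i > 0:
            v[1 + fit.spec.day_degree + (i - 1)] = 1.0
        return v

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = level_vec(i) - level_vec(j)
            est = float(c @ params)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se
            p = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
            rows.append(
                {
                    "level_1": int(levels[i]),
                    "level_2": int(levels[j]),
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_tukey": min(1.0, p),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LmmFit:
    """REML random-intercept fit of a weekly turnover series."""

    fe_params: pd.Series  # intercept, day, day^2 (day centered)
    fe_se: pd.Series
    re_variance: float  # between-year intercept variance
    resid_variance: float
    year_intercepts: pd.Series  # predicted (BLUP) deviations per year
    n_obs: int
    n_years: int
    result: object = field(repr=False, default=None)


def fit_seasonal_lmm(
    series: pd.DataFrame,
    response: Response = "beta_wn",
    day_col: str = "day_mid",
    year_col: str = "year",
) -> LmmFit:
    """LMM: response ~ day + day^2 (fixed, centered) + (1 | year), REML.

    Requires at least two years and ten rows; with one year there is no
    between-year variance to estimate and ordinary regression applies.
    """
    data = series.dropna(subset=[response, day_col, year_col])
    years = data[year_col].unique()
    if len(years) < 2:
        raise ValueError("only one year present: fit an ordinary regression instead")
    if len(data) < 10:
        raise ValueError("need at least 10 observations")
    d = data[day_col].to_numpy(float)
    d = d - d.mean()
    X = pd.DataFrame({"const": 1.0, "day": d, "day2": d**2}, index=data.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(data[response].to_numpy(float), X, groups=data[year_col].to_numpy())
        res = model.fit(reml=True, maxiter=500)
    re_variance = float(np.asarray(res.cov_re)[0, 0])
    if re_variance < 1e-10:
        # boundary estimate: the model degenerates to OLS (and the profiled
        # GLS step returns an unusable intercept), so report the OLS fit
        ols = sm.OLS(data[response].to_numpy(float), X).fit()
        return LmmFit(
            fe_params=ols.params,
            fe_se=ols.bse,
            re_variance=re_variance,
            resid_variance=float(ols.scale),
            year_intercepts=pd.Series(0.0, index=sorted(pd.unique(data[year_col]))),
            n_obs=int(ols.nobs),
            n_years=len(years),
            result=ols,
        )
    try:
        re = pd.Series(
            {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
        ).sort_index()
    except (ValueError, np.linalg.LinAlgError):
        re = pd.Series(0.0, index=sorted(pd.unique(data[year_col])))
    return LmmFit(
        fe_params=res.fe_params,
        fe_se=res.bse_fe,
        re_variance=re_variance,
        resid_variance=float(res.scale),
        year_intercepts=re,
        n_obs=int(res.nobs),
        n_years=len(years),
        result=res,
    )
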