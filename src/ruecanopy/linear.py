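"""Best-subset multiple linear regression with VIF screening.

The two linear model families for predicting RUE, biomass and IPAR are
*bcs* (best combination of sensors — any instrument or leaf layer) and *cVI*
(canopy vegetation indices only).  Both are built the same way: exhaustive
enumeration of predictor subsets up to ``max_k`` terms, discarding any subset
containing a predictor whose variance inflation factor (VIF = 1/(1 − R²) of
that predictor regressed on the others in the subset) exceeds a threshold,
then ranking survivors by in-sample R² (ties: fewer predictors, then lower
RMSE).

The module follows the statsmodels Model/Results convention:
``BestSubsetLinear(y, X).fit()`` returns a :class:`BestSubsetResults` carrying
the selected :class:`LinearModelSpec`, fit metrics, the VIF audit and a
``summary()`` table.  A registry of published models (26 entries: 13 traits ×
{bcs, cVI}) ships with the package; predictor keys follow the
``<INDEX><layer><period>`` convention with layer ∈ {can, FL, SL, TL} and
period ∈ {vg, gf} (sensor traits CT, SPAD, NDVIGS, Jmax, VcmaxNarea keep
their instrument names).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .stats import r_squared, rmse

__all__ = [
    "LinearModelSpec",
    "FitMetrics",
    "BestSubsetLinear",
    "BestSubsetResults",
    "fit_linear",
    "vif",
    "best_subset",
    "apply_model",
    "published_models",
    "PUBLISHED_MODELS",
]


@dataclass(frozen=True)
class FitMetrics:
    """In- or out-of-sample fit quality."""

    r_squared: float
    rmse: float
    n: int
    adj_r_squared: float = math.nan

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared must be <= 1")


@dataclass(frozen=True)
class LinearModelSpec:
    """Intercept + named coefficients of one linear prediction model."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    provenance: str = "fitted"  # or "published_table"

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("a model needs >= 1 coefficient")
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValueError("duplicate predictor names")

    def to_json(self) -> str:
        return json.dumps(
            {
                "response": self.response,
                "intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModelSpec":
        d = json.loads(text)
        return cls(
            response=d["response"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            provenance=d.get("provenance", "fitted"),
        )


def apply_model(spec: LinearModelSpec, predictors: pd.DataFrame | dict) -> np.ndarray:
    """Evaluate b0 + Σ b_i·x_i row-wise; errors on a missing predictor column."""
    if isinstance(predictors, dict):
        predictors = pd.DataFrame(predictors)
    missing = [k for k in spec.coefficients if k not in predictors.columns]
    if missing:
        raise KeyError(f"predictor(s) {missing} missing from table for model {spec.response!r}")
    out = np.full(len(predictors), spec.intercept, dtype=float)
    for name, b in spec.coefficients.items():
        out = out + b * predictors[name].to_numpy(dtype=float)
    return out


def fit_linear(
    design: pd.DataFrame, response: pd.Series | np.ndarray, response_name: str = "y"
) -> tuple[LinearModelSpec, FitMetrics]:
    """Ordinary least squares fit of ``response`` on all columns of ``design``."""
    X = design.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design/response contain missing values; drop or impute first")
    Xd = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < p + 1:
        # name the collinear columns via correlation of residual projections
        bad = []
        for j, col in enumerate(design.columns):
            others = np.delete(Xd, j + 1, axis=1)
            proj, *_ = np.linalg.lstsq(others, Xd[:, j + 1], rcond=None)
            if np.allclose(others @ proj, Xd[:, j + 1], atol=1e-8):
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear predictor(s): {bad}")
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    spec = LinearModelSpec(
        response=response_name,
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(design.columns, beta[1:])},
    )
    pred = Xd @ beta
    r2 = r_squared(pred, y)
    # adjusted R² from the SSE-based R² (identical to squared correlation
    # in-sample for a fitted OLS model)
    sse_r2 = 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
    adj = 1.0 - (1.0 - sse_r2) * (n - 1) / (n - p - 1)
    return spec, FitMetrics(r_squared=r2, rmse=rmse(pred, y), n=n, adj_r_squared=float(adj))


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per predictor: 1/(1 − R²_j) of j on the rest.

    Perfect collinearity is reported as ``math.inf``.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs >= 2 predictors")
    X = design.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, col in enumerate(cols):
        xj = X[:, j]
        if np.ptp(xj) == 0:
            raise ValueError(f"predictor {col!r} is constant")
        others = np.column_stack([np.ones(X.shape[0]), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        sst = np.sum((xj - xj.mean()) ** 2)
        r2_j = 1.0 - np.sum(resid**2) / sst
        out[col] = math.inf if r2_j >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2_j))
    return out


@dataclass
class SubsetSearchResult:
    """Winner of the exhaustive subset search plus its audit trail."""

    best: LinearModelSpec
    fit: FitMetrics
    vif: dict[str, float]
    candidates_evaluated: int
    leaderboard: pd.DataFrame = dc_field(repr=False, default=None)


def best_subset(
    design: pd.DataFrame,
    response: pd.Series | np.ndarray,
    max_k: int = 3,
    vif_max: float = 10.0,
    response_name: str = "y",
    size_alpha: float = 0.05,
) -> SubsetSearchResult:
    """Exhaustive best-subset regression with a VIF multicollinearity screen.

    Every predictor subset of size 1..max_k is enumerated; subsets in which
    any VIF exceeds ``vif_max`` are discarded.  Within each size the survivor
    with the highest in-sample R² wins (ties: lower RMSE); a larger size then
    displaces the current winner only when its incremental F statistic is
    significant at the Bonferroni-corrected level ``size_alpha / p`` (the
    F-to-enter rule, family-wise over the p candidate predictors).  The gate
    is what keeps noise predictors out: raw in-sample R² alone would always
    prefer the largest size.  When the improvement is exactly zero — the
    noise-free tie — the smaller subset wins.
    """
    cols = list(design.columns)
    p = len(cols)
    if p > 25:
        raise ValueError(f"exhaustive search capped at 25 predictors, got {p}")
    y = np.asarray(response, dtype=float)
    n = y.size
    if n <= max_k + 1:
        raise ValueError(f"need n > max_k + 1 (n={n}, max_k={max_k})")
    max_k = min(max_k, p)
    sst = float(np.sum((y - y.mean()) ** 2))

    evaluated = 0
    rows = []
    best_by_size: dict[int, tuple] = {}
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(cols, k):
            evaluated += 1
            sub = design[list(subset)]
            if k >= 2:
                vifs = vif(sub)
                if any(v > vif_max for v in vifs.values()):
                    continue
            else:
                vifs = {subset[0]: 1.0}
            try:
                spec, metrics = fit_linear(sub, y, response_name=response_name)
            except ValueError:
                continue  # rank-deficient subset
            rows.append(
                {
                    "predictors": subset,
                    "k": k,
                    "r2": metrics.r_squared,
                    "adj_r2": metrics.adj_r_squared,
                    "rmse": metrics.rmse,
                }
            )
            key = (-metrics.r_squared, metrics.rmse)
            if k not in best_by_size or key < best_by_size[k][0]:
                best_by_size[k] = (key, spec, metrics, vifs)
    if not best_by_size:
        raise ValueError(
            f"no subset of size <= {max_k} survives the VIF <= {vif_max} screen; "
            "consider a higher vif_max"
        )

    alpha = size_alpha / p
    sizes = sorted(best_by_size)
    winner = best_by_size[sizes[0]]
    winner_k = sizes[0]
    for k in sizes[1:]:
        cand = best_by_size[k]
        sse_small = (1.0 - _sse_r2(winner[2], sst, n)) * sst
        sse_big = (1.0 - _sse_r2(cand[2], sst, n)) * sst
        df_num = k - winner_k
        df_den = n - k - 1
        if sse_big <= 0 or df_den <= 0:
            # perfect fit at the larger size: accept only if the smaller is not
            # also perfect (the noise-free tie keeps the smaller subset)
            if sse_small > 1e-12 * sst:
                winner, winner_k = cand, k
            continue
        F = ((sse_small - sse_big) / df_num) / (sse_big / df_den)
        if F > 0 and sps_f_sf(F, df_num, df_den) < alpha:
            winner, winner_k = cand, k
    _, spec, metrics, vifs = winner
    board = pd.DataFrame(rows).sort_values(
        ["r2", "k", "rmse"], ascending=[False, True, True]
    ).reset_index(drop=True) if rows else pd.DataFrame()
    return SubsetSearchResult(
        best=spec, fit=metrics, vif=vifs, candidates_evaluated=evaluated, leaderboard=board
    )


def _sse_r2(metrics: FitMetrics, sst: float, n: int) -> float:
    """SSE-based R² recovered from RMSE (exact in-sample)."""
    return 1.0 - (metrics.rmse**2 * n) / sst


def sps_f_sf(F: float, dfn: int, dfd: int) -> float:
    from scipy.stats import f as f_dist

    return float(f_dist.sf(F, dfn, dfd))


class BestSubsetLinear:
    """Best-subset linear model, statsmodels-style.

    Parameters
    ----------
    endog : response series (named, or pass ``response_name``).
    exog : DataFrame of candidate predictors (no intercept column).
    max_k : largest subset size searched (exhaustive enumeration).
    vif_max : multicollinearity threshold; subsets with any VIF above it are
        discarded.
    """

    def __init__(
        self,
        endog: pd.Series | np.ndarray,
        exog: pd.DataFrame,
        max_k: int = 3,
        vif_max: float = 10.0,
        response_name: str | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.max_k = max_k
        self.vif_max = vif_max
        self.response_name = response_name or getattr(endog, "name", None) or "y"

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, predictors: list[str] | None = None, **kw):
        predictors = predictors or [c for c in data.columns if c != response]
        sub = data[[response, *predictors]].dropna()
        return cls(sub[response], sub[predictors], response_name=response, **kw)

    def fit(self) -> "BestSubsetResults":
        res = best_subset(
            self.exog,
            self.endog,
            max_k=self.max_k,
            vif_max=self.vif_max,
            response_name=self.response_name,
        )
        return BestSubsetResults(self, res)


class BestSubsetResults:
    """Fit results: the winning model spec, metrics, VIF audit, leaderboard."""

    def __init__(self, model: BestSubsetLinear, search: SubsetSearchResult):
        self.model = model
        self.search = search
        self.spec = search.best
        self.metrics = search.fit
        self.vif = search.vif
        self.candidates_evaluated = search.candidates_evaluated

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"Intercept": self.spec.intercept, **self.spec.coefficients},
            name=self.spec.response,
        )

    def predict(self, exog: pd.DataFrame | None = None) -> np.ndarray:
        table = self.model.exog if exog is None else exog
        return apply_model(self.spec, table)

    def evaluate(self, exog: pd.DataFrame, obs) -> FitMetrics:
        pred = self.predict(exog)
        return FitMetrics(
            r_squared=r_squared(pred, obs), rmse=rmse(pred, obs), n=len(pred)
        )

    def evaluate_best_values(self, exog: pd.DataFrame, obs, n_best: int = 10) -> FitMetrics:
        """Metrics recomputed on the n_best rows with highest *observed* response."""
        obs = np.asarray(obs, dtype=float)
        idx = np.argsort(obs)[-n_best:]
        pred = self.predict(exog)[idx]
        return FitMetrics(r_squared=r_squared(pred, obs[idx]), rmse=rmse(pred, obs[idx]), n=len(idx))

    def summary(self) -> str:
        lines = [
            f"Best-subset linear model for {self.spec.response}",
            f"  n = {self.metrics.n}, candidates evaluated = {self.candidates_evaluated}",
            f"  R^2 = {self.metrics.r_squared:.4f}   adj. R^2 = {self.metrics.adj_r_squared:.4f}   "
            f"RMSE = {self.metrics.rmse:.4f}",
            f"  Intercept  {self.spec.intercept: .6g}",
        ]
        for name, b in self.spec.coefficients.items():
            v = self.vif.get(name, float("nan"))
            lines.append(f"  {name:<18s}{b: .6g}   VIF={v:.2f}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Published model registry: 13 traits × {bcs, cVI}.  Coefficients are the
# printed values; cVI predictor names are normalised to <INDEX>can<period>.
# --------------------------------------------------------------------------

_PUBLISHED: list[tuple[str, str, float, dict[str, float]]] = [
    ("RUE_E40InB", "bcs", -9.347,
     {"WIcanvg": 12.906, "NDVITLvg": -4.004, "TCARITLvg": -0.795}),
    ("RUE_E40InB", "cVI", -15.443,
     {"PSSRbcanvg": -0.0674, "WIcanvg": 16.469}),
    ("RUE_InBA7", "bcs", -1.791,
     {"NDWI-3canvg": 13.247, "EVITLvg": 4.721, "TCARI_705,750TLvg": 6.656}),
    ("RUE_InBA7", "cVI", 7.543,
     {"NDWI-3canvg": 28.717, "EVIcanvg": -3.123}),
    ("RUE_preGF", "bcs", 0.47,
     {"SPADTLvg": 0.0446}),
    ("RUE_preGF", "cVI", 19.762,
     {"CRIcanvg": 0.0389, "NDVIcanvg": -22.547, "NDWIcanvg": 10.455, "PRIcanvg": 53.698}),
    ("RUE_GF", "bcs", -2.523,
     {"VARIcanvg": -10.05, "RARSacangf": -4.661, "SIPI-1TLvg": 16.258,
      "GITLgf": 1.17, "JmaxFLgf": -0.0112, "VcmaxNareaSLvg": -0.0401}),
    ("RUE_GF", "cVI", 3.886,
     {"PRIcanvg": -79.296, "GIcangf": -0.675}),
    ("RUE_Total", "bcs", 5.972,
     {"NDWI-2canvg": -15.681, "CURSLvg": -5.458, "NPCITLgf": 2.21}),
    ("RUE_Total", "cVI", 0.845,
     {"RGRcangf": 0.992}),
    ("BM_E40", "bcs", 294.202,
     {"JmaxTLvg": -0.394}),
    ("BM_E40", "cVI", 56.67,
     {"WIcanvg": 610.986, "NDVIcanvg": -844.888, "SAVIcanvg": 308.836}),
    ("BM_InB", "bcs", 89.423,
     {"NDWI-4canvg": -220.49, "GIFLvg": 213.15, "TCARITLvg": -344.448}),
    ("BM_InB", "cVI", -206.393,
     {"NDWI-4canvg": -7575.28, "TCARIcanvg": 737.072}),
    ("BM_A7", "bcs", 435.468,
     {"PRIcanvg": 14412.02, "PRIFLgf": 9039.943}),
    ("BM_A7", "cVI", 696.304,
     {"PRIcanvg": 15902.35}),
    ("BM_PM", "bcs", 361.694,
     {"PSSRaFLvg": 98.526, "RARSbSLvg": 106.66, "SIPI-2SLvg": -1.52, "SR-1TLvg": -135.394}),
    ("BM_PM", "cVI", 674.582,
     {"CRIcanvg": -44.419, "PSSRacanvg": 43.295, "SIPI-2canvg": -2.543}),
    ("IPAR_E40", "bcs", 289.723,
     {"CTvg": -9.158, "NDVIGSvg": 168.407}),
    ("IPAR_E40", "cVI", 80.287,
     {"NDWI-3canvg": -2056.97}),
    ("IPAR_InB", "bcs", 26.039,
     {"NDVIGSvg": 306.267, "PRIcanvg": 6808.693}),
    ("IPAR_InB", "cVI", -500.416,
     {"OSAVIcanvg": 1051.142}),
    ("IPAR_A7", "bcs", 875.05,
     {"CTgf": 36.048, "PRIcanvg": 6718.306, "GNDVI-1cangf": 509.163, "NDWI-4cangf": -2997.16}),
    ("IPAR_A7", "cVI", 618.021,
     {"PRIcanvg": 6935.272, "rNDVIcangf": -33.644}),
    ("IPAR_PM", "bcs", 40.181,
     {"PRIcanvg": 12435.71, "SAVIcanvg": 1050.561, "SIPI-1cangf": -201.546}),
    ("IPAR_PM", "cVI", 40.181,
     {"PRIcanvg": 12435.71, "SAVIcanvg": 1050.561, "SIPI-1cangf": -201.546}),
]

PUBLISHED_MODELS: dict[str, LinearModelSpec] = {
    f"{trait}_{approach}": LinearModelSpec(
        response=trait,
        intercept=intercept,
        coefficients=coeffs,
        provenance="published_table",
    )
    for trait, approach, intercept, coeffs in _PUBLISHED
}


def published_models() -> dict[str, LinearModelSpec]:
    """The registry of published prediction models, keyed ``<trait>_<approach>``."""
    return dict(PUBLISHED_MODELS)
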