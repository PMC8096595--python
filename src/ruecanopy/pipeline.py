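"""Orchestration: build predictor tables and compare the three model families.

For each RUE growth window the pipeline fits and evaluates six approaches:

* ``bcs`` — best-subset linear model over every sensor column and every
  vegetation index at every layer/period (best combination of sensors);
* ``cVI`` — best-subset linear model over canopy-level vegetation indices only;
* ``PLSR`` — partial least squares on the trimmed canopy reflectance matrix;

each either *direct* (the RUE window is the response) or via *components*
(biomass and IPAR at the window endpoints are predicted separately and RUE is
derived from them with the growth-window formulas; error propagation through
the ratio generally makes this route worse, which is the point of comparing).

Predictor columns follow ``<INDEX><layer><period>`` naming with layer ∈
{can, FL, SL, TL} and period ∈ {vg, gf}; scalar sensor columns (CTvg, SPADTLvg,
NDVIGSvg, JmaxFLgf, ...) come straight from the trait table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import vegindex
from .linear import BestSubsetLinear
from .plsr import PLSRegression, train_test_split
from .spectra import SpectralSet, clean_spurious, select_windows
from .stats import correlation_screen, r_squared, rmse
from .synthetic import SyntheticTrial

__all__ = [
    "LAYER_CODES",
    "PERIOD_CODES",
    "build_predictor_table",
    "canopy_band_matrix",
    "run_direct",
    "run_components",
    "compare_all",
]

LAYER_CODES = {"canopy": "can", "flag_leaf": "FL", "second_leaf": "SL", "third_leaf": "TL"}
PERIOD_CODES = {"vegetative": "vg", "grain_filling": "gf"}

RUE_WINDOWS = ("E40InB", "InBA7", "preGF", "GF", "Total")

#: biomass/IPAR endpoints per window for the components route
_WINDOW_ENDPOINTS = {
    "E40InB": ("BM_E40", "BM_InB", "IPAR_E40", "IPAR_InB"),
    "InBA7": ("BM_InB", "BM_A7", "IPAR_InB", "IPAR_A7"),
    "preGF": ("BM_E40", "BM_A7", "IPAR_E40", "IPAR_A7"),
}


def build_predictor_table(trial: SyntheticTrial) -> pd.DataFrame:
    """One row per plot: sensor columns plus every VI at every layer/period."""
    base = trial.trait_table.set_index("plot_id")
    if len(trial.spectra) == 0:
        return base.reset_index()
    panel = vegindex.compute_panel(trial.spectra)
    # melt index columns into <INDEX><layer><period> names
    long = panel.melt(
        id_vars=["plot_id", "layer", "period"],
        value_vars=list(vegindex.REGISTRY),
        var_name="index",
        value_name="value",
    )
    long["column"] = (
        long["index"]
        + long["layer"].map(LAYER_CODES)
        + long["period"].map(PERIOD_CODES)
    )
    wide = long.pivot_table(index="plot_id", columns="column", values="value", aggfunc="mean")
    return base.join(wide, how="left").reset_index()


def canopy_band_matrix(
    spectra: SpectralSet, period: str | None = "vegetative"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Cleaned, window-trimmed canopy reflectance matrix.

    Returns (X, wavelengths, plot_ids); when ``period`` is None the vegetative
    and grain-filling spectra of each plot are stacked horizontally.
    """
    canopy = SpectralSet([r for r in spectra if r.layer == "canopy"], list(spectra.provenance))
    canopy = select_windows(clean_spurious(canopy, mode="clip"))
    if period is not None:
        sub = SpectralSet([r for r in canopy if r.period == period])
        X, g = sub.to_matrix()
        return X, g, [r.plot_id for r in sub.records]
    by_plot: dict[str, dict[str, np.ndarray]] = {}
    grid = canopy.grid()
    for r in canopy:
        by_plot.setdefault(r.plot_id, {})[r.period] = r.reflectance
    plots = [p for p, d in by_plot.items() if {"vegetative", "grain_filling"} <= set(d)]
    X = np.vstack(
        [np.concatenate([by_plot[p]["vegetative"], by_plot[p]["grain_filling"]]) for p in plots]
    )
    return X, np.concatenate([grid, grid]), plots


def _candidate_columns(table: pd.DataFrame, approach: str) -> list[str]:
    meta = {"plot_id", "genotype_id", "replicate_id", "year"}
    truth = {c for c in table.columns if c.startswith(("BM_", "IPAR_", "RUE_", "GF_MJ"))}
    cols = [c for c in table.columns if c not in meta | truth]
    if approach == "cVI":
        cols = [c for c in cols if any(c == f"{n}can{p}" for n in vegindex.REGISTRY for p in ("vg", "gf"))]
    return [c for c in cols if pd.api.types.is_numeric_dtype(table[c])]


def _screened_design(
    table: pd.DataFrame, response: str, approach: str, alpha: float = 0.05, cap: int = 12
) -> pd.DataFrame:
    """Pearson-screened candidate design (P < alpha, |r|-ranked, capped)."""
    cols = _candidate_columns(table, approach)
    screen = correlation_screen(table, response, alpha=alpha, columns=cols)
    kept = screen[screen["retained"]].reindex(
        screen[screen["retained"]]["r"].abs().sort_values(ascending=False).index
    )["column"].tolist()
    if not kept:  # nothing survives the screen; fall back to the |r| ranking
        kept = screen.reindex(screen["r"].abs().sort_values(ascending=False).index)[
            "column"
        ].tolist()[:3]
    return table[kept[:cap]]


@dataclass
class FittedApproach:
    """A fitted trait model and the plot rows it can predict."""

    trait: str
    approach: str
    predict: object  # callable plot-indexed DataFrame/array -> predictions


def _fit_trait(
    table: pd.DataFrame,
    trial: SyntheticTrial,
    trait: str,
    approach: str,
    train_idx: np.ndarray,
    max_k: int,
    seed: int,
):
    """Fit one trait with one approach on the training rows.

    Returns (predict(rows) callable over positional row indices, model spec
    or summary object).
    """
    if approach in ("bcs", "cVI"):
        design_all = _screened_design(table.iloc[train_idx], trait, approach)
        cols = list(design_all.columns)
        model = BestSubsetLinear(
            table[trait].iloc[train_idx],
            table[cols].iloc[train_idx],
            max_k=max_k,
            response_name=trait,
        )
        res = model.fit()

        def predict(rows: np.ndarray) -> np.ndarray:
            return res.predict(table[cols].iloc[rows])

        return predict, res.spec
    if approach == "PLSR":
        period = "vegetative" if trait.endswith(("E40InB", "InBA7", "preGF", "E40", "InB")) else None
        X, _, plots = canopy_band_matrix(trial.spectra, period=period)
        pos = {p: i for i, p in enumerate(plots)}
        row_to_spec = np.array([pos[p] for p in table["plot_id"]])
        y = table[trait].to_numpy(dtype=float)
        Xtr = X[row_to_spec[train_idx]]
        m = PLSRegression(y[train_idx], Xtr, response_name=trait)
        sel = m.select_components(max_comp=min(12, m.max_components), folds=5, seed=seed)
        res = m.fit(sel.chosen)
        res.selection = sel

        def predict(rows: np.ndarray) -> np.ndarray:
            return res.predict(X[row_to_spec[rows]])

        return predict, {"n_components": res.n_components, "trait": trait}
    raise ValueError(f"unknown approach {approach!r}")


def run_direct(
    trial: SyntheticTrial,
    window: str,
    approach: str,
    table: pd.DataFrame | None = None,
    train_fraction: float = 0.8,
    max_k: int = 3,
    seed: int = 0,
) -> dict:
    """Fit the chosen approach on RUE_<window> directly; hold-out metrics."""
    if window not in RUE_WINDOWS:
        raise ValueError(f"window must be one of {RUE_WINDOWS}")
    table = build_predictor_table(trial) if table is None else table
    trait = f"RUE_{window}"
    train, test = train_test_split(len(table), train_fraction, seed)
    predict, spec = _fit_trait(table, trial, trait, approach, train, max_k, seed)
    obs = table[trait].to_numpy(dtype=float)
    pred = predict(test)
    return {
        "trait": trait,
        "window": window,
        "approach": approach,
        "route": "direct",
        "r2": r_squared(pred, obs[test]),
        "rmse": rmse(pred, obs[test]),
        "n": len(test),
        "spec": spec,
    }


def run_components(
    trial: SyntheticTrial,
    window: str,
    approach: str,
    table: pd.DataFrame | None = None,
    train_fraction: float = 0.8,
    max_k: int = 3,
    seed: int = 0,
) -> dict:
    """Predict the window's biomass/IPAR endpoints, derive RUE, evaluate."""
    if window not in RUE_WINDOWS:
        raise ValueError(f"window must be one of {RUE_WINDOWS}")
    table = build_predictor_table(trial) if table is None else table
    train, test = train_test_split(len(table), train_fraction, seed)

    def fit_pred(trait: str) -> np.ndarray:
        predict, _ = _fit_trait(table, trial, trait, approach, train, max_k, seed)
        return predict(test)

    if window in _WINDOW_ENDPOINTS:
        bm0, bm1, ip0, ip1 = _WINDOW_ENDPOINTS[window]
        num = fit_pred(bm1) - fit_pred(bm0)
        den = fit_pred(ip1) - fit_pred(ip0)
    elif window == "GF":
        table = table.assign(GF_eff=table["GF_MJ75"] + 0.5 * table["GF_MJ25"])
        num = fit_pred("BM_PM") - fit_pred("BM_A7")
        den = fit_pred("GF_eff")
    else:  # Total
        table = table.assign(GF_eff=table["GF_MJ75"] + 0.5 * table["GF_MJ25"])
        num = fit_pred("BM_PM") - fit_pred("BM_E40")
        den = fit_pred("IPAR_A7") + fit_pred("GF_eff") - fit_pred("IPAR_E40")
    den = np.where(np.abs(den) < 1e-9, np.nan, den)
    pred = num / den
    obs = table[f"RUE_{window}"].to_numpy(dtype=float)[test]
    ok = np.isfinite(pred)
    return {
        "trait": f"RUE_{window}",
        "window": window,
        "approach": approach,
        "route": "components",
        "r2": r_squared(pred[ok], obs[ok]),
        "rmse": rmse(pred[ok], obs[ok]),
        "n": int(ok.sum()),
        "spec": None,
    }


def compare_all(
    trial: SyntheticTrial,
    windows=RUE_WINDOWS,
    approaches=("bcs", "cVI", "PLSR"),
    routes=("direct", "components"),
    train_fraction: float = 0.8,
    max_k: int = 3,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Full grid of RUE windows × approaches × routes; tidy comparison table.

    Partial failures (e.g. a window whose derived denominator degenerates) are
    recorded with NaN metrics rather than aborting the grid.  With ``out_dir``
    set, writes comparison.csv, fitted linear model specs under models/, and a
    manifest.json carrying the seed and an input hash.
    """
    table = build_predictor_table(trial)
    rows, specs = [], {}
    for window in windows:
        for approach in approaches:
            for route in routes:
                runner = run_direct if route == "direct" else run_components
                try:
                    res = runner(
                        trial,
                        window,
                        approach,
                        table=table,
                        train_fraction=train_fraction,
                        max_k=max_k,
                        seed=seed,
                    )
                except Exception as exc:  # pragma: no cover - defensive grid
                    res = {
                        "trait": f"RUE_{window}",
                        "window": window,
                        "approach": approach,
                        "route": route,
                        "r2": np.nan,
                        "rmse": np.nan,
                        "n": 0,
                        "spec": None,
                        "error": str(exc),
                    }
                spec = res.pop("spec", None)
                if spec is not None and hasattr(spec, "to_json"):
                    specs[f"RUE_{window}_{approach}_{route}"] = spec
                rows.append(res)
    comparison = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "models").mkdir(parents=True, exist_ok=True)
        comparison.to_csv(out / "comparison.csv", index=False)
        for name, spec in specs.items():
            (out / "models" / f"{name}.json").write_text(spec.to_json())
        digest = hashlib.sha256(
            pd.util.hash_pandas_object(trial.trait_table.round(9)).values.tobytes()
        ).hexdigest()
        manifest = {
            "seed": seed,
            "trial_seed": trial.config.seed,
            "n_rows": int(len(table)),
            "windows": list(windows),
            "approaches": list(approaches),
            "routes": list(routes),
            "input_hash": digest,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return comparison
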