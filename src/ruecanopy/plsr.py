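"""Partial least squares regression on trimmed canopy spectra (NIPALS).

PLSR projects the (samples × bands) reflectance matrix onto a small number of
latent components chosen to maximise covariance with the response, then
regresses the response on the component scores.  The decomposition collapses
to a per-band regression vector and an intercept, so a fitted model is just
"one coefficient per wavelength" and predicts by a dot product with a new
spectrum.

Implementation: single-response NIPALS with X centered (variance scaling
optional; reflectance shares units across bands so it is off by default).
Component count is chosen by k-fold cross-validation: the smallest RMSEP-CV,
with PRESS (= n · RMSEP²) reported alongside; ties break toward fewer
components.  Model validation uses a seeded random 80/20 train/test split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .stats import r_squared, rmse

__all__ = [
    "PLSRegression",
    "PLSResults",
    "ComponentSelection",
    "train_test_split",
    "fit_plsr",
    "select_components",
    "predict_plsr",
]


def train_test_split(
    n_or_index, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random partition of row indices into train/test.

    ``round(train_fraction · n)`` rows go to training.  Accepts either a row
    count or an index-like; returns positional index arrays.
    """
    n = n_or_index if isinstance(n_or_index, (int, np.integer)) else len(n_or_index)
    if n < 5:
        raise ValueError(f"need >= 5 rows to split, got {n}")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _nipals(Xc: np.ndarray, yc: np.ndarray, ncomp: int, tol: float = 1e-12):
    """Single-response NIPALS on centered data.

    Returns weights W, X-loadings P, y-loadings q, scores T (all per
    component).  For a single y the inner iteration converges in one pass.
    """
    n, m = Xc.shape
    W = np.zeros((m, ncomp))
    P = np.zeros((m, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    X, y = Xc.copy(), yc.copy()
    for a in range(ncomp):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < tol:
            # residual X carries no covariance with y; truncate
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < tol:
            return W[:, :a], P[:, :a], q[:a], T[:, :a]
        p = X.T @ t / tt
        qa = (y @ t) / tt
        X = X - np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    return W, P, q, T


@dataclass
class ComponentSelection:
    """Cross-validation trace for choosing the PLSR component count."""

    rmsep_cv: np.ndarray
    press: np.ndarray
    chosen: int
    folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.chosen < 1:
            raise ValueError("chosen component count must be >= 1")


class PLSRegression:
    """PLS regression model for a single response on a band matrix.

    Parameters
    ----------
    endog : response values, length n.
    exog : (n × bands) reflectance matrix (cleaned and window-trimmed).
    wavelengths : optional band grid in nm, kept for model persistence and
        grid checks at prediction time.
    scale : divide each band by its standard deviation after centering.
    """

    def __init__(self, endog, exog, wavelengths=None, scale: bool = False,
                 response_name: str = "y"):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError(
                f"exog must be (n × bands) with n = len(endog); got {self.exog.shape}"
            )
        if np.ptp(self.endog) == 0:
            raise ValueError("response has zero variance")
        self.wavelengths = None if wavelengths is None else np.asarray(wavelengths, dtype=float)
        if self.wavelengths is not None and self.wavelengths.size != self.exog.shape[1]:
            raise ValueError("wavelengths length must equal the band count")
        self.scale = scale
        self.response_name = response_name

    @property
    def max_components(self) -> int:
        return min(self.exog.shape[0] - 1, self.exog.shape[1])

    def _center(self):
        x_mean = self.exog.mean(axis=0)
        x_scale = self.exog.std(axis=0, ddof=1) if self.scale else np.ones(self.exog.shape[1])
        x_scale = np.where(x_scale == 0, 1.0, x_scale)
        Xc = (self.exog - x_mean) / x_scale
        y_mean = self.endog.mean()
        return Xc, self.endog - y_mean, x_mean, x_scale, y_mean

    def fit(self, n_components: int) -> "PLSResults":
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > self.max_components:
            raise ValueError(
                f"n_components={n_components} exceeds rank bound {self.max_components}"
            )
        Xc, yc, x_mean, x_scale, y_mean = self._center()
        W, P, q, T = _nipals(Xc, yc, n_components)
        if W.shape[1] == 0:
            raise ValueError("response carries no covariance with the spectra")
        # regression vector in original band units: B = W (PᵀW)⁻¹ q
        R = W @ np.linalg.inv(P.T @ W)
        beta = (R @ q) / x_scale
        intercept = y_mean - x_mean @ beta
        return PLSResults(
            model=self,
            weights=W,
            loadings=P,
            y_loadings=q,
            scores=T,
            regression_vector=beta,
            intercept=float(intercept),
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=float(y_mean),
            n_components=W.shape[1],
        )

    def select_components(
        self, max_comp: int = 15, folds: int = 10, seed: int = 0
    ) -> ComponentSelection:
        """k-fold CV RMSEP/PRESS per component count; chosen = argmin RMSEP."""
        if folds < 2:
            raise ValueError("folds must be >= 2")
        if max_comp < 1:
            raise ValueError("max_comp must be >= 1")
        n = self.endog.size
        folds = min(folds, n)
        # CV rank bound: the largest training fold has n - floor(n/folds) rows
        cv_bound = min(n - n // folds - 1, self.exog.shape[1])
        if max_comp > cv_bound:
            warnings.warn(
                f"max_comp truncated from {max_comp} to rank bound {cv_bound}",
                stacklevel=2,
            )
            max_comp = cv_bound
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(n) % folds
        press = np.zeros(max_comp)
        for f in range(folds):
            test = assignment == f
            train = ~test
            sub = PLSRegression(
                self.endog[train], self.exog[train], scale=self.scale
            )
            kmax = min(max_comp, sub.max_components)
            res = sub.fit(kmax)
            # predictions for every component count from one decomposition
            for k in range(1, max_comp + 1):
                kk = min(k, res.n_components)
                beta_k = (res.weights[:, :kk] @ np.linalg.inv(
                    res.loadings[:, :kk].T @ res.weights[:, :kk]
                ) @ res.y_loadings[:kk]) / res.x_scale
                icp_k = res.y_mean - res.x_mean @ beta_k
                pred = self.exog[test] @ beta_k + icp_k
                press[k - 1] += np.sum((pred - self.endog[test]) ** 2)
        rmsep = np.sqrt(press / n)
        chosen = int(np.argmin(rmsep)) + 1  # argmin takes the first (fewest) on ties
        return ComponentSelection(
            rmsep_cv=rmsep, press=press, chosen=chosen, folds=folds, seed=seed
        )


@dataclass
class PLSResults:
    """A fitted PLSR model: per-band regression vector plus the decomposition."""

    model: PLSRegression
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    regression_vector: np.ndarray
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    n_components: int
    selection: ComponentSelection | None = dc_field(default=None)

    def predict(self, X_new) -> np.ndarray:
        X = np.asarray(X_new, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.regression_vector.size:
            raise ValueError(
                f"band-grid mismatch: model has {self.regression_vector.size} bands, "
                f"input has {X.shape[1]}"
            )
        return X @ self.regression_vector + self.intercept

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def evaluate(self, X_new, obs) -> dict[str, float]:
        pred = self.predict(X_new)
        return {
            "r2": r_squared(pred, np.asarray(obs, dtype=float)),
            "rmse": rmse(pred, np.asarray(obs, dtype=float)),
            "n": int(len(pred)),
        }

    def summary(self) -> str:
        lines = [
            f"PLSR model for {self.model.response_name}",
            f"  n = {self.model.endog.size}, bands = {self.regression_vector.size}, "
            f"components = {self.n_components}",
            f"  intercept = {self.intercept:.6g}",
            f"  |beta| range = [{np.abs(self.regression_vector).min():.3g}, "
            f"{np.abs(self.regression_vector).max():.3g}]",
        ]
        if self.selection is not None:
            lines.append(
                f"  CV ({self.selection.folds}-fold, seed {self.selection.seed}): "
                f"chosen = {self.selection.chosen}, "
                f"RMSEP = {self.selection.rmsep_cv[self.selection.chosen - 1]:.4g}"
            )
        tr = self.evaluate(self.model.exog, self.model.endog)
        lines.append(f"  training R^2 = {tr['r2']:.4f}, RMSE = {tr['rmse']:.4g}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist as a JSON header line plus (wavelength_nm, coefficient) rows."""
        wl = (
            self.model.wavelengths
            if self.model.wavelengths is not None
            else np.arange(self.regression_vector.size, dtype=float)
        )
        header = {
            "response": self.model.response_name,
            "intercept": self.intercept,
            "y_mean": self.y_mean,
            "n_components": int(self.n_components),
            "scaled": bool(self.model.scale),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            fh.write("wavelength_nm,coefficient\n")
            for w, b in zip(wl, self.regression_vector):
                fh.write(f"{w:g},{b!r}\n")


def fit_plsr(X, y, ncomp: int, wavelengths=None, scale: bool = False) -> PLSResults:
    """Functional wrapper: fit a PLSR model with a fixed component count."""
    return PLSRegression(y, X, wavelengths=wavelengths, scale=scale).fit(ncomp)


def select_components(
    X, y, max_comp: int = 15, folds: int = 10, seed: int = 0, scale: bool = False
) -> ComponentSelection:
    """Functional wrapper: k-fold CV component selection."""
    return PLSRegression(y, X, scale=scale).select_components(
        max_comp=max_comp, folds=folds, seed=seed
    )


def predict_plsr(result: PLSResults, X_new, obs=None):
    """Predict with a fitted model; with observations, also return metrics."""
    pred = result.predict(X_new)
    if obs is None:
        return pred
    return pred, result.evaluate(X_new, obs)
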