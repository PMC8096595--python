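"""Adjusted means, covariate adjustment, correlation screening and fit metrics.

Trial traits are adjusted for replicate (block) effects with the additive
two-way model Y_ij = μ + Rep_i + Genotype_j + ε_ij before genotype means are
compared across years; vegetation indices can additionally be adjusted for
phenology (days to a reference stage) as a covariate.  Candidate predictors
are screened by Pearson correlation with the target at a raw two-sided
P < 0.05 (no multiple-testing correction by default; Benjamini–Hochberg is
available as an option).

Note on R²: throughout this package R² is the squared Pearson correlation
between predicted and observed values (the scatter-plot convention), not
1 − SSE/SST.  The two diverge for biased predictions — squared correlation
ignores calibration offset/slope — so hold-out metrics here reward ranking
fidelity rather than absolute calibration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "adjusted_means",
    "covariate_adjust",
    "correlation_screen",
    "rmse",
    "r_squared",
]


def adjusted_means(
    table: pd.DataFrame,
    trait: str,
    genotype: str = "genotype_id",
    replicate: str = "replicate_id",
) -> pd.Series:
    """Genotype means of ``trait`` after removing additive replicate effects.

    Fits the two-way additive least-squares model with genotype and replicate
    as factors and returns each genotype's predicted value at the average
    replicate effect.  For balanced data this equals the plain genotype mean.
    Rows with missing trait values are dropped.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in table columns {list(table.columns)}")
    df = table[[genotype, replicate, trait]].dropna()
    reps = df[replicate].unique()
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates for block adjustment")

    genos = np.sort(df[genotype].unique())
    g_idx = pd.Categorical(df[genotype], categories=genos).codes
    r_idx = pd.Categorical(df[replicate], categories=np.sort(reps)).codes
    n, nG, nR = len(df), len(genos), len(reps)

    # design: genotype indicators + replicate contrasts (sum-to-zero)
    X = np.zeros((n, nG + nR - 1))
    X[np.arange(n), g_idx] = 1.0
    for j in range(nR - 1):
        X[:, nG + j] = (r_idx == j).astype(float) - (r_idx == nR - 1).astype(float)
    y = df[trait].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta[:nG], index=pd.Index(genos, name=genotype), name=trait)


def covariate_adjust(
    table: pd.DataFrame, trait: str, covariate: str
) -> pd.Series:
    """ANCOVA-style centering: residuals of trait on covariate plus grand mean."""
    for col in (trait, covariate):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    y = table[trait].to_numpy(dtype=float)
    x = table[covariate].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    if np.ptp(x[ok]) == 0:
        raise ValueError(f"covariate {covariate!r} is constant")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - (intercept + slope * x[ok]) + np.mean(y[ok])
    return pd.Series(out, index=table.index, name=f"{trait}_adj")


def correlation_screen(
    panel: pd.DataFrame,
    target: pd.Series | str,
    alpha: float = 0.05,
    columns: list[str] | None = None,
    method: str = "none",
) -> pd.DataFrame:
    """Pearson screen of panel columns against a target trait.

    Returns a DataFrame (column, r, p, n, retained) using pairwise-complete
    observations; columns with fewer than 3 complete pairs are skipped with a
    warning.  ``method="bh"`` applies Benjamini–Hochberg to the p-values
    before thresholding (off by default; the screen is a raw P < alpha
    filter).
    """
    if isinstance(target, str):
        y_all = panel[target]
        candidates = [c for c in (columns or panel.columns) if c != target]
    else:
        y_all = target
        candidates = list(columns or panel.columns)
    y_all = pd.to_numeric(y_all, errors="coerce")

    rows = []
    for col in candidates:
        x = pd.to_numeric(panel[col], errors="coerce")
        ok = x.notna() & y_all.notna()
        n = int(ok.sum())
        if n < 3:
            warnings.warn(f"column {col!r} skipped: only {n} complete pair(s)", stacklevel=2)
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y_all[ok]) == 0:
            warnings.warn(f"column {col!r} skipped: zero variance", stacklevel=2)
            continue
        r, p = sps.pearsonr(x[ok], y_all[ok])
        rows.append({"column": col, "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows, columns=["column", "r", "p", "n"])
    if method == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["retained"] = out["p_adj"] < alpha
    elif method == "none":
        out["retained"] = out["p"] < alpha
    else:
        raise ValueError(f"method must be 'none' or 'bh', got {method!r}")
    return out


def rmse(pred, obs) -> float:
    """Root mean square error, sqrt(mean((pred − obs)²))."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("need >= 1 observation")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(pred, obs) -> float:
    """Squared Pearson correlation between predictions and observations."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if np.ptp(o) == 0:
        raise ValueError("observations have zero variance")
    if np.ptp(p) == 0:
        return 0.0
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)
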