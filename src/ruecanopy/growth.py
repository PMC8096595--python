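"""Ground-truth growth analysis: light interception, IPAR and RUE.

Radiation use efficiency (RUE, g MJ⁻¹) is aboveground dry biomass accumulated
per unit intercepted photosynthetically active radiation (IPAR, MJ m⁻²).  The
analysis follows the classical growth-window decomposition for spring wheat:

* ``E40InB`` — canopy closure (40 days after emergence) to initiation of
  booting (GS41);
* ``InBA7`` — initiation of booting to 7 days after anthesis (GS65 + 7 d);
* ``preGF`` — 40 DAE to 7 days after anthesis;
* ``GF`` — grain filling, 7 days after anthesis to physiological maturity
  (GS87), with a senescence correction: IPAR over the final 25% (in days) of
  grain filling is weighted at 50% because the canopy no longer intercepts
  (or uses) light at full efficiency;
* ``Total`` — 40 DAE to physiological maturity, carrying the same correction.

Incident solar irradiance (MJ m⁻² d⁻¹) is converted to PAR with the standard
0.45 factor; daily canopy interception is the ceptometer-derived LI%
interpolated linearly in calendar time between measurement stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PAR_FRACTION",
    "STAGES",
    "WINDOWS",
    "LightReading",
    "HarvestRecord",
    "GrainFillPAR",
    "RueResult",
    "light_interception_pct",
    "par_from_irradiance",
    "accumulate_ipar",
    "grain_fill_par",
    "aboveground_biomass",
    "rue_interval",
    "rue_grain_filling",
    "rue_total",
    "rue_slope",
]

#: PAR is taken as 0.45 × total solar irradiance.
PAR_FRACTION = 0.45

#: Biomass-harvest stages in phenological order.
STAGES = ("E40", "InB", "A7", "PM")

#: RUE growth windows.
WINDOWS = ("E40InB", "InBA7", "preGF", "GF", "Total")


@dataclass(frozen=True)
class LightReading:
    """One ceptometer triplet: incident, reflected and transmitted PAR."""

    PAR_i: float
    PAR_r: float
    PAR_g: float
    stage_tag: str = ""
    plot_id: str = ""

    def __post_init__(self) -> None:
        if self.PAR_i <= 0:
            raise ValueError(f"incident PAR must be > 0, got {self.PAR_i}")
        if self.PAR_r < 0 or self.PAR_g < 0:
            raise ValueError("reflected/transmitted PAR must be >= 0")
        if self.PAR_r + self.PAR_g > self.PAR_i:
            warnings.warn(
                f"PAR_r + PAR_g exceeds PAR_i for plot {self.plot_id!r} "
                f"({self.PAR_r} + {self.PAR_g} > {self.PAR_i})",
                stacklevel=2,
            )

    @property
    def li_pct(self) -> float:
        return light_interception_pct(self.PAR_i, self.PAR_r, self.PAR_g)


@dataclass(frozen=True)
class HarvestRecord:
    """One biomass cut: fresh/dry subsample weights scaled by total fresh weight."""

    total_FW: float        # g
    subsample_FW: float    # g
    subsample_DW: float    # g
    harvested_area: float  # m²
    stage: str = "E40"
    plot_id: str = ""

    def __post_init__(self) -> None:
        if self.harvested_area <= 0:
            raise ValueError(f"harvested_area must be > 0, got {self.harvested_area}")
        if not (0 < self.subsample_DW <= self.subsample_FW <= self.total_FW):
            raise ValueError(
                "weights must satisfy 0 < subsample_DW <= subsample_FW <= total_FW; "
                f"got DW={self.subsample_DW}, FW={self.subsample_FW}, total={self.total_FW}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")


@dataclass(frozen=True)
class GrainFillPAR:
    """Accumulated PAR split at 75% of the grain-filling period (in days).

    ``mj_acc_75`` is intercepted PAR accumulated over the first 75% of
    grain-filling days (counted at full weight); ``mj_acc_25`` over the final
    25% (counted at half weight in the RUE denominators).
    """

    mj_acc_75: float
    mj_acc_25: float

    def __post_init__(self) -> None:
        if self.mj_acc_75 < 0 or self.mj_acc_25 < 0:
            raise ValueError("grain-fill PAR accumulations must be >= 0")

    @property
    def effective(self) -> float:
        """Senescence-corrected grain-filling IPAR denominator, MJ m⁻²."""
        return self.mj_acc_75 + 0.5 * self.mj_acc_25


@dataclass(frozen=True)
class RueResult:
    """RUE over one growth window, g MJ⁻¹."""

    window: str
    rue: float
    plot_id: str = ""
    genotype_id: str = ""
    flagged_negative: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.window not in WINDOWS:
            raise ValueError(f"window must be one of {WINDOWS}, got {self.window!r}")
        if not np.isfinite(self.rue):
            raise ValueError(f"RUE must be finite, got {self.rue}")
        object.__setattr__(self, "flagged_negative", bool(self.rue < 0))


def light_interception_pct(PAR_i: float, PAR_r: float, PAR_g: float) -> float:
    """Percentage of light intercepted by the canopy.

    LI% = 100 · (PAR_i − PAR_r − PAR_g) / (PAR_i − PAR_r).  Values outside
    [0, 100] can only arise from inconsistent sensor readings and are clipped
    with a warning.
    """
    denom = PAR_i - PAR_r
    if denom <= 0:
        raise ValueError(f"PAR_i must exceed PAR_r (got {PAR_i} <= {PAR_r})")
    li = 100.0 * (PAR_i - PAR_r - PAR_g) / denom
    if li < 0.0 or li > 100.0:
        warnings.warn(f"LI% = {li:.2f} outside [0, 100]; clipped", stacklevel=2)
        li = float(np.clip(li, 0.0, 100.0))
    return li


def par_from_irradiance(irradiance):
    """Convert daily solar irradiance (MJ m⁻² d⁻¹) to PAR (× 0.45)."""
    arr = np.asarray(irradiance, dtype=float)
    if np.any(arr < 0):
        raise ValueError("irradiance must be >= 0")
    out = arr * PAR_FRACTION
    if isinstance(irradiance, pd.Series):
        return pd.Series(out, index=irradiance.index, name=irradiance.name)
    return out if out.ndim else float(out)


def _li_daily(days: np.ndarray, li_days: np.ndarray, li_values: np.ndarray) -> np.ndarray:
    """LI(t) linearly interpolated between measurements, held flat outside."""
    return np.interp(days, li_days, li_values)


def accumulate_ipar(
    li_by_stage: dict[str, float],
    par_daily: pd.Series | np.ndarray,
    stage_days: dict[str, int],
    day_index: np.ndarray | None = None,
) -> dict[str, float]:
    """Accumulated intercepted PAR (MJ m⁻²) at each biomass stage.

    Parameters
    ----------
    li_by_stage : mapping stage -> LI% measured at that stage.
    par_daily : daily PAR series (MJ m⁻² d⁻¹) indexed from emergence; either a
        pandas Series with an integer day index or a plain array taken as
        days 1..n after emergence.
    stage_days : mapping stage -> day after emergence; must be ordered
        E40 < InB < A7 < PM for the stages present.
    day_index : optional explicit day numbers matching ``par_daily``.

    Daily IPAR is PAR(t) × LI(t)/100 with LI(t) interpolated linearly in time
    between measured stages and held constant before the first and after the
    last measurement.  The accumulation runs from the start of the series
    through each stage day inclusive.
    """
    if not li_by_stage:
        raise ValueError("need LI measured at >= 1 stage")
    if isinstance(par_daily, pd.Series):
        days = par_daily.index.to_numpy(dtype=float)
        par = par_daily.to_numpy(dtype=float)
    else:
        par = np.asarray(par_daily, dtype=float)
        days = np.arange(1, par.size + 1, dtype=float) if day_index is None else np.asarray(day_index, dtype=float)

    ordered = [s for s in STAGES if s in stage_days]
    sd = [stage_days[s] for s in ordered]
    if any(b <= a for a, b in zip(sd, sd[1:])):
        raise ValueError(f"stage days must be strictly increasing in {STAGES} order, got {stage_days}")
    for s, d in stage_days.items():
        if d < days[0] or d > days[-1]:
            raise ValueError(f"stage {s!r} day {d} outside met series [{days[0]:g}, {days[-1]:g}]")

    li_stages = [s for s in STAGES if s in li_by_stage]
    li_days = np.array([stage_days[s] for s in li_stages], dtype=float)
    li_vals = np.array([li_by_stage[s] for s in li_stages], dtype=float)
    if np.any(li_vals < 0) or np.any(li_vals > 100):
        raise ValueError("LI% values must lie in [0, 100]")

    li_t = _li_daily(days, li_days, li_vals)
    daily_ipar = par * li_t / 100.0
    cum = np.cumsum(daily_ipar)

    out: dict[str, float] = {}
    prev = -np.inf
    for s in ordered:
        i = int(np.searchsorted(days, stage_days[s], side="right")) - 1
        acc = float(cum[i]) if i >= 0 else 0.0
        out[s] = acc
        if acc < prev - 1e-9:
            raise AssertionError("accumulated IPAR must be non-decreasing across stages")
        prev = acc
    return out


def grain_fill_par(
    li_by_stage: dict[str, float],
    par_daily: pd.Series | np.ndarray,
    stage_days: dict[str, int],
    day_index: np.ndarray | None = None,
) -> GrainFillPAR:
    """Split grain-filling IPAR at 75% of its duration in days.

    Grain filling runs from A7 (exclusive) to PM (inclusive); the split day is
    A7 + 0.75 × (PM − A7), with days at or before the split counted in the
    75% tranche.
    """
    if "A7" not in stage_days or "PM" not in stage_days:
        raise ValueError("grain_fill_par needs stage days for A7 and PM")
    if isinstance(par_daily, pd.Series):
        days = par_daily.index.to_numpy(dtype=float)
        par = par_daily.to_numpy(dtype=float)
    else:
        par = np.asarray(par_daily, dtype=float)
        days = np.arange(1, par.size + 1, dtype=float) if day_index is None else np.asarray(day_index, dtype=float)

    li_stages = [s for s in STAGES if s in li_by_stage]
    li_days = np.array([stage_days[s] for s in li_stages], dtype=float)
    li_vals = np.array([li_by_stage[s] for s in li_stages], dtype=float)
    li_t = _li_daily(days, li_days, li_vals)
    daily_ipar = par * li_t / 100.0

    a7, pm = stage_days["A7"], stage_days["PM"]
    split = a7 + 0.75 * (pm - a7)
    in75 = (days > a7) & (days <= split)
    in25 = (days > split) & (days <= pm)
    return GrainFillPAR(
        mj_acc_75=float(daily_ipar[in75].sum()),
        mj_acc_25=float(daily_ipar[in25].sum()),
    )


def aboveground_biomass(h: HarvestRecord) -> float:
    """Aboveground dry biomass, g m⁻².

    (subsample_DW / subsample_FW) × total_FW / harvested_area — the dry-matter
    fraction of the subsample scales the plot's total fresh weight, expressed
    per unit harvested ground area.
    """
    return (h.subsample_DW / h.subsample_FW) * h.total_FW / h.harvested_area


def rue_interval(
    bm_start: float,
    bm_end: float,
    ipar_start: float,
    ipar_end: float,
    window: str = "preGF",
    **meta,
) -> RueResult:
    """RUE over a window as the ratio of biomass gain to IPAR gain."""
    if ipar_end <= ipar_start:
        raise ValueError(
            f"IPAR must increase over the window (got {ipar_start} -> {ipar_end})"
        )
    return RueResult(window=window, rue=(bm_end - bm_start) / (ipar_end - ipar_start), **meta)


def rue_grain_filling(
    bm_A7: float,
    bm_PM: float,
    gf: GrainFillPAR,
    **meta,
) -> RueResult:
    """Grain-filling RUE with the senescence correction.

    Denominator = IPAR accumulated over the first 75% of grain-filling days
    plus half the IPAR of the final 25%, crediting light intercepted by the
    senescing canopy at 50% efficiency.
    """
    D = gf.effective
    if D <= 0:
        raise ValueError(f"grain-filling IPAR denominator must be > 0, got {D}")
    return RueResult(window="GF", rue=(bm_PM - bm_A7) / D, **meta)


def rue_total(
    bm_E40: float,
    bm_PM: float,
    acc_ipar_E40: float,
    acc_ipar_PM_75: float,
    gf: GrainFillPAR,
    **meta,
) -> RueResult:
    """Whole-cycle RUE (40 DAE to physiological maturity), senescence-corrected.

    ``acc_ipar_PM_75`` is the accumulation from the start of the series
    through 75% of grain filling; the final 25% enters at half weight, so the
    denominator equals the preGF denominator plus the GF denominator.
    """
    D = acc_ipar_PM_75 + 0.5 * gf.mj_acc_25 - acc_ipar_E40
    if D <= 0:
        raise ValueError(f"total IPAR denominator must be > 0, got {D}")
    return RueResult(window="Total", rue=(bm_PM - bm_E40) / D, **meta)


def rue_slope(biomass: np.ndarray, acc_ipar: np.ndarray, window: str = "Total", **meta) -> RueResult:
    """RUE as the least-squares slope of biomass against accumulated IPAR.

    Alternative to the ratio-of-differences estimator when three or more
    (biomass, IPAR) stage points are available for a plot.
    """
    bm = np.asarray(biomass, dtype=float)
    ip = np.asarray(acc_ipar, dtype=float)
    if bm.size != ip.size or bm.size < 2:
        raise ValueError("need >= 2 matching (biomass, IPAR) points")
    if np.ptp(ip) <= 0:
        raise ValueError("IPAR values must vary")
    slope = float(np.polyfit(ip, bm, 1)[0])
    return RueResult(window=window, rue=slope, **meta)
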