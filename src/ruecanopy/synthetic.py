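"""Synthetic multi-genotype canopy trials with known ground truth.

The generator emulates a spring-wheat yield-potential trial: a randomized
complete block design (default 11 genotypes × 3 replicates), biomass harvests
at four stages (canopy closure 40 days after emergence, initiation of booting,
7 days after anthesis, physiological maturity), daily meteorological
irradiance, ceptometer light-interception readings, and hyperspectral
reflectance above the canopy and at three leaf layers.

Construction guarantees
-----------------------
* Biomass follows BM(stage) = BM(prev) + RUE_true · ΔIPAR(window) exactly, so
  in noise-free mode the growth-analysis formulas recover the per-window RUE
  used to generate the trial to machine precision.
* Genotype latent traits (leaf area index, chlorophyll, canopy water,
  stay-green) are tied to the genotype's vegetative and grain-filling RUE, so
  water indices correlate with vegetative growth and senescence indices with
  grain-filling efficiency — the qualitative structure the prediction models
  exploit.
* The forward spectral model is a soil/vegetation mixture (Beer–Lambert in
  LAI) with Gaussian absorption features: chlorophyll at 430/680 nm, water at
  970/1240/1450/1940 nm, a red-edge whose position retreats with senescence.
  It is deliberately not a radiative-transfer model; it only needs monotone,
  physically-signed trait–index links (e.g. deeper 970 nm absorption with
  more canopy water).

All randomness flows from ``TrialConfig.seed`` via one ``numpy`` generator;
the same seed reproduces the trial bit-for-bit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth
from .growth import GrainFillPAR, HarvestRecord, LightReading
from .spectra import SpectralRecord, SpectralSet

__all__ = [
    "TrialConfig",
    "SyntheticTrial",
    "simulate_trial",
    "spectral_forward_model",
    "soil_spectrum",
    "fixtures_table1",
    "DEFAULT_GRID",
]

#: Common 1 nm synthetic band grid.
DEFAULT_GRID = np.arange(350.0, 2501.0)

#: Soil baseline constants: a dull, slowly brightening curve with a mild
#: shoulder through the red edge (ferric absorption analogue).  Its NDVI is
#: ~0.18, the bare-ground baseline downstream tests refer to.
_SOIL_BASE = 0.10
_SOIL_STEP = 0.14
_SOIL_STEP_CENTER = 730.0
_SOIL_STEP_WIDTH = 60.0
_SOIL_SLOPE = 0.03  # total rise over the full grid


def soil_spectrum(grid: np.ndarray = DEFAULT_GRID) -> np.ndarray:
    """Fixed smooth bare-soil reflectance baseline on ``grid``."""
    lam = np.asarray(grid, dtype=float)
    step = 1.0 / (1.0 + np.exp(-(lam - _SOIL_STEP_CENTER) / _SOIL_STEP_WIDTH))
    return _SOIL_BASE + _SOIL_STEP * step + _SOIL_SLOPE * (lam - lam[0]) / (lam[-1] - lam[0])


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def spectral_forward_model(
    lai: float,
    chlorophyll: float,
    water: float,
    senescence: float,
    grid: np.ndarray = DEFAULT_GRID,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    pure_leaf: bool = False,
    **meta,
) -> SpectralRecord:
    """Forward-model one reflectance spectrum from latent canopy traits.

    Parameters
    ----------
    lai : leaf area index, 0–8; sets the vegetation cover fraction
        f = 1 − exp(−0.5·LAI) of the soil/vegetation mixture.
    chlorophyll : SPAD-like chlorophyll index, 0–60; deepens the 430/680 nm
        absorptions and darkens the visible plateau (saturating).
    water : canopy water status, 0–1; deepens the 970/1240/1450/1940 nm
        absorptions.
    senescence : 0 (green) – 1 (fully senesced); retreats the red edge,
        yellows the visible and bleaches chlorophyll absorption.
    noise_sd : additive Gaussian band noise (reflectance units).
    pure_leaf : skip the soil mixture (leaf-clip geometry).
    """
    lam = np.asarray(grid, dtype=float)
    chl_eff = max(chlorophyll * (1.0 - 0.7 * senescence), 0.0)
    chl_sat = chl_eff / (chl_eff + 25.0)  # saturating response

    red_edge = 718.0 - 25.0 * senescence
    plateau = 0.38 + 0.04 * min(lai, 6.0) / 6.0
    nir = plateau / (1.0 + np.exp(-(lam - red_edge) / 28.0))
    nir *= 1.0 - 0.30 / (1.0 + np.exp(-(lam - 1550.0) / 180.0))  # SWIR decline

    vis = 0.16 - 0.10 * chl_sat + 0.08 * senescence
    leaf = vis + nir
    leaf -= chl_sat * (0.045 * _gauss(lam, 430.0, 28.0) + 0.055 * _gauss(lam, 680.0, 22.0))
    leaf -= water * (
        0.08 * _gauss(lam, 970.0, 45.0)
        + 0.12 * _gauss(lam, 1240.0, 60.0)
        + 0.32 * _gauss(lam, 1450.0, 80.0)
        + 0.28 * _gauss(lam, 1940.0, 90.0)
    )
    leaf = np.clip(leaf, 0.02, 0.95)

    if pure_leaf:
        refl = leaf
    else:
        f_veg = 1.0 - np.exp(-0.5 * max(lai, 0.0))
        refl = f_veg * leaf + (1.0 - f_veg) * soil_spectrum(lam)

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        refl = refl + rng.normal(0.0, noise_sd, size=lam.size)
    refl = np.clip(refl, 0.0, 1.0)
    meta.setdefault("plot_id", "synthetic")
    return SpectralRecord(wavelengths=lam, reflectance=refl, **meta)


@dataclass
class TrialConfig:
    """Study conditions of one synthetic trial.

    Defaults mirror the field design the package targets: 11 genotypes,
    3 replicates, stage days E40 = 40, booting = 61, anthesis + 7 d = 83,
    maturity = 116 days after emergence; genotype-mean RUE centred on
    2.03 g MJ⁻¹ (E40→booting), 2.69 (booting→A7) and 1.23 (grain filling);
    1% reflectance noise, 5% biomass CV and 1.5 LI-percentage-point noise.
    """

    n_genotypes: int = 11
    n_replicates: int = 3
    n_years: int = 1
    stage_days: dict[str, int] = field(
        default_factory=lambda: {"E40": 40, "InB": 61, "A7": 83, "PM": 116}
    )
    rue_mean: dict[str, float] = field(
        default_factory=lambda: {"E40InB": 2.03, "InBA7": 2.69, "GF": 1.23}
    )
    rue_sd: dict[str, float] = field(
        default_factory=lambda: {"E40InB": 0.20, "InBA7": 0.22, "GF": 0.18}
    )
    bm_e40_mean: float = 201.6  # g m⁻²
    noise: dict[str, float] = field(
        default_factory=lambda: {"reflectance_sd": 0.01, "biomass_cv": 0.05, "li_sd": 1.5}
    )
    seed: int = 0
    include_spectra: bool = True
    include_leaf_layers: bool = True
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy(), repr=False)

    def __post_init__(self) -> None:
        days = [self.stage_days[s] for s in growth.STAGES]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"stage_days must be strictly increasing, got {self.stage_days}")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise terms must be >= 0")
        if self.n_genotypes < 1 or self.n_replicates < 1 or self.n_years < 1:
            raise ValueError("design sizes must be >= 1")


@dataclass
class SyntheticTrial:
    """One simulated trial plus its generating truth."""

    config: TrialConfig
    trait_table: pd.DataFrame
    spectra: SpectralSet
    harvests: list[HarvestRecord]
    light: list[LightReading]
    met: pd.DataFrame
    truth: dict

    def met_par(self) -> pd.Series:
        """Daily PAR series (MJ m⁻² d⁻¹) indexed by day after emergence."""
        s = self.met.set_index("day")["solar_MJ"]
        return growth.par_from_irradiance(s)


def _met_series(pm_day: int) -> pd.DataFrame:
    """Deterministic smooth seasonal irradiance, MJ m⁻² d⁻¹."""
    days = np.arange(1, pm_day + 1)
    solar = 17.0 + 7.0 * np.sin(np.pi * days / (1.35 * pm_day))
    return pd.DataFrame({"day": days, "solar_MJ": solar})


def _lai_curve(days: np.ndarray, plateau: float, a7: int, pm: int, staygreen: float) -> np.ndarray:
    """Logistic canopy build-up, then senescent decline after A7."""
    rise = plateau / (1.0 + np.exp(-(days - 28.0) / 7.0))
    lai = rise.copy()
    after = days > a7
    # linear decline reaching a stay-green-dependent floor at maturity
    frac = (days[after] - a7) / max(pm - a7, 1)
    floor = 0.15 + 0.45 * staygreen
    lai[after] = rise[after] * (1.0 - (1.0 - floor) * frac)
    return lai


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def simulate_trial(config: TrialConfig | None = None) -> SyntheticTrial:
    """Generate a full synthetic trial under ``config`` (deterministic in seed)."""
    c = config or TrialConfig()
    rng = np.random.default_rng(c.seed)
    sd = c.stage_days
    met = _met_series(sd["PM"])
    days = met["day"].to_numpy(dtype=float)
    par = met["solar_MJ"].to_numpy() * growth.PAR_FRACTION

    # --- genotype-level truth -------------------------------------------------
    nG = c.n_genotypes
    rue_e40inb = c.rue_mean["E40InB"] + c.rue_sd["E40InB"] * rng.standard_normal(nG)
    rue_inba7 = c.rue_mean["InBA7"] + c.rue_sd["InBA7"] * rng.standard_normal(nG)
    rue_gf = c.rue_mean["GF"] + c.rue_sd["GF"] * rng.standard_normal(nG)
    rue_e40inb = np.clip(rue_e40inb, 0.5, None)
    rue_inba7 = np.clip(rue_inba7, 0.5, None)
    rue_gf = np.clip(rue_gf, 0.3, None)

    z_veg = _standardize(0.4 * rue_e40inb + 0.6 * rue_inba7)
    z_gf = _standardize(rue_gf)
    lai_plateau = 5.5 + 0.6 * z_veg
    chl_g = 45.0 + 4.0 * z_veg
    water_g = np.clip(0.50 + 0.12 * z_veg, 0.15, 0.85)
    staygreen_g = np.clip(0.5 + 0.35 * np.tanh(z_gf), 0.05, 0.95)

    genotypes = [f"G{i + 1:02d}" for i in range(nG)]
    bm_cv = c.noise["biomass_cv"]
    li_sd = c.noise["li_sd"]
    refl_sd = c.noise["reflectance_sd"]

    rows = []
    harvests: list[HarvestRecord] = []
    light: list[LightReading] = []
    spectra_records: list[SpectralRecord] = []
    truth_geno: dict[str, dict] = {}

    area_by_stage = {"E40": 0.4, "InB": 0.8, "A7": 0.8, "PM": 0.8}
    dm_ratio = {"E40": 0.18, "InB": 0.22, "A7": 0.32, "PM": 0.85}
    # layer-specific chlorophyll gradient down the canopy
    layer_chl_scale = {"flag_leaf": 1.0, "second_leaf": 0.9, "third_leaf": 0.78}

    for year in range(1, c.n_years + 1):
        # additive replicate (block) effects on measured biomass, scaled so the
        # noise-free trial stays exact
        rep_effect = rng.normal(0.0, 1.5 * bm_cv * c.bm_e40_mean, size=c.n_replicates)
        for gi, g in enumerate(genotypes):
            for rep in range(1, c.n_replicates + 1):
                plot = f"{g}_r{rep}_y{year}"
                # plot-level jitter on the latent traits (zero if noise off)
                jit = rng.normal(0.0, 1.0, size=4)
                lai_p = max(lai_plateau[gi] + 0.3 * bm_cv / 0.05 * jit[0] * (bm_cv > 0), 1.0)
                chl_p = max(chl_g[gi] + 2.0 * jit[1] * (refl_sd > 0), 5.0)
                water_p = float(np.clip(water_g[gi] + 0.03 * jit[2] * (refl_sd > 0), 0.1, 0.9))
                sg_p = float(np.clip(staygreen_g[gi] + 0.05 * jit[3] * (refl_sd > 0), 0.02, 0.98))

                # --- daily light interception and IPAR -----------------------
                lai_t = _lai_curve(days, lai_p, sd["A7"], sd["PM"], sg_p)
                li_t = 100.0 * (1.0 - np.exp(-0.5 * lai_t))
                daily_ipar = par * li_t / 100.0
                cum = np.cumsum(daily_ipar)
                ipar = {s: float(cum[int(sd[s]) - 1]) for s in growth.STAGES}
                a7, pm = sd["A7"], sd["PM"]
                split = a7 + 0.75 * (pm - a7)
                in75 = (days > a7) & (days <= split)
                in25 = (days > split) & (days <= pm)
                gf = GrainFillPAR(
                    mj_acc_75=float(daily_ipar[in75].sum()),
                    mj_acc_25=float(daily_ipar[in25].sum()),
                )

                # --- true biomass trajectory (construction identity) ---------
                bm = {"E40": c.bm_e40_mean * (1.0 + 0.05 * jit[0] * (bm_cv > 0))}
                bm["InB"] = bm["E40"] + rue_e40inb[gi] * (ipar["InB"] - ipar["E40"])
                bm["A7"] = bm["InB"] + rue_inba7[gi] * (ipar["A7"] - ipar["InB"])
                bm["PM"] = bm["A7"] + rue_gf[gi] * gf.effective

                # measured biomass: multiplicative noise + block effect
                bm_meas = {
                    s: bm[s] * (1.0 + bm_cv * rng.standard_normal())
                    + (rep_effect[rep - 1] if bm_cv > 0 else 0.0)
                    for s in growth.STAGES
                }

                for s in growth.STAGES:
                    ratio = dm_ratio[s]
                    area = area_by_stage[s]
                    sub_fw = 150.0
                    harvests.append(
                        HarvestRecord(
                            total_FW=bm_meas[s] * area / ratio,
                            subsample_FW=sub_fw,
                            subsample_DW=ratio * sub_fw,
                            harvested_area=area,
                            stage=s,
                            plot_id=plot,
                        )
                    )

                # --- ceptometer readings at the three LI stages ---------------
                for s in ("E40", "InB", "A7"):
                    li_true = li_t[int(sd[s]) - 1]
                    li_obs = float(np.clip(li_true + li_sd * rng.standard_normal(), 0.0, 99.9))
                    par_i, par_r = 2000.0, 100.0
                    par_g = (par_i - par_r) * (1.0 - li_obs / 100.0)
                    light.append(
                        LightReading(PAR_i=par_i, PAR_r=par_r, PAR_g=par_g, stage_tag=s, plot_id=plot)
                    )

                # --- spectra ---------------------------------------------------
                ndvigs = {}
                if c.include_spectra:
                    latents = {
                        "vegetative": dict(
                            lai=lai_p, chlorophyll=chl_p, water=water_p, senescence=0.05
                        ),
                        "grain_filling": dict(
                            lai=lai_p * (0.35 + 0.5 * sg_p),
                            chlorophyll=chl_p * (0.45 + 0.5 * sg_p),
                            water=water_p * (0.55 + 0.35 * sg_p),
                            senescence=1.0 - sg_p,
                        ),
                    }
                    for period, lat in latents.items():
                        rec = spectral_forward_model(
                            grid=c.grid,
                            rng=rng,
                            noise_sd=refl_sd,
                            plot_id=plot,
                            genotype_id=g,
                            layer="canopy",
                            period=period,
                            **lat,
                        )
                        spectra_records.append(rec)
                        # Green Seeker NDVI reads the same canopy
                        from .vegindex import compute_index

                        ndvigs[period] = compute_index(rec, "NDVI")
                        if c.include_leaf_layers:
                            for layer, scale in layer_chl_scale.items():
                                spectra_records.append(
                                    spectral_forward_model(
                                        grid=c.grid,
                                        rng=rng,
                                        noise_sd=refl_sd,
                                        plot_id=plot,
                                        genotype_id=g,
                                        layer=layer,
                                        period=period,
                                        pure_leaf=True,
                                        lai=lat["lai"],
                                        chlorophyll=lat["chlorophyll"] * scale,
                                        water=lat["water"],
                                        senescence=lat["senescence"],
                                    )
                                )

                # --- scalar sensor columns ------------------------------------
                spad_base = chl_p + (1.2 * rng.standard_normal() if refl_sd > 0 else 0.0)
                ct_vg = 27.0 - 4.0 * water_p + (0.4 * rng.standard_normal() if refl_sd > 0 else 0.0)
                ct_gf = 30.0 - 3.0 * water_p * sg_p + (
                    0.4 * rng.standard_normal() if refl_sd > 0 else 0.0
                )
                jmax = 90.0 + 1.8 * (chl_p - 45.0) + (3.0 * rng.standard_normal() if refl_sd > 0 else 0.0)
                vcn = 0.55 + 0.01 * (chl_p - 45.0) + (0.02 * rng.standard_normal() if refl_sd > 0 else 0.0)

                row = {
                    "genotype_id": g,
                    "replicate_id": rep,
                    "year": year,
                    "plot_id": plot,
                    "BM_E40": bm_meas["E40"],
                    "BM_InB": bm_meas["InB"],
                    "BM_A7": bm_meas["A7"],
                    "BM_PM": bm_meas["PM"],
                    "IPAR_E40": ipar["E40"],
                    "IPAR_InB": ipar["InB"],
                    "IPAR_A7": ipar["A7"],
                    "IPAR_PM": ipar["PM"],
                    "GF_MJ75": gf.mj_acc_75,
                    "GF_MJ25": gf.mj_acc_25,
                    "CTvg": ct_vg,
                    "CTgf": ct_gf,
                    "SPADTLvg": spad_base * layer_chl_scale["third_leaf"],
                    "SPADFLvg": spad_base,
                    "JmaxTLvg": jmax * 0.85,
                    "JmaxFLgf": jmax * (0.5 + 0.45 * sg_p),
                    "VcmaxNareaSLvg": vcn * 100.0,
                }
                if ndvigs:
                    row["NDVIGSvg"] = ndvigs.get("vegetative", np.nan)
                    row["NDVIGSgf"] = ndvigs.get("grain_filling", np.nan)
                rows.append(row)

            if g not in truth_geno:
                # noise-free per-window truth from the genotype means of the
                # construction (exact for every plot when noise is off)
                truth_geno[g] = {
                    "rue_E40InB": float(rue_e40inb[gi]),
                    "rue_InBA7": float(rue_inba7[gi]),
                    "rue_GF": float(rue_gf[gi]),
                    "lai_plateau": float(lai_plateau[gi]),
                    "chlorophyll": float(chl_g[gi]),
                    "water": float(water_g[gi]),
                    "staygreen": float(staygreen_g[gi]),
                }

    trait_table = pd.DataFrame(rows)

    # derived per-plot RUE ground truth columns (as the growth module computes them)
    trait_table["RUE_E40InB"] = (trait_table["BM_InB"] - trait_table["BM_E40"]) / (
        trait_table["IPAR_InB"] - trait_table["IPAR_E40"]
    )
    trait_table["RUE_InBA7"] = (trait_table["BM_A7"] - trait_table["BM_InB"]) / (
        trait_table["IPAR_A7"] - trait_table["IPAR_InB"]
    )
    trait_table["RUE_preGF"] = (trait_table["BM_A7"] - trait_table["BM_E40"]) / (
        trait_table["IPAR_A7"] - trait_table["IPAR_E40"]
    )
    gf_eff = trait_table["GF_MJ75"] + 0.5 * trait_table["GF_MJ25"]
    trait_table["RUE_GF"] = (trait_table["BM_PM"] - trait_table["BM_A7"]) / gf_eff
    trait_table["RUE_Total"] = (trait_table["BM_PM"] - trait_table["BM_E40"]) / (
        trait_table["IPAR_A7"] + gf_eff - trait_table["IPAR_E40"]
    )

    spectra = SpectralSet(spectra_records)
    spectra.log(
        f"simulate_trial(seed={c.seed}): {len(spectra_records)} record(s), "
        f"{nG} genotype(s) x {c.n_replicates} rep(s) x {c.n_years} year(s)"
    )
    truth = {
        "genotypes": truth_geno,
        "stage_days": dict(sd),
        "seed": c.seed,
    }
    return SyntheticTrial(
        config=c,
        trait_table=trait_table,
        spectra=spectra,
        harvests=harvests,
        light=light,
        met=met,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Packaged genotype-mean fixture: 11 genotypes, phenology, IPAR (MJ m⁻²),
# biomass (g m⁻²) and RUE (g MJ⁻¹) at the growth stages.
# --------------------------------------------------------------------------

_TABLE1_CSV = """\
genotype_id,cross_name,DTInB,DTA,DTPM,IPAR_E40,IPAR_InB,IPAR_A7,IPAR_PM,BM_E40,BM_InB,BM_A7,BM_PM,RUE_E40InB,RUE_InBA7,RUE_preGF,RUE_GF,RUE_Total
1,KRICHAUFF,60,77,119,224.39,365.82,543.27,833.56,188.47,466.32,978.38,1348.94,1.75,2.91,2.33,1.21,1.61
2,W15.92/4/PASTOR//HXL7573/2*BAU/3/WBLL1,59,74,113,230.22,359.2,524.44,762.38,217.14,515.19,905.55,1210.31,2.21,2.3,2.11,1.26,1.55
3,KUKRI,64,79,117,232.446,405.17,575.98,836.45,196.14,569.52,1075.3,1319.4,2.06,3.08,2.52,1.04,1.62
4,MUNAL #1,65,80,116,226.94,406.3,565.17,804.02,199.21,558.62,998.14,1235.51,1.87,2.8,2.27,0.85,1.51
5,JANZ,60,73,116,229,371.49,534.41,822.75,190.05,497.99,893.31,1260.97,2.08,2.39,2.21,1.41,1.57
6,CHEWINK #1,62,80,118,233.53,385.28,567.81,843.43,186.36,517.53,994.67,1319.23,2.02,2.57,2.32,1.12,1.62
7,SOKOLL//PUB94.15.1.12/WBLL1,60,75,116,232.73,375.19,551.88,833.83,211.96,495.62,943.88,1390.22,1.92,2.58,2.28,1.55,1.77
8,PUB94.15.1.12/FRTL/5/CROC_1/AE.SQUARROSA(205)//BORL95/3/PRL/SARA//TSI/VEE#5/4/FRET2,59,74,116,230.92,368.04,538.45,824.21,214.35,551.04,1027.9,1445.18,2.26,2.71,2.56,1.43,1.8
9,C80.1/3*QT4118//KAUZ/RAYON/3/2*TRCH/7/CMH79A.955/4/AGA/3/4*SN64/CNO67//INIA66/5/NAC/6/RIALTO/8/WBLL1*2/KURUKU,64,80,120,230.75,409,576.06,870.62,205.15,607.09,1127.2,1416.93,2.11,2.77,2.55,1.15,1.68
10,QUAIU*2/KINDE,58,74,114,223.5,346.8,522.34,759.87,206.70,517.04,987.58,1345.11,2.35,2.59,2.44,1.37,1.72
11,BORLAUG100 F2014,59,74,115,228,357.51,525.58,791.4,202.45,444.28,953.7,1259.33,1.65,2.86,2.35,1.19,1.57
"""


def fixtures_table1() -> pd.DataFrame:
    """Genotype-mean reference fixture (11 genotypes × 16 numeric columns).

    Phenology in days after emergence, IPAR in MJ m⁻², biomass in g m⁻² and
    RUE in g MJ⁻¹ at the four harvest stages / five growth windows.
    """
    df = pd.read_csv(io.StringIO(_TABLE1_CSV))
    return df.set_index("genotype_id")
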