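"""Registry and evaluator for canopy/leaf vegetation indices.

Each index is a fixed scalar combination of reflectances at specific
wavelengths (R_λ, reflectance fraction at λ nm).  The registry holds the 27
spectral-formula indices used to predict radiation use efficiency, biomass and
intercepted PAR; non-spectral sensor traits (canopy temperature, SPAD,
Green Seeker NDVI, PLSR-derived J_max and V_cmax/N_area) are plain input
columns and are not registered here.

Bands are resolved by nearest-neighbour lookup on the record grid with a
3 nm tolerance (the instrument's VNIR resolution); ties break toward the
higher wavelength.  Division by zero or an unresolvable band yields a missing
value (NaN), never a silent zero.

Notes on typographically ambiguous formulas
-------------------------------------------
* GNDVI-1 is (R810 − m)/(R810 + m) with m = (R510 + R561)/2.
* SAVI uses the printed soil factor L = 0.75 (the common literature value is
  0.5): ((R800 − R680)/(R800 + R680 + L)) · (1 + L).
* TCARI binds the (R700/R670) ratio to the 0.2 term:
  3[(R700 − R670) − 0.2(R700 − R550)(R700/R670)]; likewise TCARI_705,750.
* SIPI-2 is implemented exactly as printed, (R800 − R435)/(R415 − R435);
  note it is a homogeneous ratio and therefore scale-invariant.
* RARSb = R675/(R650·R700) carries units of 1/reflectance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import SpectralRecord, SpectralSet, WAVELENGTH_MIN, WAVELENGTH_MAX

__all__ = [
    "IndexDefinition",
    "band",
    "compute_index",
    "compute_panel",
    "list_registry",
    "REGISTRY",
    "BAND_TOLERANCE_NM",
]

BAND_TOLERANCE_NM = 3.0


def band(record: SpectralRecord, lam: float, tolerance: float = BAND_TOLERANCE_NM) -> float:
    """Reflectance at the grid point nearest ``lam`` (nm).

    Returns NaN when the nearest grid point is farther than ``tolerance`` or
    its reflectance is masked.  Ties between two equally near grid points
    break toward the higher wavelength.
    """
    if not (WAVELENGTH_MIN <= lam <= WAVELENGTH_MAX):
        raise ValueError(f"wavelength {lam:g} nm outside [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}]")
    wl = record.wavelengths
    i = int(np.searchsorted(wl, lam))
    candidates = [j for j in (i - 1, i) if 0 <= j < wl.size]
    # prefer the higher wavelength on exact ties
    best = min(candidates, key=lambda j: (abs(wl[j] - lam), -wl[j]))
    if abs(wl[best] - lam) > tolerance:
        return math.nan
    return float(record.reflectance[best])


@dataclass(frozen=True)
class IndexDefinition:
    """A named vegetation index: formula text, band list, and evaluator."""

    name: str
    formula: str
    bands: tuple[float, ...]
    func: Callable[..., float]
    reference_tag: str = ""

    def evaluate(self, record: SpectralRecord, tolerance: float = BAND_TOLERANCE_NM) -> float:
        vals = [band(record, lam, tolerance) for lam in self.bands]
        if any(math.isnan(v) for v in vals):
            return math.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            try:
                out = self.func(*vals)
            except ZeroDivisionError:
                return math.nan
        if out is None or not math.isfinite(out):
            return math.nan
        return float(out)


def _defs() -> list[IndexDefinition]:
    D = IndexDefinition
    return [
        D("CRI", "(1/R510) - (1/R550)", (510, 550),
          lambda r510, r550: 1.0 / r510 - 1.0 / r550, "carotenoid content"),
        D("CUR", "(R675*R690)/R683^2", (675, 690, 683),
          lambda r675, r690, r683: (r675 * r690) / r683**2, "chlorophyll fluorescence"),
        D("EVI", "2.5*(R900 - R680)/(R900 + 6*R680 - 7.5*R475 + 1)", (900, 680, 475),
          lambda r900, r680, r475: 2.5 * (r900 - r680) / (r900 + 6.0 * r680 - 7.5 * r475 + 1.0),
          "canopy greenness, saturation-resistant"),
        D("GI", "R554/R677", (554, 677),
          lambda r554, r677: r554 / r677, "canopy greenness"),
        D("GNDVI-1", "(R810 - m)/(R810 + m), m=(R510 + R561)/2", (810, 510, 561),
          lambda r810, r510, r561: (r810 - (r510 + r561) / 2.0) / (r810 + (r510 + r561) / 2.0),
          "green normalized difference"),
        D("NDVI", "(R800 - R680)/(R800 + R680)", (800, 680),
          lambda r800, r680: (r800 - r680) / (r800 + r680), "canopy greenness"),
        D("NDWI", "(R860 - R1240)/(R860 + R1240)", (860, 1240),
          lambda r860, r1240: (r860 - r1240) / (r860 + r1240), "canopy water"),
        D("NDWI-2", "(R970 - R850)/(R970 + R850)", (970, 850),
          lambda r970, r850: (r970 - r850) / (r970 + r850), "canopy water"),
        D("NDWI-3", "(R970 - R920)/(R970 + R920)", (970, 920),
          lambda r970, r920: (r970 - r920) / (r970 + r920), "canopy water"),
        D("NDWI-4", "(R970 - R880)/(R970 + R880)", (970, 880),
          lambda r970, r880: (r970 - r880) / (r970 + r880), "canopy water"),
        D("NPCI", "(R680 - R430)/(R680 + R430)", (680, 430),
          lambda r680, r430: (r680 - r430) / (r680 + r430), "pigment/chlorophyll ratio"),
        D("OSAVI", "(1 + 0.16)*(R800 - R670)/(R800 + R670 + 0.16)", (800, 670),
          lambda r800, r670: 1.16 * (r800 - r670) / (r800 + r670 + 0.16),
          "soil-adjusted greenness"),
        D("PRI", "(R531 - R570)/(R531 + R570)", (531, 570),
          lambda r531, r570: (r531 - r570) / (r531 + r570), "xanthophyll cycle / NPQ"),
        D("PSSRa", "R800/R675", (800, 675),
          lambda r800, r675: r800 / r675, "chlorophyll a"),
        D("PSSRb", "R800/R650", (800, 650),
          lambda r800, r650: r800 / r650, "chlorophyll b"),
        D("RARSa", "R675/R700", (675, 700),
          lambda r675, r700: r675 / r700, "chlorophyll a"),
        D("RARSb", "R675/(R650*R700)", (675, 650, 700),
          lambda r675, r650, r700: r675 / (r650 * r700), "chlorophyll b (1/reflectance units)"),
        D("RGR", "(R612 + R660)/(R510 + R560)", (612, 660, 510, 560),
          lambda r612, r660, r510, r560: (r612 + r660) / (r510 + r560), "red/green pigments"),
        D("rNDVI", "(R750 - R705)/(R750 + R705)", (750, 705),
          lambda r750, r705: (r750 - r705) / (r750 + r705), "red-edge greenness"),
        D("SAVI", "((R800 - R680)/(R800 + R680 + 0.75))*(1 + 0.75)", (800, 680),
          lambda r800, r680: (r800 - r680) / (r800 + r680 + 0.75) * 1.75,
          "soil-adjusted greenness, L=0.75"),
        D("SIPI-1", "(R800 - R445)/(R800 - R680)", (800, 445, 680),
          lambda r800, r445, r680: (r800 - r445) / (r800 - r680), "senescence / carotenoid:chlorophyll"),
        D("SIPI-2", "(R800 - R435)/(R415 - R435)", (800, 435, 415),
          lambda r800, r435, r415: (r800 - r435) / (r415 - r435), "senescence (as printed)"),
        D("SR-1", "R800/R680", (800, 680),
          lambda r800, r680: r800 / r680, "simple ratio greenness"),
        D("TCARI", "3*((R700 - R670) - 0.2*(R700 - R550)*(R700/R670))", (700, 670, 550),
          lambda r700, r670, r550: 3.0 * ((r700 - r670) - 0.2 * (r700 - r550) * (r700 / r670)),
          "chlorophyll absorption"),
        D("TCARI_705,750", "3*((R750 - R705) - 0.2*(R750 - R550)*(R750/R705))", (750, 705, 550),
          lambda r750, r705, r550: 3.0 * ((r750 - r705) - 0.2 * (r750 - r550) * (r750 / r705)),
          "chlorophyll absorption, red-edge bands"),
        D("VARI", "(R560 - R660)/(R560 + R660 - R459)", (560, 660, 459),
          lambda r560, r660, r459: (r560 - r660) / (r560 + r660 - r459), "canopy coverage"),
        D("WI", "R900/R970", (900, 970),
          lambda r900, r970: r900 / r970, "canopy water"),
    ]


REGISTRY: dict[str, IndexDefinition] = {d.name: d for d in _defs()}

#: Indices that are homogeneous ratios of reflectances (scale-invariant).
SCALE_INVARIANT = (
    "NDVI", "WI", "SR-1", "GI", "PSSRa", "PSSRb", "RARSa", "RGR", "VARI", "CUR",
    "PRI", "NPCI", "rNDVI", "NDWI", "NDWI-2", "NDWI-3", "NDWI-4", "GNDVI-1",
    "SIPI-1", "SIPI-2",
)

#: Normalized-difference indices bounded in [-1, 1] for reflectance in (0, 1].
NORMALIZED_DIFFERENCE = (
    "NDVI", "rNDVI", "NDWI", "NDWI-2", "NDWI-3", "NDWI-4", "PRI", "NPCI", "GNDVI-1",
)


def list_registry() -> list[IndexDefinition]:
    """All registered spectral index definitions (27 Table-style formulas)."""
    return list(REGISTRY.values())


def compute_index(
    record: SpectralRecord, name: str, tolerance: float = BAND_TOLERANCE_NM
) -> float:
    """Evaluate one registered index on a spectrum; NaN when unresolvable."""
    try:
        definition = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; registered: {sorted(REGISTRY)}"
        ) from None
    return definition.evaluate(record, tolerance)


def compute_panel(
    s: SpectralSet,
    names: Sequence[str] | None = None,
    tolerance: float = BAND_TOLERANCE_NM,
) -> pd.DataFrame:
    """Evaluate indices for every record: one row per record, one column per index."""
    if names is None:
        names = list(REGISTRY)
    unknown = [n for n in names if n not in REGISTRY]
    if unknown:
        raise KeyError(f"unknown index name(s) {unknown}; registered: {sorted(REGISTRY)}")
    rows = []
    for r in s.records:
        row: dict[str, object] = {
            "plot_id": r.plot_id,
            "genotype_id": r.genotype_id,
            "layer": r.layer,
            "period": r.period,
        }
        for n in names:
            row[n] = compute_index(r, n, tolerance)
        rows.append(row)
    return pd.DataFrame(rows, columns=["plot_id", "genotype_id", "layer", "period", *names])
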