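"""Reading, cleaning, windowing and averaging of field reflectance spectra.

Canopy spectra are collected with a field spectroradiometer (350–2500 nm,
3 nm resolution in the VNIR and 10 nm in the SWIR); leaf spectra come from a
leaf clip at the flag, second and third leaves.  All records are resampled to
a common 1 nm grid on read so that downstream vegetation-index lookups and
PLSR band matrices are rectangular.

Reflectance is stored as a unitless fraction in [0, 1]; values outside that
range are instrument artefacts (mostly in the atmospheric water-vapour bands)
and are clipped or masked by :func:`clean_spurious`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralRecord",
    "SpectralSet",
    "read_spectra",
    "write_spectra",
    "clean_spurious",
    "select_windows",
    "average_replicates",
    "average_period",
    "DEFAULT_WINDOWS",
    "WAVELENGTH_MIN",
    "WAVELENGTH_MAX",
]

WAVELENGTH_MIN = 350.0
WAVELENGTH_MAX = 2500.0

#: PLSR pre-processing windows: the 1801–1950 nm atmospheric water-vapour
#: band is excluded, as is the noisy tail above 2450 nm.
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((350.0, 1800.0), (1951.0, 2450.0))

LAYERS = ("canopy", "flag_leaf", "second_leaf", "third_leaf")
PERIODS = ("vegetative", "grain_filling", "unassigned")


class SpectraFormatError(ValueError):
    """Raised when an input file does not match the expected tabular layout."""


class SpectraValidationError(ValueError):
    """Raised when spectra violate a structural invariant (grid, range, duplicates)."""


@dataclass(frozen=True)
class SpectralRecord:
    """A single reflectance spectrum with plot / layer / stage metadata."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    plot_id: str
    genotype_id: str = ""
    layer: str = "canopy"
    stage_tag: str = ""
    period: str = "unassigned"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.shape != rf.shape or wl.ndim != 1:
            raise SpectraValidationError(
                f"wavelength/reflectance shape mismatch for plot {self.plot_id!r}"
            )
        if wl.size == 0:
            raise SpectraValidationError(f"empty spectrum for plot {self.plot_id!r}")
        if np.any(np.diff(wl) <= 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0]) + 1
            raise SpectraValidationError(
                f"wavelengths not strictly increasing for plot {self.plot_id!r} "
                f"at position {bad} ({wl[bad]} nm)"
            )
        if wl[0] < WAVELENGTH_MIN - 1e-9 or wl[-1] > WAVELENGTH_MAX + 1e-9:
            raise SpectraValidationError(
                f"wavelengths outside [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm "
                f"for plot {self.plot_id!r}"
            )
        if self.layer not in LAYERS:
            raise SpectraValidationError(f"unknown layer {self.layer!r}")
        if self.period not in PERIODS:
            raise SpectraValidationError(f"unknown period {self.period!r}")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths.size)

    def key(self) -> tuple[str, str, str, str]:
        return (self.plot_id, self.genotype_id, self.layer, self.stage_tag)


@dataclass
class SpectralSet:
    """A collection of :class:`SpectralRecord` sharing a wavelength grid."""

    records: list[SpectralRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def with_records(self, records: Iterable[SpectralRecord], message: str) -> "SpectralSet":
        out = SpectralSet(list(records), list(self.provenance))
        out.log(message)
        return out

    def grid(self) -> np.ndarray:
        """Common wavelength grid; raises if records disagree."""
        if not self.records:
            raise SpectraValidationError("empty SpectralSet has no grid")
        g = self.records[0].wavelengths
        for r in self.records[1:]:
            if r.n_bands != g.size or not np.allclose(r.wavelengths, g):
                raise SpectraValidationError("records do not share a wavelength grid")
        return g

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_records × n_bands) reflectance matrix and the shared grid."""
        g = self.grid()
        X = np.vstack([r.reflectance for r in self.records])
        return X, g

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per record × band)."""
        frames = []
        for r in self.records:
            frames.append(
                pd.DataFrame(
                    {
                        "plot_id": r.plot_id,
                        "genotype_id": r.genotype_id,
                        "layer": r.layer,
                        "stage_tag": r.stage_tag,
                        "period": r.period,
                        "wavelength_nm": r.wavelengths,
                        "reflectance": r.reflectance,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _resample_1nm(wl: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation onto the integer-nm grid spanned by the input."""
    lo = int(np.ceil(wl[0]))
    hi = int(np.floor(wl[-1]))
    grid = np.arange(lo, hi + 1, dtype=float)
    return grid, np.interp(grid, wl, rf)


def read_spectra(path, layout: str = "long", resample: bool = True) -> SpectralSet:
    """Read reflectance spectra from a CSV file.

    Parameters
    ----------
    path : str or file-like
        CSV file.  ``layout="long"`` expects columns
        (plot_id[, genotype_id, layer, stage_tag], wavelength_nm, reflectance);
        ``layout="wide"`` expects metadata columns followed by one column per
        band whose header is the wavelength in nm.
    layout : {"long", "wide"}
    resample : bool
        Resample each record to a 1 nm grid by linear interpolation
        (mixed 3 nm VNIR / 10 nm SWIR instrument grids become uniform).
    """
    df = pd.read_csv(path)
    records: list[SpectralRecord] = []
    if layout == "long":
        required = {"plot_id", "wavelength_nm", "reflectance"}
        missing = required - set(df.columns)
        if missing:
            raise SpectraFormatError(f"missing column(s): {sorted(missing)}")
        meta_cols = [
            c for c in ("plot_id", "genotype_id", "layer", "stage_tag", "period")
            if c in df.columns
        ]
        for key, grp in df.groupby(meta_cols, sort=True, dropna=False):
            if not isinstance(key, tuple):
                key = (key,)
            meta = {k: ("" if pd.isna(v) else str(v)) for k, v in zip(meta_cols, key)}
            wl = grp["wavelength_nm"].to_numpy(dtype=float)
            if pd.Index(wl).has_duplicates:
                dup = pd.Index(wl)[pd.Index(wl).duplicated()][0]
                raise SpectraValidationError(
                    f"duplicate wavelength {dup:g} nm for group {meta}"
                )
            order = np.argsort(wl)
            rf = grp["reflectance"].to_numpy(dtype=float)[order]
            wl = wl[order]
            if resample:
                wl, rf = _resample_1nm(wl, rf)
            records.append(
                SpectralRecord(
                    wavelengths=wl,
                    reflectance=rf,
                    plot_id=meta.get("plot_id", ""),
                    genotype_id=meta.get("genotype_id", ""),
                    layer=meta.get("layer") or "canopy",
                    stage_tag=meta.get("stage_tag", ""),
                    period=meta.get("period") or "unassigned",
                )
            )
    elif layout == "wide":
        band_cols, meta_cols = [], []
        for c in df.columns:
            try:
                float(c)
                band_cols.append(c)
            except ValueError:
                meta_cols.append(c)
        if not band_cols:
            raise SpectraFormatError("no numeric wavelength columns found in wide layout")
        if "plot_id" not in meta_cols:
            raise SpectraFormatError("missing column(s): ['plot_id']")
        wl = np.array([float(c) for c in band_cols])
        order = np.argsort(wl)
        wl_sorted = wl[order]
        if pd.Index(wl_sorted).has_duplicates:
            raise SpectraValidationError("duplicate wavelength columns in wide layout")
        def _meta(row, col, default=""):
            v = row.get(col, default)
            return default if pd.isna(v) else str(v)

        for _, row in df.iterrows():
            rf = row[band_cols].to_numpy(dtype=float)[order]
            w, r = (wl_sorted, rf)
            if resample:
                w, r = _resample_1nm(w, r)
            records.append(
                SpectralRecord(
                    wavelengths=w,
                    reflectance=r,
                    plot_id=str(row["plot_id"]),
                    genotype_id=_meta(row, "genotype_id"),
                    layer=_meta(row, "layer", "canopy") or "canopy",
                    stage_tag=_meta(row, "stage_tag"),
                    period=_meta(row, "period", "unassigned") or "unassigned",
                )
            )
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")

    s = SpectralSet(records)
    s.log(f"read {len(records)} record(s) from {getattr(path, 'name', path)} ({layout})")
    return s


def write_spectra(s: SpectralSet, path, layout: str = "long") -> None:
    """Write a SpectralSet back to CSV (inverse of :func:`read_spectra`)."""
    if layout == "long":
        s.to_frame().to_csv(path, index=False)
    elif layout == "wide":
        X, g = s.to_matrix()
        meta = pd.DataFrame(
            {
                "plot_id": [r.plot_id for r in s.records],
                "genotype_id": [r.genotype_id for r in s.records],
                "layer": [r.layer for r in s.records],
                "stage_tag": [r.stage_tag for r in s.records],
                "period": [r.period for r in s.records],
            }
        )
        bands = pd.DataFrame(X, columns=[f"{w:g}" for w in g])
        pd.concat([meta, bands], axis=1).to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def clean_spurious(s: SpectralSet, mode: str = "clip") -> SpectralSet:
    """Remove reflectance values outside [0, 1].

    ``mode="clip"`` saturates offending bands to the nearest bound (keeps the
    grid rectangular, the default for the PLSR path); ``mode="drop"`` masks
    them to NaN.  Records with more than half their bands spurious are flagged
    with a warning but retained.
    """
    if mode not in ("clip", "drop"):
        raise ValueError(f"mode must be 'clip' or 'drop', got {mode!r}")
    out, total = [], 0
    for r in s.records:
        rf = r.reflectance
        bad = (rf < 0.0) | (rf > 1.0)
        n_bad = int(np.count_nonzero(bad))
        total += n_bad
        if n_bad > 0.5 * rf.size:
            warnings.warn(
                f"record {r.key()} has {n_bad}/{rf.size} spurious bands",
                stacklevel=2,
            )
        if n_bad == 0:
            out.append(r)
            continue
        new = rf.copy()
        if mode == "clip":
            new = np.clip(new, 0.0, 1.0)
        else:
            new[bad] = np.nan
        out.append(replace(r, reflectance=new))
    return s.with_records(out, f"clean_spurious(mode={mode}): {total} band(s) affected")


def select_windows(
    s: SpectralSet, windows: Sequence[tuple[float, float]] = DEFAULT_WINDOWS
) -> SpectralSet:
    """Retain only bands inside the closed nm intervals ``windows``."""
    windows = sorted((float(a), float(b)) for a, b in windows)
    for (a, b) in windows:
        if a > b or a < WAVELENGTH_MIN or b > WAVELENGTH_MAX:
            raise ValueError(f"invalid window [{a:g}, {b:g}]")
    for (a0, b0), (a1, _) in zip(windows, windows[1:]):
        if a1 <= b0:
            raise ValueError("windows overlap")
    out = []
    for r in s.records:
        mask = np.zeros(r.n_bands, dtype=bool)
        for (a, b) in windows:
            mask |= (r.wavelengths >= a) & (r.wavelengths <= b)
        if not mask.any():
            raise SpectraValidationError(
                f"window selection leaves record {r.key()} empty"
            )
        out.append(
            replace(r, wavelengths=r.wavelengths[mask], reflectance=r.reflectance[mask])
        )
    return s.with_records(out, f"select_windows({windows})")


def average_replicates(
    s: SpectralSet, group_by: Sequence[str] = ("plot_id", "layer", "stage_tag")
) -> SpectralSet:
    """Per-band arithmetic mean over records sharing the ``group_by`` fields."""
    groups: dict[tuple, list[SpectralRecord]] = {}
    for r in s.records:
        key = tuple(getattr(r, f) for f in group_by)
        groups.setdefault(key, []).append(r)
    out = []
    for key, members in groups.items():
        g = members[0].wavelengths
        for m in members[1:]:
            if m.n_bands != g.size or not np.allclose(m.wavelengths, g):
                raise SpectraValidationError(
                    f"group {key} mixes wavelength grids; resample first"
                )
        mean_rf = np.mean([m.reflectance for m in members], axis=0)
        proto = members[0]
        meta = {
            f: (getattr(proto, f) if all(getattr(m, f) == getattr(proto, f) for m in members) else "")
            for f in ("plot_id", "genotype_id", "layer", "stage_tag", "period")
        }
        out.append(SpectralRecord(wavelengths=g.copy(), reflectance=mean_rf, **meta))
    return s.with_records(out, f"average_replicates(group_by={tuple(group_by)}): {len(out)} group(s)")


def average_period(
    s: SpectralSet,
    calendar: dict[str, str],
    on_missing: str = "skip",
) -> SpectralSet:
    """Average stage-tagged spectra into per-period representatives.

    ``calendar`` maps each stage_tag to "vegetative", "grain_filling" or
    "excluded".  Vegetative spans canopy closure (40 DAE) through GS55 and
    grain filling spans GS65 through GS75; dates strictly between the two are
    excluded.  Output has one record per (plot, genotype, layer, period).
    """
    if on_missing not in ("skip", "error"):
        raise ValueError("on_missing must be 'skip' or 'error'")
    groups: dict[tuple, list[SpectralRecord]] = {}
    skipped = 0
    for r in s.records:
        if r.stage_tag not in calendar:
            if on_missing == "error":
                raise SpectraValidationError(
                    f"stage_tag {r.stage_tag!r} has no calendar entry"
                )
            skipped += 1
            continue
        period = calendar[r.stage_tag]
        if period == "excluded":
            skipped += 1
            continue
        if period not in ("vegetative", "grain_filling"):
            raise ValueError(f"calendar value {period!r} invalid")
        key = (r.plot_id, r.genotype_id, r.layer, period)
        groups.setdefault(key, []).append(r)
    out = []
    for (plot, geno, layer, period), members in groups.items():
        g = members[0].wavelengths
        mean_rf = np.mean([m.reflectance for m in members], axis=0)
        out.append(
            SpectralRecord(
                wavelengths=g.copy(),
                reflectance=mean_rf,
                plot_id=plot,
                genotype_id=geno,
                layer=layer,
                stage_tag="",
                period=period,
            )
        )
    return s.with_records(
        out, f"average_period: {len(out)} record(s), {skipped} unassigned spectra skipped"
    )
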