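"""Melt-curve (quasi-digital HRM) input: calibration and normalization.

Each well of a melt assay reports zero or more secondary melt-peak
temperatures; each secondary peak marks one methylated DNA molecule whose
peak temperature encodes its methylation density.  This module calibrates
temperature to density against sequencing-confirmed patterns, quantizes
predictions onto the amplicon's density lattice, applies the
conversion-efficiency QC filter, and normalizes molecule counts to
epialleles per mL of plasma — emitting the same density tables the
classifier consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epidense.density import DensityTable

__all__ = [
    "MeltWell",
    "MeltWellSet",
    "SequencedPattern",
    "CalibrationModel",
    "conversion_efficiency_filter",
    "rank_match",
    "fit_temp_to_density",
    "temp_to_density",
    "quantize_density",
    "epialleles_per_ml",
    "well_set_to_density_table",
    "dreaming_mean_methylation_proxy",
    "read_melt_csv",
    "write_melt_csv",
]

#: CpG sites in the default 14-CpG amplicon; sets the density lattice.
DEFAULT_N_CPGS = 14


@dataclass(frozen=True)
class MeltWell:
    well_id: str
    peak_temps: tuple[float, ...] = ()   # secondary melt peaks, may be empty


@dataclass
class MeltWellSet:
    """All melt wells plus loading metadata for one plasma sample."""

    sample_id: str
    wells: list[MeltWell]
    genomic_equivalents_loaded: float
    total_genomic_equivalents: float
    plasma_volume_ml: float

    def __post_init__(self) -> None:
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma volume must be positive")
        if self.total_genomic_equivalents < 0:
            raise ValueError("total genomic equivalents must be non-negative")
        if (self.total_genomic_equivalents
                and self.genomic_equivalents_loaded > self.total_genomic_equivalents):
            raise ValueError("cannot load more genomic equivalents than measured")

    @property
    def peak_temps(self) -> list[float]:
        return [t for w in self.wells for t in w.peak_temps]

    @property
    def volume_assessed_ml(self) -> float:
        """Plasma volume effectively interrogated by the loaded aliquot."""
        if self.total_genomic_equivalents == 0:
            raise ValueError(
                f"sample {self.sample_id!r}: total genomic equivalents is "
                "zero; volume assessed undefined")
        return (self.genomic_equivalents_loaded
                / self.total_genomic_equivalents) * self.plasma_volume_ml


@dataclass(frozen=True)
class SequencedPattern:
    """A sequencing-confirmed epiallele pattern used for calibration."""

    density: float
    abundance: int
    conversion_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion efficiency must lie in [0, 1]")


@dataclass
class CalibrationModel:
    """Affine melt-temperature -> methylation-density map."""

    slope: float                      # density per degree C
    intercept: float                  # density at 0 degrees C
    n_cpgs: int = DEFAULT_N_CPGS
    r_squared: float | None = None
    residuals: np.ndarray | None = None
    slope_stderr: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive "
                             "(density increases with melt temperature)")

    def predict_raw(self, temp: float) -> float:
        """Unquantized prediction, clipped to [0, 1]."""
        return float(np.clip(self.slope * temp + self.intercept, 0.0, 1.0))

    def temp_for_density(self, density: float) -> float:
        """Inverse map: the melt temperature of a given density."""
        return (density - self.intercept) / self.slope


def conversion_efficiency_filter(
    patterns: Iterable[SequencedPattern], threshold: float = 0.95,
) -> list[SequencedPattern]:
    """Drop patterns below the bisulfite conversion-efficiency QC bar.

    The rule is strict at the boundary: a pattern at exactly the threshold
    is retained (only *less than* threshold is discarded).
    """
    return [p for p in patterns if p.conversion_efficiency >= threshold]


def rank_match(patterns: Sequence[SequencedPattern],
               peak_temps: Sequence[float]) -> list[tuple[float, float]]:
    """Pair sequenced densities with melt peaks by rank.

    Patterns are ordered by (density, abundance) descending; peak
    temperatures descending; the two lists are zipped positionally so the
    densest pattern takes the hottest peak.  Excess entries on either side
    are dropped with a warning.
    """
    ordered = sorted(patterns,
                     key=lambda p: (p.density, p.abundance), reverse=True)
    temps = sorted(peak_temps, reverse=True)
    k = min(len(ordered), len(temps))
    if len(ordered) != len(temps):
        warnings.warn(
            f"rank_match: {len(ordered)} patterns vs {len(temps)} peaks; "
            f"keeping the top {k} of each", stacklevel=2)
    return [(temps[i], ordered[i].density) for i in range(k)]


def fit_temp_to_density(pairs: Sequence[tuple[float, float]],
                        n_cpgs: int = DEFAULT_N_CPGS) -> CalibrationModel:
    """Ordinary least squares of density on melt temperature."""
    if len(pairs) < 2:
        raise ValueError("calibration needs at least 2 (temp, density) pairs")
    temps = np.array([t for t, _ in pairs], dtype=float)
    dens = np.array([d for _, d in pairs], dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("calibration needs at least 2 distinct temperatures")
    fit = stats.linregress(temps, dens)
    resid = dens - (fit.slope * temps + fit.intercept)
    return CalibrationModel(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            n_cpgs=n_cpgs,
                            r_squared=float(fit.rvalue ** 2),
                            residuals=resid,
                            slope_stderr=float(fit.stderr))


def quantize_density(raw: float, n_cpgs: int = DEFAULT_N_CPGS) -> Fraction:
    """Snap a density in [0, 1] to the nearest multiple of ``1/n_cpgs``.

    Half-way cases round up (toward the denser lattice point); the lattice
    has exactly ``n_cpgs + 1`` attainable values.
    """
    raw = min(max(float(raw), 0.0), 1.0)
    k = math.floor(raw * n_cpgs + 0.5)
    return Fraction(min(k, n_cpgs), n_cpgs)


def temp_to_density(model: CalibrationModel, temp: float) -> Fraction:
    """Convert one melt-peak temperature to a lattice density."""
    return quantize_density(model.predict_raw(temp), model.n_cpgs)


def epialleles_per_ml(counts, well_set: MeltWellSet):
    """Normalize molecule counts to epialleles per mL of plasma.

    The volume assessed is the loaded fraction of the total genomic
    equivalents times the starting plasma volume; counts (scalar or
    array-like) are divided by it.
    """
    vol = well_set.volume_assessed_ml
    arr = np.asarray(counts, dtype=float) / vol
    return float(arr) if arr.ndim == 0 else arr


def well_set_to_density_table(
    well_set: MeltWellSet,
    model: CalibrationModel,
    include_background: bool = True,
    occupancy_warn: float = 0.3,
    poisson_correct: bool = False,
) -> DensityTable:
    """Convert a sample's melt wells into a density table.

    Each secondary melt peak contributes one methylated molecule at the
    temperature's quantized density.  With ``include_background``, the
    remaining loaded genomic equivalents appear as fully unmethylated
    molecules so fraction-type measures are meaningful.

    The one-molecule-per-peak reading assumes dilute (Poissonian, at most
    one methylated molecule per well) loading; a warning is emitted when
    the implied occupancy exceeds ``occupancy_warn``.  ``poisson_correct``
    (an extension, off by default) replaces the raw peak count with the
    Poisson estimate ``-n_wells * ln(fraction of peak-free wells)``.
    """
    n = model.n_cpgs
    n_wells = len(well_set.wells)
    peak_densities = [temp_to_density(model, t) for t in well_set.peak_temps]
    n_peaks = len(peak_densities)

    if n_wells and n_peaks / n_wells > occupancy_warn:
        warnings.warn(
            f"sample {well_set.sample_id!r}: mean occupancy "
            f"{n_peaks / n_wells:.2f} peaks/well exceeds {occupancy_warn}; "
            "single-molecule counting may undercount", stacklevel=2)

    table = DensityTable(well_set.sample_id)
    dens_counts: dict[Fraction, int] = {}
    for d in peak_densities:
        dens_counts[d] = dens_counts.get(d, 0) + 1

    scale = 1.0
    if poisson_correct and n_wells and 0 < n_peaks:
        occupied = sum(1 for w in well_set.wells if w.peak_temps)
        if occupied < n_wells:
            lam = -math.log(1 - occupied / n_wells)
            scale = lam * n_wells / n_peaks
    for d, c in dens_counts.items():
        k = int(round(c * scale))
        if k and d > 0:
            table.add(int(d * n), n, k)
        elif k:  # a peak that quantized to zero density stays unmethylated
            table.add(0, n, k)

    if include_background:
        bg = int(round(well_set.genomic_equivalents_loaded)) - table.total_reads
        if bg > 0:
            table.add(0, n, bg)
    return table


def dreaming_mean_methylation_proxy(table: DensityTable) -> float:
    """Mean-methylation stand-in for melt data: fraction of molecules
    with any methylation (density > 0).

    Valid because every molecule of a melt amplicon covers the same CpG
    count, making the methylated-molecule fraction proportional to the
    mean methylation level.
    """
    if table.is_empty():
        raise ValueError("empty density table")
    _, _, c = table.arrays()
    mask = table.passing_mask(0, strict=True)
    return int(c[mask].sum()) / table.total_reads


# ---------------------------------------------------------------------------
# Melt table CSV schema
# ---------------------------------------------------------------------------

_MELT_COLUMNS = ["sample_id", "well_id", "peak_temp_c", "ge_loaded",
                 "ge_total", "plasma_ml"]


def write_melt_csv(well_sets: Iterable[MeltWellSet], path) -> None:
    """One row per (well, peak); peak-free wells get an empty temp field."""
    rows = []
    for ws in well_sets:
        for w in ws.wells:
            temps = w.peak_temps or (None,)
            for t in temps:
                rows.append((ws.sample_id, w.well_id, t,
                             ws.genomic_equivalents_loaded,
                             ws.total_genomic_equivalents,
                             ws.plasma_volume_ml))
    pd.DataFrame(rows, columns=_MELT_COLUMNS).to_csv(path, index=False)


def read_melt_csv(path) -> list[MeltWellSet]:
    df = pd.read_csv(path)
    missing = set(_MELT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"melt CSV missing columns: {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        meta = grp.iloc[0]
        wells = []
        for wid, wgrp in grp.groupby("well_id", sort=True):
            temps = tuple(float(t) for t in wgrp["peak_temp_c"]
                          if pd.notna(t))
            wells.append(MeltWell(well_id=str(wid), peak_temps=temps))
        out.append(MeltWellSet(
            sample_id=str(sid), wells=wells,
            genomic_equivalents_loaded=float(meta.ge_loaded),
            total_genomic_equivalents=float(meta.ge_total),
            plasma_volume_ml=float(meta.plasma_ml)))
    return out
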