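"""Seeded generators for every input the package consumes.

All generators are pure functions of their parameters plus a seed and emit
the package's interchange formats (density tables, melt well sets, SAM
text, beta matrices) together with the generative ground truth, so tests
and simulations run without any external data.

The epiallele generator uses a zero-inflated beta-binomial family: each
read draws a latent density (a point mass at zero, a low-mean Beta for
background noise, or — in cases, with the tumor fraction's probability — a
high-mean Beta) and then binomial CpG calls at that density.  This
reproduces a dominant near-zero density mode plus rare dense molecules in
cases with three interpretable knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from epidense.density import DensityTable, MarkerRegion
from epidense.dreaming import MeltWell, MeltWellSet, SequencedPattern
from epidense.multimarker import BetaMatrix

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_source_tables",
    "generate_melt_dataset",
    "generate_calibration_pairs",
    "generate_alignment_fixture",
    "sam_header",
    "sam_read_line",
    "generate_beta_matrix",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic case/control cohort.

    ``cpgs_per_read`` is either a fixed count (melt-amplicon-like) or an
    inclusive ``(lo, hi)`` range sampled uniformly (RRBS-like).
    ``weight_zero`` is the point mass at density zero in the background
    mixture; the rest of the background is Beta(*low_beta_shapes*).  Case
    reads are tumor-derived (Beta(*high_beta_shapes*)) with probability
    ``tumor_fraction``, otherwise background.
    """

    n_cases: int = 10
    n_controls: int = 10
    reads_per_sample: int = 200
    cpgs_per_read: int | tuple[int, int] = 14
    weight_zero: float = 0.7
    low_beta_shapes: tuple[float, float] = (1.0, 19.0)    # mean 0.05
    tumor_fraction: float = 0.01
    high_beta_shapes: tuple[float, float] = (8.5, 1.5)    # mean 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_zero <= 1.0:
            raise ValueError("weight_zero must lie in [0, 1]")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        for a, b in (self.low_beta_shapes, self.high_beta_shapes):
            if a <= 0 or b <= 0:
                raise ValueError("beta shapes must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for assertion against outputs."""

    spec: CohortSpec
    tumor_reads_per_sample: dict[str, int]
    read_sources: dict[str, list[str]]    # per sample: "tumor"/"background"


def _draw_n_cpgs(spec: CohortSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.cpgs_per_read, tuple):
        lo, hi = spec.cpgs_per_read
        return int(rng.integers(lo, hi + 1))
    return int(spec.cpgs_per_read)


def _background_density(spec: CohortSpec, rng: np.random.Generator) -> float:
    if rng.random() < spec.weight_zero:
        return 0.0
    a, b = spec.low_beta_shapes
    return float(rng.beta(a, b))


def _one_sample(sid: str, is_case: bool, spec: CohortSpec,
                rng: np.random.Generator) -> tuple[DensityTable, int, list[str]]:
    table = DensityTable(sid)
    n_tumor = 0
    sources = []
    for _ in range(spec.reads_per_sample):
        n = _draw_n_cpgs(spec, rng)
        if is_case and rng.random() < spec.tumor_fraction:
            a, b = spec.high_beta_shapes
            d = float(rng.beta(a, b))
            src = "tumor"
            n_tumor += 1
        else:
            d = _background_density(spec, rng)
            src = "background"
        m = int(rng.binomial(n, d))
        table.add(m, n)
        sources.append(src)
    return table, n_tumor, sources


def generate_cohort(spec: CohortSpec) -> tuple[dict[str, DensityTable], GroundTruth]:
    """Generate labeled density tables for a full synthetic cohort.

    Sample ids are ``case_00..`` / ``control_00..``; the label is
    recoverable from the id prefix.  Byte-identical output for a fixed
    spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, DensityTable] = {}
    tumor_counts: dict[str, int] = {}
    sources: dict[str, list[str]] = {}
    for i in range(spec.n_cases):
        sid = f"case_{i:02d}"
        tables[sid], tumor_counts[sid], sources[sid] = _one_sample(
            sid, True, spec, rng)
    for i in range(spec.n_controls):
        sid = f"control_{i:02d}"
        tables[sid], tumor_counts[sid], sources[sid] = _one_sample(
            sid, False, spec, rng)
    return tables, GroundTruth(spec=spec,
                               tumor_reads_per_sample=tumor_counts,
                               read_sources=sources)


def generate_source_tables(
    n_tumor: int, n_background: int, reads_per_sample: int = 2000,
    cpgs_per_read: int | tuple[int, int] = 14,
    high_beta_shapes: tuple[float, float] = (8.5, 1.5),
    weight_zero: float = 0.7,
    low_beta_shapes: tuple[float, float] = (1.0, 19.0),
    seed: int = 0,
) -> tuple[dict[str, DensityTable], dict[str, DensityTable]]:
    """Pure tumor and pure background source tables for dilution studies."""
    tumor_spec = CohortSpec(n_cases=n_tumor, n_controls=0,
                            reads_per_sample=reads_per_sample,
                            cpgs_per_read=cpgs_per_read,
                            tumor_fraction=1.0,
                            high_beta_shapes=high_beta_shapes, seed=seed)
    bg_spec = CohortSpec(n_cases=0, n_controls=n_background,
                         reads_per_sample=reads_per_sample,
                         cpgs_per_read=cpgs_per_read,
                         weight_zero=weight_zero,
                         low_beta_shapes=low_beta_shapes, seed=seed + 1)
    tumors, _ = generate_cohort(tumor_spec)
    backgrounds, _ = generate_cohort(bg_spec)
    tumors = {k.replace("case", "tumor"): v for k, v in tumors.items()}
    backgrounds = {k.replace("control", "background"): v
                   for k, v in backgrounds.items()}
    for k, t in {**tumors, **backgrounds}.items():
        t.sample_id = k
    return tumors, backgrounds


# ---------------------------------------------------------------------------
# Melt fixtures
# ---------------------------------------------------------------------------

def generate_melt_dataset(
    n_samples: int,
    slope: float,
    intercept: float,
    noise_sigma: float = 0.1,
    n_cpgs: int = 14,
    wells_per_sample: int = 24,
    occupancy_lambda: float = 0.2,
    ge_loaded: float = 4800.0,
    ge_total: float = 9600.0,
    plasma_ml: float = 2.0,
    density_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[list[MeltWellSet], dict[str, list[Fraction]]]:
    """Simulate melt-well data under a known affine temp<->density map.

    The map is ``density = slope * temp + intercept``; emitted peak
    temperatures are its inverse at a lattice density plus Gaussian noise
    of ``noise_sigma`` degrees.  Per well, the number of methylated
    molecules is Poisson(``occupancy_lambda``).  Returns the well sets and
    the true lattice densities per sample.
    """
    rng = np.random.default_rng(seed)
    if density_weights is None:
        density_weights = np.ones(n_cpgs)
    probs = np.asarray(density_weights, float)
    probs = probs / probs.sum()
    well_sets, truth = [], {}
    for i in range(n_samples):
        sid = f"melt_{i:02d}"
        wells, dens = [], []
        for w in range(wells_per_sample):
            n_peaks = int(rng.poisson(occupancy_lambda))
            temps = []
            for _ in range(n_peaks):
                k = int(rng.choice(np.arange(1, n_cpgs + 1), p=probs))
                d = Fraction(k, n_cpgs)
                t = (float(d) - intercept) / slope
                temps.append(t + float(rng.normal(0, noise_sigma)))
                dens.append(d)
            wells.append(MeltWell(well_id=f"W{w:02d}",
                                  peak_temps=tuple(temps)))
        well_sets.append(MeltWellSet(
            sample_id=sid, wells=wells,
            genomic_equivalents_loaded=ge_loaded,
            total_genomic_equivalents=ge_total,
            plasma_volume_ml=plasma_ml))
        truth[sid] = dens
    return well_sets, truth


def generate_calibration_pairs(
    n_pairs: int, slope: float, intercept: float,
    noise_sigma: float = 0.1, n_cpgs: int = 14, seed: int = 0,
) -> tuple[list[SequencedPattern], list[float], list[Fraction]]:
    """Sequenced patterns plus noisy peak temps for calibration tests.

    Densities are distinct lattice points so rank matching is well posed;
    returns ``(patterns, peak_temps, true_densities)`` with both lists in
    generation order (not pre-sorted).
    """
    if n_pairs > n_cpgs:
        raise ValueError("cannot draw more distinct lattice densities "
                         f"than {n_cpgs}")
    rng = np.random.default_rng(seed)
    ks = rng.choice(np.arange(1, n_cpgs + 1), size=n_pairs, replace=False)
    patterns, temps, dens = [], [], []
    for k in ks:
        d = Fraction(int(k), n_cpgs)
        patterns.append(SequencedPattern(density=float(d),
                                         abundance=int(rng.integers(1, 20)),
                                         conversion_efficiency=1.0))
        temps.append((float(d) - intercept) / slope
                     + float(rng.normal(0, noise_sigma)))
        dens.append(d)
    return patterns, temps, dens


# ---------------------------------------------------------------------------
# Alignment fixtures (plain-text SAM with per-read call strings)
# ---------------------------------------------------------------------------

def sam_header(region: MarkerRegion, samples: Sequence[str],
               ref_length: int | None = None) -> list[str]:
    length = ref_length or region.end0 + 1000
    lines = ["@HD\tVN:1.6\tSO:unsorted",
             f"@SQ\tSN:{region.chrom}\tLN:{length}"]
    lines += [f"@RG\tID:{s}\tSM:{s}" for s in samples]
    return lines


def sam_read_line(qname: str, chrom: str, pos0: int, xm: str,
                  sample: str | None = None, flag: int = 0,
                  cigar: str | None = None) -> str:
    """One SAM record whose sequence length equals the call-string length."""
    seq = "".join("C" if c == "Z" else "T" for c in xm)
    fields = [qname, str(flag), chrom, str(pos0 + 1), "42",
              cigar or f"{len(xm)}M", "*", "0", "0", seq, "I" * len(xm),
              f"XM:Z:{xm}"]
    if sample is not None:
        fields.append(f"RG:Z:{sample}")
    return "\t".join(fields)


def generate_alignment_fixture(
    tables: Mapping[str, DensityTable],
    region: MarkerRegion,
    path,
) -> None:
    """Write a SAM file whose per-read call strings reproduce ``tables``.

    Each tallied read becomes one single-end record fully inside the
    region, with a call string of ``n_meth`` methylated and the rest
    unmethylated CpG calls and an RG tag naming its sample.  Empty tables
    yield a header-only file.
    """
    samples = sorted(tables)
    lines = sam_header(region, samples)
    span = region.end0 - region.start0
    idx = 0
    for sid in samples:
        for (m, n), c in sorted(tables[sid].counts.items()):
            for _ in range(c):
                xm = "Z" * m + "z" * (n - m)
                if n > span:
                    raise ValueError(
                        f"read with {n} CpGs does not fit inside region "
                        f"{region.name} (span {span})")
                pos0 = region.start0 + (idx % (span - n + 1))
                lines.append(sam_read_line(f"{sid}.r{idx}", region.chrom,
                                           pos0, xm, sample=sid))
                idx += 1
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Beta-matrix fixtures
# ---------------------------------------------------------------------------

def generate_beta_matrix(
    n_probes: int = 50,
    n_pairs: int = 10,
    n_planted: int = 3,
    include_decoy: bool = True,
    seed: int = 0,
) -> tuple[BetaMatrix, list[MarkerRegion], dict]:
    """Beta matrix with planted clean markers and an optional decoy.

    Planted probes have normals below 0.1 and tumors near 0.9 and sit
    inside the returned candidate regions; the decoy matches them except
    one normal sample at beta 0.3 (so the max-normal filter must reject
    it).  Remaining probes are uniform background noise.
    """
    rng = np.random.default_rng(seed)
    tumors = [f"T{i:02d}" for i in range(n_pairs)]
    normals = [f"N{i:02d}" for i in range(n_pairs)]
    samples = tumors + normals
    probes = [f"cg{i:07d}" for i in range(n_probes)]

    values = pd.DataFrame(rng.uniform(0, 1, size=(n_probes, len(samples))),
                          index=probes, columns=samples)
    coords = pd.DataFrame({
        "chrom": ["chr1"] * n_probes,
        "pos": [10_000 + 100 * i for i in range(n_probes)],
    }, index=probes)

    planted = probes[:n_planted]
    for j, p in enumerate(planted):
        values.loc[p, tumors] = rng.uniform(0.85, 0.95, n_pairs)
        # stagger normal levels so ranking by paired difference is stable
        values.loc[p, normals] = rng.uniform(0.0, 0.05 + 0.02 * j, n_pairs)
    decoy = None
    if include_decoy and n_probes > n_planted:
        decoy = probes[n_planted]
        values.loc[decoy, tumors] = rng.uniform(0.85, 0.95, n_pairs)
        values.loc[decoy, normals] = rng.uniform(0.0, 0.1, n_pairs)
        values.loc[decoy, normals[0]] = 0.3

    covered = planted + ([decoy] if decoy else [])
    lo = min(int(coords.loc[p, "pos"]) for p in covered)
    hi = max(int(coords.loc[p, "pos"]) for p in covered)
    regions = [MarkerRegion(name="planted", chrom="chr1",
                            start=lo + 1 - 50, end=hi + 50)]
    beta = BetaMatrix(values=values, probe_coords=coords,
                      sample_class=pd.Series(
                          ["tumor"] * n_pairs + ["normal"] * n_pairs,
                          index=samples),
                      pairs=list(zip(tumors, normals)))
    truth = {"planted": planted, "decoy": decoy, "seed": seed}
    return beta, regions, truth
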