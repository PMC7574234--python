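"""Per-read methylation densities and per-sample density tables.

A *density table* tallies the DNA fragments observed at a locus by their
``(methylated CpGs, total CpGs)`` pair.  It is the unit every downstream
classifier consumes and the interchange format between modules
(serialized as tidy CSV: ``sample_id,n_meth,n_cpgs,count``).

Densities are kept as exact integer pairs internally; cutoffs are compared
with integer cross-multiplication so that grid values such as 0.60 never
suffer float-boundary misclassification.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MarkerRegion",
    "EpialleleRecord",
    "DensityTable",
    "methylation_density",
    "read_epialleles",
    "build_density_table",
    "mean_locus_methylation",
    "epiallelic_fraction",
    "read_density_csv",
    "write_density_csv",
]


class AlignmentParseError(ValueError):
    """A read in the alignment source could not be interpreted."""


def as_fraction(x) -> Fraction:
    """Coerce a cutoff to an exact :class:`~fractions.Fraction`.

    Floats are snapped to the nearest small rational so that 0.05-step grid
    values written in decimal survive the float round trip exactly.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, np.integer)):
        return Fraction(int(x))
    if isinstance(x, (float, np.floating)):
        return Fraction(float(x)).limit_denominator(10**6)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as a fraction")


@dataclass(frozen=True)
class MarkerRegion:
    """A genomic target region.

    ``start``/``end`` are 1-based, fully closed coordinates, matching the
    conventional ``chrom:start-end`` notation.  ``start0``/``end0`` give the
    0-based half-open equivalents used against alignment records.

    ``overlap_mode`` must be chosen explicitly per dataset:

    - ``"any_overlap"``: a read is retained if at least one aligned base
      falls inside the region.
    - ``"full_containment"``: only reads lying entirely within the region
      are retained.
    """

    name: str
    chrom: str
    start: int
    end: int
    overlap_mode: str = "full_containment"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name}: start must be < end")
        if self.overlap_mode not in ("any_overlap", "full_containment"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @classmethod
    def from_string(cls, text: str, overlap_mode: str = "full_containment",
                    name: str | None = None) -> "MarkerRegion":
        """Parse ``"Chr19:58220000-58220800"`` (1-based, closed)."""
        try:
            chrom, span = text.strip().split(":")
            lo, hi = span.replace(",", "").split("-")
            start, end = int(lo), int(hi)
        except ValueError as exc:
            raise ValueError(f"cannot parse region string {text!r}") from exc
        return cls(name=name or text.strip(), chrom=chrom, start=start,
                   end=end, overlap_mode=overlap_mode)

    @classmethod
    def from_bed_fields(cls, chrom: str, start0: int, end0: int,
                        name: str | None = None,
                        overlap_mode: str = "full_containment") -> "MarkerRegion":
        """Build from BED (0-based half-open) fields."""
        return cls(name=name or f"{chrom}:{start0 + 1}-{end0}", chrom=chrom,
                   start=int(start0) + 1, end=int(end0),
                   overlap_mode=overlap_mode)


@dataclass(frozen=True)
class EpialleleRecord:
    """One sequenced DNA fragment at a locus."""

    sample_id: str
    n_cpgs: int
    n_meth: int

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("epiallele must carry at least one CpG")
        if not 0 <= self.n_meth <= self.n_cpgs:
            raise ValueError("need 0 <= n_meth <= n_cpgs")

    @property
    def density(self) -> Fraction:
        return Fraction(self.n_meth, self.n_cpgs)


def methylation_density(n_meth: int, n_cpgs: int) -> Fraction:
    """Fraction of a single molecule's CpG sites that are methylated.

    Raises ``ValueError`` for ``n_cpgs == 0``: a read carrying no CpGs has
    no density and must be dropped by the caller.
    """
    if n_cpgs < 1:
        raise ValueError("methylation density undefined for a read with no CpGs")
    if not 0 <= n_meth <= n_cpgs:
        raise ValueError("need 0 <= n_meth <= n_cpgs")
    return Fraction(n_meth, n_cpgs)


class DensityTable:
    """Tally of one sample's epialleles keyed by ``(n_meth, n_cpgs)``."""

    def __init__(self, sample_id: str,
                 counts: Mapping[tuple[int, int], int] | None = None) -> None:
        self.sample_id = sample_id
        self.counts: Counter[tuple[int, int]] = Counter()
        if counts:
            for (m, n), c in counts.items():
                self.add(int(m), int(n), int(c))

    def add(self, n_meth: int, n_cpgs: int, count: int = 1) -> None:
        if n_cpgs < 1:
            raise ValueError("cannot tally a read with no CpGs")
        if not 0 <= n_meth <= n_cpgs:
            raise ValueError("need 0 <= n_meth <= n_cpgs")
        if count < 0:
            raise ValueError("count must be non-negative")
        if count:
            self.counts[(n_meth, n_cpgs)] += count

    # -- aggregates ---------------------------------------------------------

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def total_cpgs(self) -> int:
        return sum(n * c for (_, n), c in self.counts.items())

    @property
    def total_meth_cpgs(self) -> int:
        return sum(m * c for (m, _), c in self.counts.items())

    def is_empty(self) -> bool:
        return not self.counts

    # -- vectorized views ---------------------------------------------------

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(n_meth, n_cpgs, count)`` integer arrays over distinct keys."""
        if not self.counts:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        keys = sorted(self.counts)
        m = np.array([k[0] for k in keys], dtype=np.int64)
        n = np.array([k[1] for k in keys], dtype=np.int64)
        c = np.array([self.counts[k] for k in keys], dtype=np.int64)
        return m, n, c

    def passing_mask(self, md_cutoff, strict: bool = False) -> np.ndarray:
        """Boolean mask over :meth:`arrays` keys with density >= cutoff.

        Comparison is exact: ``m/n >= p/q`` is evaluated as ``m*q >= p*n``
        in integer arithmetic.  With ``strict=True`` the comparison is
        ``>`` instead of ``>=`` (used for the density-zero special case).
        """
        cut = as_fraction(md_cutoff)
        m, n, _ = self.arrays()
        lhs = m * cut.denominator
        rhs = cut.numerator * n
        return lhs > rhs if strict else lhs >= rhs

    def __eq__(self, other) -> bool:
        return (isinstance(other, DensityTable)
                and self.sample_id == other.sample_id
                and self.counts == other.counts)

    def __repr__(self) -> str:
        return (f"DensityTable({self.sample_id!r}, reads={self.total_reads}, "
                f"cpgs={self.total_cpgs}, meth={self.total_meth_cpgs})")


def mean_locus_methylation(table: DensityTable) -> float:
    """Weighted methylation level: total methylated CpGs over all CpGs."""
    tot = table.total_cpgs
    if tot == 0:
        raise ValueError(f"sample {table.sample_id!r}: no CpGs tallied; "
                         "mean locus methylation is undefined")
    return table.total_meth_cpgs / tot


def epiallelic_fraction(table: DensityTable, md_cutoff,
                        weighting: str = "cpg_weighted",
                        zero_mode: str = "inclusive") -> float:
    """Fraction of a sample's material at or above a density cutoff.

    weighting
        ``"read_count"``: passing reads / total reads.
        ``"cpg_weighted"``: CpGs covered by passing reads / total CpGs
        (reads with many CpGs count proportionally more).
    zero_mode
        At ``md_cutoff == 0``, ``"inclusive"`` counts every read (fraction
        is 1 by definition) while ``"strict"`` counts only reads with
        density strictly above zero.  Ignored for nonzero cutoffs.
    """
    if table.is_empty():
        raise ValueError(f"sample {table.sample_id!r}: empty density table")
    cut = as_fraction(md_cutoff)
    if not 0 <= cut <= 1:
        raise ValueError("md_cutoff must lie in [0, 1]")
    if weighting not in ("read_count", "cpg_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if zero_mode not in ("inclusive", "strict"):
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    strict = zero_mode == "strict" and cut == 0
    mask = table.passing_mask(cut, strict=strict)
    _, n, c = table.arrays()
    if weighting == "read_count":
        return int(c[mask].sum()) / table.total_reads
    return int((n * c)[mask].sum()) / table.total_cpgs


# ---------------------------------------------------------------------------
# Alignment parsing
# ---------------------------------------------------------------------------

_CPG_CALLS = frozenset("zZ")


def _fragment_calls(read: "pysam.AlignedSegment") -> dict[int, bool]:
    """CpG-context calls of one read keyed by reference position.

    Uses the Bismark-style per-read call string (XM tag): ``Z``/``z`` mark
    methylated/unmethylated CpG; other contexts and ``.`` are skipped.
    Unaligned query positions (insertions, clips) carry no reference
    coordinate and are skipped.
    """
    try:
        xm = read.get_tag("XM")
    except KeyError:
        raise AlignmentParseError(
            f"read {read.query_name!r} has no XM methylation-call tag"
        ) from None
    calls: dict[int, bool] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        ch = xm[qpos]
        if ch in _CPG_CALLS:
            calls[rpos] = ch == "Z"
    return calls


def _retained(read: "pysam.AlignedSegment", region: MarkerRegion) -> bool:
    if read.is_unmapped or read.reference_name != region.chrom:
        return False
    start, end = read.reference_start, read.reference_end
    if region.overlap_mode == "full_containment":
        return start >= region.start0 and end <= region.end0
    return start < region.end0 and end > region.start0


def _sample_of(read: "pysam.AlignedSegment",
               rg_to_sample: Mapping[str, str]) -> str:
    try:
        rg = read.get_tag("RG")
    except KeyError:
        return "sample"
    return rg_to_sample.get(rg, rg)


def read_epialleles(alignment_source, region: MarkerRegion) -> list[EpialleleRecord]:
    """Extract one epiallele per retained fragment from SAM/BAM.

    Reads must carry Bismark-style XM call strings.  Retention follows
    ``region.overlap_mode``.  Mates of a paired fragment that are both
    retained are merged into a single record: their CpG calls are unioned
    by reference position (a methylated call wins on the rare mate
    disagreement), so the unit of counting is the DNA molecule.  Reads
    whose call string contains no CpG-context call are dropped.
    """
    own = isinstance(alignment_source, (str, Path))
    af = (pysam.AlignmentFile(str(alignment_source), check_sq=False)
          if own else alignment_source)
    try:
        refs = set(af.references or ())
        if refs and region.chrom not in refs:
            raise ValueError(
                f"chromosome {region.chrom!r} absent from alignment header "
                f"(has {sorted(refs)[:5]}...)")
        rg_to_sample = {
            rg.get("ID", ""): rg.get("SM", rg.get("ID", ""))
            for rg in (af.header.to_dict().get("RG") or [])
        }
        # fragment key -> (sample, merged calls)
        fragments: dict[tuple[str, str], dict[int, bool]] = {}
        frag_sample: dict[tuple[str, str], str] = {}
        order: list[tuple[str, str]] = []
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if not _retained(read, region):
                continue
            calls = _fragment_calls(read)
            if not calls:
                continue
            sample = _sample_of(read, rg_to_sample)
            key = (sample, read.query_name) if read.is_paired else (
                sample, f"{read.query_name}\x00{read.reference_start}")
            if key not in fragments:
                fragments[key] = {}
                frag_sample[key] = sample
                order.append(key)
            merged = fragments[key]
            for rpos, meth in calls.items():
                merged[rpos] = merged.get(rpos, False) or meth
    finally:
        if own:
            af.close()

    records = []
    for key in order:
        calls = fragments[key]
        records.append(EpialleleRecord(
            sample_id=frag_sample[key],
            n_cpgs=len(calls),
            n_meth=sum(calls.values()),
        ))
    return records


# ---------------------------------------------------------------------------
# Table construction and interchange format
# ---------------------------------------------------------------------------

def build_density_table(
    records: Iterable[EpialleleRecord],
    pooling_map: Mapping[str, str] | None = None,
    expected_samples: Sequence[str] | None = None,
) -> tuple[dict[str, DensityTable], list[str]]:
    """Tally epiallele records into one :class:`DensityTable` per sample.

    ``pooling_map`` maps library ids to pooled sample ids so replicate
    libraries of the same sample are summed; without it, record sample ids
    are used directly.  Returns ``(tables, dropped)`` where ``dropped``
    lists expected samples that had zero reads at the locus — these are
    excluded from the result but reported, never silently lost.
    """
    records = list(records)
    if not records:
        warnings.warn("no epiallele records supplied; result is empty",
                      stacklevel=2)

    tables: dict[str, DensityTable] = {}
    for rec in records:
        if pooling_map is not None:
            if rec.sample_id not in pooling_map:
                raise KeyError(
                    f"library {rec.sample_id!r} not resolvable through the "
                    "pooling map")
            sid = pooling_map[rec.sample_id]
        else:
            sid = rec.sample_id
        tables.setdefault(sid, DensityTable(sid)).add(rec.n_meth, rec.n_cpgs)

    expected: set[str] = set(expected_samples or ())
    if pooling_map is not None:
        expected |= set(pooling_map.values())
    dropped = sorted(expected - set(tables))
    for sid in dropped:
        warnings.warn(f"sample {sid!r} had no reads at the locus; excluded",
                      stacklevel=2)
    return tables, dropped


def write_density_csv(tables: Mapping[str, DensityTable] | Iterable[DensityTable],
                      path) -> None:
    """Serialize density tables as tidy CSV (the interchange format)."""
    if isinstance(tables, Mapping):
        tables = tables.values()
    rows = []
    for t in tables:
        for (m, n), c in sorted(t.counts.items()):
            rows.append((t.sample_id, m, n, c))
    pd.DataFrame(rows, columns=["sample_id", "n_meth", "n_cpgs", "count"]) \
        .to_csv(path, index=False)


def read_density_csv(path) -> dict[str, DensityTable]:
    """Load tables from tidy CSV written by :func:`write_density_csv`."""
    df = pd.read_csv(path)
    required = {"sample_id", "n_meth", "n_cpgs", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"density CSV missing columns: {sorted(missing)}")
    tables: dict[str, DensityTable] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        t = DensityTable(str(sid))
        for _, row in grp.iterrows():
            t.add(int(row.n_meth), int(row.n_cpgs), int(row["count"]))
        tables[str(sid)] = t
    return tables
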