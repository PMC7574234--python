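"""Joint optimization of density and epiallelic-fraction cutoffs.

A sample is called positive when its epiallelic measure at a density
cutoff ``md`` is at least an epiallelic-fraction cutoff ``ef``.  Both
cutoffs are learned together by exhaustively maximizing Youden's J
(TPR − FPR) over a density grid crossed with every observed measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from epidense.density import (
    DensityTable,
    as_fraction,
    epiallelic_fraction,
    mean_locus_methylation,
)

__all__ = [
    "DEFAULT_MD_GRID",
    "MEASURES",
    "PRESETS",
    "SampleScoreSet",
    "CutoffGrid",
    "OptimalCutoffs",
    "score_samples",
    "build_cutoff_grid",
    "optimize_cutoffs",
    "roc_at_md",
    "performance_profile",
    "classify",
    "baseline_scores",
    "bootstrap_auc_ci",
]

#: Density-cutoff grid: 0 to 1 in steps of 0.05, as exact fractions.
DEFAULT_MD_GRID: tuple[Fraction, ...] = tuple(Fraction(k, 20) for k in range(21))

MEASURES = ("fraction", "per_ml_count", "normalized_read_count")

#: Published cutoff presets, shipped as data rather than hard-coded logic.
#: ``ef_star`` units depend on the measure the preset was derived with.
PRESETS: dict[str, dict] = {
    "ovarian_plasma_melt": {
        "md_star": Fraction(3, 5),        # 60% density cutoff
        "ef_star": 6.7,                   # epialleles per mL plasma
        "measure": "per_ml_count",
    },
    "hcc_wgbs": {
        "md_star": Fraction(9, 20),       # 45% density cutoff
        "measure": "normalized_read_count",
    },
}


@dataclass
class SampleScoreSet:
    """One sample's epiallelic measure at every density cutoff of a grid."""

    sample_id: str
    label: str                      # "case" or "control"
    md_grid: tuple[Fraction, ...]
    scores: np.ndarray              # aligned with md_grid
    measure: str = "fraction"

    def __post_init__(self) -> None:
        if self.label not in ("case", "control"):
            raise ValueError(f"label must be case/control, got {self.label!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.md_grid),):
            raise ValueError("score vector length must match md grid")

    def score_at(self, md) -> float:
        md = as_fraction(md)
        try:
            i = self.md_grid.index(md)
        except ValueError:
            raise KeyError(f"md cutoff {md} not on this sample's grid") from None
        return float(self.scores[i])


@dataclass
class CutoffGrid:
    """TPR/FPR surfaces over (density cutoff, observed measure) pairs.

    The measure axis is ragged: each density cutoff carries the sorted
    unique measures observed in training at that cutoff, with ``+inf``
    appended so a row with FPR = 0 (nothing called positive) always exists.
    """

    md_grid: tuple[Fraction, ...]
    ef_candidates: list[np.ndarray]
    tpr: list[np.ndarray]
    fpr: list[np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.md_grid)
        if not (len(self.ef_candidates) == len(self.tpr) == len(self.fpr) == k):
            raise ValueError("per-md arrays must align with the md grid")
        for ef, t, f in zip(self.ef_candidates, self.tpr, self.fpr):
            if not (len(ef) == len(t) == len(f)):
                raise ValueError("ef/tpr/fpr lengths differ at some md")
            if np.any((t < 0) | (t > 1)) or np.any((f < 0) | (f > 1)):
                raise ValueError("rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for md, efs, ts, fs in zip(self.md_grid, self.ef_candidates,
                                   self.tpr, self.fpr):
            for ef, t, f in zip(efs, ts, fs):
                rows.append((float(md), float(ef), t, f, t - f))
        return pd.DataFrame(rows, columns=["md_cutoff", "ef_cutoff",
                                           "tpr", "fpr", "youden_j"])


@dataclass
class OptimalCutoffs:
    """Argmax of Youden's J over a cutoff grid, ties included."""

    ties: list[tuple[Fraction, float]]
    canonical: tuple[Fraction, float]
    j_star: float

    @property
    def md_star(self) -> Fraction:
        return self.canonical[0]

    @property
    def ef_star(self) -> float:
        return self.canonical[1]


def _table_score(table: DensityTable, md: Fraction, measure: str,
                 normalizer: float | None) -> float:
    # density-zero cutoff counts only strictly methylated fragments
    strict = md == 0
    if measure == "fraction":
        return epiallelic_fraction(table, md, weighting="cpg_weighted",
                                   zero_mode="strict" if strict else "inclusive")
    mask = table.passing_mask(md, strict=strict)
    _, _, c = table.arrays()
    passing = int(c[mask].sum())
    if measure == "per_ml_count":
        if normalizer is None:
            raise ValueError(
                f"sample {table.sample_id!r}: per_ml_count requires a plasma "
                "volume normalizer")
        return passing / float(normalizer)
    if measure == "normalized_read_count":
        return passing / table.total_reads
    raise ValueError(f"unknown measure {measure!r}")


def score_samples(
    tables: Mapping[str, DensityTable],
    labels: Mapping[str, str],
    md_grid: Sequence | None = None,
    measure: str = "fraction",
    normalizers: Mapping[str, float] | None = None,
) -> list[SampleScoreSet]:
    """Evaluate every sample's epiallelic measure on a shared density grid.

    ``measure`` selects the units: CpG-weighted fraction, epialleles per mL
    of plasma (requires per-sample volumes in ``normalizers``), or passing
    reads over total reads at the locus.  The density-zero grid point uses
    the strict rule (only fragments with density > 0 count).
    """
    if md_grid is None:
        md_grid = DEFAULT_MD_GRID
    grid = tuple(as_fraction(x) for x in md_grid)
    if not grid:
        raise ValueError("md grid is empty")
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    if measure == "per_ml_count" and normalizers is None:
        raise ValueError("per_ml_count requires per-sample volume normalizers")

    out = []
    for sid, table in tables.items():
        norm = normalizers.get(sid) if normalizers else None
        scores = np.array(
            [_table_score(table, md, measure, norm) for md in grid])
        out.append(SampleScoreSet(sample_id=sid, label=labels[sid],
                                  md_grid=grid, scores=scores,
                                  measure=measure))
    return out


def _split_scores(scores: Sequence[SampleScoreSet]):
    cases = [s for s in scores if s.label == "case"]
    controls = [s for s in scores if s.label == "control"]
    if not cases or not controls:
        raise ValueError("need at least one case and one control")
    grid = cases[0].md_grid
    for s in scores:
        if s.md_grid != grid:
            raise ValueError("all samples must share one md grid")
    return cases, controls, grid


def build_cutoff_grid(scores: Sequence[SampleScoreSet]) -> CutoffGrid:
    """TPR/FPR at every (density cutoff, observed measure) combination.

    Candidate measure cutoffs at each density cutoff are exactly the
    values observed in the training data there, plus ``+inf``.  A sample
    counts as positive when its measure is >= the candidate.
    """
    cases, controls, grid = _split_scores(scores)
    case_m = np.stack([s.scores for s in cases])        # (n_cases, n_md)
    ctrl_m = np.stack([s.scores for s in controls])

    ef_candidates, tprs, fprs = [], [], []
    for j in range(len(grid)):
        observed = np.unique(np.concatenate([case_m[:, j], ctrl_m[:, j]]))
        efs = np.append(observed, np.inf)
        tpr = (case_m[:, j][:, None] >= efs[None, :]).mean(axis=0)
        fpr = (ctrl_m[:, j][:, None] >= efs[None, :]).mean(axis=0)
        ef_candidates.append(efs)
        tprs.append(tpr)
        fprs.append(fpr)
    return CutoffGrid(md_grid=grid, ef_candidates=ef_candidates,
                      tpr=tprs, fpr=fprs)


def optimize_cutoffs(grid: CutoffGrid, tol: float = 1e-12) -> OptimalCutoffs:
    """Exhaustive argmax of TPR − FPR over every grid cell.

    All ties within ``tol`` of the maximum are returned; the canonical
    pair is the tie with the smallest density cutoff, then the smallest
    measure cutoff (favoring sensitivity).
    """
    j_star = -np.inf
    for t, f in zip(grid.tpr, grid.fpr):
        if len(t):
            j_star = max(j_star, float(np.max(t - f)))
    ties: list[tuple[Fraction, float]] = []
    for md, efs, t, f in zip(grid.md_grid, grid.ef_candidates,
                             grid.tpr, grid.fpr):
        j = t - f
        for i in np.flatnonzero(j >= j_star - tol):
            ties.append((md, float(efs[i])))
    ties.sort(key=lambda p: (p[0], p[1]))
    return OptimalCutoffs(ties=ties, canonical=ties[0], j_star=j_star)


def roc_at_md(scores: Sequence[SampleScoreSet], md_cutoff):
    """ROC curve and AUC for the measure at one density cutoff.

    The AUC equals the Mann–Whitney U statistic of case versus control
    measures divided by ``n_cases * n_controls``, with ties counted 1/2.
    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    cases, controls, _ = _split_scores(scores)
    md = as_fraction(md_cutoff)
    y = np.array([1] * len(cases) + [0] * len(controls))
    x = np.array([s.score_at(md) for s in cases]
                 + [s.score_at(md) for s in controls])
    fpr, tpr, thr = roc_curve(y, x)
    return fpr, tpr, thr, float(roc_auc_score(y, x))


def performance_profile(scores: Sequence[SampleScoreSet]) -> pd.DataFrame:
    """Per-density-cutoff AUC and best achievable operating point.

    One row per density cutoff with the AUC of the measure there, plus the
    TPR, 1−FPR and Youden J of the measure cutoff maximizing J at that
    density cutoff alone.  ``is_global_optimum`` marks the rows whose J
    attains the grid-wide maximum.
    """
    grid = build_cutoff_grid(scores)
    opt = optimize_cutoffs(grid)
    rows = []
    for md, efs, t, f in zip(grid.md_grid, grid.ef_candidates,
                             grid.tpr, grid.fpr):
        j = t - f
        i = int(np.argmax(j))
        _, _, _, auc = roc_at_md(scores, md)
        rows.append({
            "md_cutoff": float(md),
            "auc": auc,
            "tpr": float(t[i]),
            "one_minus_fpr": 1.0 - float(f[i]),
            "youden_j": float(j[i]),
            "best_ef": float(efs[i]),
            "is_global_optimum": bool(j[i] >= opt.j_star - 1e-12),
        })
    return pd.DataFrame(rows)


def classify(sample_table: DensityTable, md_star, ef_star: float,
             measure: str = "fraction",
             normalizer: float | None = None) -> str:
    """Call one sample positive/negative at fixed cutoffs.

    Positive when the sample's measure at the density cutoff is at least
    the fraction cutoff (a measure exactly equal to ``ef_star`` is
    positive).
    """
    md = as_fraction(md_star)
    score = _table_score(sample_table, md, measure, normalizer)
    return "positive" if score >= ef_star else "negative"


def baseline_scores(table: DensityTable) -> dict[str, float]:
    """Reference single-number summaries for comparison classifiers.

    ``mean_meth`` is the weighted mean methylation of the locus;
    ``msp_like`` counts only heavily methylated molecules (density >= 0.95),
    emulating methylation-specific PCR.
    """
    return {
        "mean_meth": mean_locus_methylation(table),
        "msp_like": epiallelic_fraction(table, Fraction(19, 20),
                                        weighting="read_count"),
    }


def bootstrap_auc_ci(scores: Sequence[SampleScoreSet], md_cutoff,
                     n_replicates: int = 2000, alpha: float = 0.05,
                     seed: int | None = None) -> tuple[float, float, float]:
    """Stratified bootstrap percentile CI for the AUC at one density cutoff.

    Cases and controls are resampled independently (stratified) in each
    replicate.  Returns ``(auc, lo, hi)``.  A seed is required so the
    interval is reproducible.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    cases, controls, _ = _split_scores(scores)
    md = as_fraction(md_cutoff)
    xc = np.array([s.score_at(md) for s in cases])
    xn = np.array([s.score_at(md) for s in controls])
    y = np.array([1] * len(xc) + [0] * len(xn))
    auc = float(roc_auc_score(y, np.concatenate([xc, xn])))

    rng = np.random.default_rng(seed)
    reps = np.empty(n_replicates)
    for i in range(n_replicates):
        bc = rng.choice(xc, size=len(xc), replace=True)
        bn = rng.choice(xn, size=len(xn), replace=True)
        reps[i] = roc_auc_score(y, np.concatenate([bc, bn]))
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return auc, float(lo), float(hi)
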