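"""In-silico dilution of tumor reads into a healthy background.

Spike-in samples are built by drawing reads with replacement from a tumor
sample's CpG-weighted density distribution and a background sample's, at a
fixed tumor:background ratio and total depth, then classified with the
density-cutoff machinery to quantify when density-cutoff classification
beats mean-methylation classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from epidense.classifier import (
    DEFAULT_MD_GRID,
    build_cutoff_grid,
    roc_at_md,
    score_samples,
)
from epidense.density import DensityTable, mean_locus_methylation

__all__ = [
    "AdmixtureSpec",
    "DilutionResult",
    "spike_in",
    "build_spikein_cohort",
    "dilution_experiment",
    "probability_of_improvement",
    "default_depth",
]

STANDARD_DEPTHS = (100, 1000, 10000)


@dataclass(frozen=True)
class AdmixtureSpec:
    """Parameters of one dilution condition."""

    ratio: float                 # tumor fraction of the read pool
    depth: int                   # total reads per simulated sample
    n_iterations: int = 50
    seed: int | None = None
    count_mode: str = "fixed"    # "fixed": round(ratio*depth); "binomial"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.count_mode not in ("fixed", "binomial"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if 0 < self.ratio * self.depth < 1:
            import warnings
            warnings.warn(
                f"ratio*depth = {self.ratio * self.depth:.3g} < 1: the tumor "
                "component is not representable at this depth", stacklevel=2)


@dataclass
class DilutionResult:
    """Per-iteration AUC pairs and summaries for each dilution ratio."""

    per_iteration: pd.DataFrame   # ratio, iteration, best_md, auc_md, auc_mean
    summary: pd.DataFrame         # ratio, classifier, mean_auc, ci_lo, ci_hi
    seed: int


def default_depth(ratio: float,
                  depths: Sequence[int] = STANDARD_DEPTHS) -> int:
    """Smallest standard depth at which the ratio yields >= 1 tumor read."""
    for d in sorted(depths):
        if ratio * d >= 1:
            return d
    return max(depths)


def _sampling_probs(table: DensityTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CpG-weighted draw probabilities over a table's distinct read types."""
    m, n, c = table.arrays()
    w = (n * c).astype(float)
    return m, n, w / w.sum()


def spike_in(tumor_table: DensityTable, background_table: DensityTable,
             spec: AdmixtureSpec, rng: np.random.Generator,
             sample_id: str | None = None) -> DensityTable:
    """Simulate one diluted sample at the spec's ratio and depth.

    ``round(ratio * depth)`` reads are drawn with replacement from the
    tumor table's CpG-weighted density distribution and the remainder from
    the background's; each draw inherits an observed ``(n_meth, n_cpgs)``
    pair.  ``count_mode="binomial"`` draws the tumor read count from
    Binomial(depth, ratio) instead of fixing it.
    """
    if rng is None:
        raise ValueError("an explicit rng is required for reproducibility")
    if tumor_table.is_empty() or background_table.is_empty():
        raise ValueError("both source tables must be nonempty")
    if spec.count_mode == "binomial":
        n_tumor = int(rng.binomial(spec.depth, spec.ratio))
    else:
        n_tumor = int(math.floor(spec.ratio * spec.depth + 0.5))
    n_tumor = min(n_tumor, spec.depth)

    out = DensityTable(sample_id or
                       f"spike_{tumor_table.sample_id}_in_{background_table.sample_id}")
    for src, k in ((tumor_table, n_tumor),
                   (background_table, spec.depth - n_tumor)):
        if k == 0:
            continue
        m, n, p = _sampling_probs(src)
        draws = rng.multinomial(k, p)
        for mi, ni, ci in zip(m, n, draws):
            if ci:
                out.add(int(mi), int(ni), int(ci))
    return out


def build_spikein_cohort(
    tumor_tables: Mapping[str, DensityTable],
    background_tables: Mapping[str, DensityTable],
    spec: AdmixtureSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, DensityTable], dict[str, DensityTable]]:
    """One spike-in case per background sample; controls are the originals.

    Each background sample is paired with a tumor sample drawn uniformly
    with replacement (there may be fewer tumors than backgrounds), so the
    case set has the same size as the background set.
    """
    if not tumor_tables or not background_tables:
        raise ValueError("need at least one tumor and one background sample")
    tumor_ids = sorted(tumor_tables)
    cases: dict[str, DensityTable] = {}
    for bg_id in sorted(background_tables):
        t_id = tumor_ids[int(rng.integers(len(tumor_ids)))]
        sid = f"case_{bg_id}"
        cases[sid] = spike_in(tumor_tables[t_id], background_tables[bg_id],
                              spec, rng, sample_id=sid)
    controls = {f"control_{k}": DensityTable(f"control_{k}", v.counts)
                for k, v in background_tables.items()}
    return cases, controls


def _cohort_aucs(cases: Mapping[str, DensityTable],
                 controls: Mapping[str, DensityTable],
                 md_grid) -> tuple[float, float, float]:
    """(best md on grid, its AUC, mean-methylation AUC) for one cohort."""
    tables = {**cases, **controls}
    labels = {k: ("case" if k in cases else "control") for k in tables}
    scores = score_samples(tables, labels, md_grid=md_grid, measure="fraction")
    best_md, best_auc = None, -np.inf
    for md in scores[0].md_grid:
        _, _, _, auc = roc_at_md(scores, md)
        if auc > best_auc:
            best_md, best_auc = md, auc
    y = np.array([1] * len(cases) + [0] * len(controls))
    x = np.array([mean_locus_methylation(t) for t in cases.values()]
                 + [mean_locus_methylation(t) for t in controls.values()])
    mean_auc = float(roc_auc_score(y, x))
    return float(best_md), float(best_auc), mean_auc


def dilution_experiment(
    tumor_tables: Mapping[str, DensityTable],
    background_tables: Mapping[str, DensityTable],
    ratios: Sequence[float],
    n_iterations: int = 50,
    seed: int | None = None,
    depth: int | None = None,
    md_grid=None,
    count_mode: str = "fixed",
) -> DilutionResult:
    """Repeat the spike-in/classify cycle over a ladder of dilution ratios.

    Per iteration and ratio, a fresh cohort is built and the best
    density-cutoff AUC (over the grid) and the mean-methylation AUC are
    recorded.  Summaries report the mean AUC with a 95% percentile
    interval over iterations.
    """
    if seed is None:
        raise ValueError("dilution_experiment requires an explicit seed")
    if md_grid is None:
        md_grid = DEFAULT_MD_GRID
    rng = np.random.default_rng(seed)
    rows = []
    for ratio in ratios:
        d = depth if depth is not None else default_depth(ratio)
        spec = AdmixtureSpec(ratio=ratio, depth=d,
                             n_iterations=n_iterations, seed=seed,
                             count_mode=count_mode)
        for it in range(n_iterations):
            cases, controls = build_spikein_cohort(
                tumor_tables, background_tables, spec, rng)
            best_md, auc_md, auc_mean = _cohort_aucs(cases, controls, md_grid)
            rows.append((ratio, d, it, best_md, auc_md, auc_mean))
    per_it = pd.DataFrame(rows, columns=["ratio", "depth", "iteration",
                                         "best_md", "auc_best_md",
                                         "auc_mean_meth"])
    summ = []
    for ratio, grp in per_it.groupby("ratio"):
        for col, name in (("auc_best_md", "density_cutoff"),
                          ("auc_mean_meth", "mean_methylation")):
            vals = grp[col].to_numpy()
            lo, hi = np.quantile(vals, [0.025, 0.975])
            summ.append((ratio, name, vals.mean(), float(lo), float(hi)))
    summary = pd.DataFrame(summ, columns=["ratio", "classifier", "mean_auc",
                                          "ci_lo", "ci_hi"])
    return DilutionResult(per_iteration=per_it, summary=summary, seed=seed)


def probability_of_improvement(aucs_md: Sequence[float],
                               aucs_mean: Sequence[float]) -> float:
    """Probability that a density-cutoff run outperforms a mean-methylation run.

    Treats the two AUC collections as test results of cases and controls
    respectively and returns the AUC of that comparison — the all-pairs
    probability with ties counted 1/2 (Mann–Whitney U over n1*n2).
    """
    a = np.asarray(aucs_md, dtype=float)
    b = np.asarray(aucs_mean, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both AUC lists must be nonempty")
    diff = a[:, None] - b[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (a.size * b.size))
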