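"""Marker selection, repeated splits, and linear-SVM score combination.

Candidate marker probes are filtered and ranked on array beta values;
samples are repeatedly split in half into train/test runs; per-marker
density-cutoff scores (cutoffs learned strictly inside each training
partition) feed a linear-kernel SVM whose continuous output drives the
per-run ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from epidense.classifier import (
    DEFAULT_MD_GRID,
    build_cutoff_grid,
    optimize_cutoffs,
    score_samples,
)
from epidense.density import DensityTable, MarkerRegion, as_fraction

__all__ = [
    "BetaMatrix",
    "SplitPlan",
    "select_markers",
    "make_splits",
    "train_combined",
    "marker_features",
    "run_combined_analysis",
    "evaluate_runs",
    "compare_auc_sets",
]


@dataclass
class BetaMatrix:
    """Probe x sample beta-value matrix with coordinates and classes.

    ``values``: DataFrame indexed by probe id, columns are sample ids.
    ``probe_coords``: DataFrame indexed by probe id with ``chrom``/``pos``.
    ``sample_class``: Series mapping sample id to {tumor, normal, plasma}.
    ``pairs``: matched (tumor_sample, normal_sample) id pairs.
    """

    values: pd.DataFrame
    probe_coords: pd.DataFrame
    sample_class: pd.Series
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        for t, nrm in self.pairs:
            if t not in self.values.columns or nrm not in self.values.columns:
                raise ValueError(f"pair ({t!r}, {nrm!r}) not resolvable in matrix")

    @property
    def normal_samples(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "normal"].index)


@dataclass
class SplitPlan:
    """Materialized repeated stratified train/test splits."""

    n_runs: int
    train_fraction: float
    seed: int
    runs: list[tuple[list[str], list[str]]] = field(default_factory=list)


def select_markers(beta: BetaMatrix, k: int,
                   candidate_regions: Sequence[MarkerRegion],
                   snp_blocklist: Sequence[str] = ()) -> pd.DataFrame:
    """Rank hypermethylated probes and return the top ``k``.

    A probe passes when it (1) is not on the SNP blocklist, (2) has a
    maximum beta across normal samples below 0.2, (3) is hypermethylated
    in tumors (positive median paired tumor-minus-normal difference), and
    (4) falls inside a candidate region.  Passing probes are ranked by
    the median paired difference, descending.
    """
    blocked = set(snp_blocklist)
    normals = beta.normal_samples
    rows = []
    for probe in beta.values.index:
        if probe in blocked:
            continue
        coords = beta.probe_coords.loc[probe]
        in_region = any(
            r.chrom == coords["chrom"] and r.start0 <= coords["pos"] < r.end0
            for r in candidate_regions)
        if not in_region:
            continue
        if normals and beta.values.loc[probe, normals].max() >= 0.2:
            continue
        diffs = [beta.values.loc[probe, t] - beta.values.loc[probe, nrm]
                 for t, nrm in beta.pairs]
        med = float(np.median(diffs)) if diffs else 0.0
        if med <= 0:
            continue
        rows.append((probe, coords["chrom"], int(coords["pos"]), med))
    out = pd.DataFrame(rows, columns=["probe", "chrom", "pos",
                                      "median_paired_diff"])
    out = out.sort_values(["median_paired_diff", "probe"],
                          ascending=[False, True]).reset_index(drop=True)
    if out.empty:
        warnings.warn("no probes passed the marker filters", stacklevel=2)
    elif k > len(out):
        warnings.warn(f"requested {k} markers but only {len(out)} passed "
                      "the filters; returning all", stacklevel=2)
    return out.head(k)


def make_splits(sample_ids: Sequence[str], labels: Mapping[str, str],
                n_runs: int = 10, train_fraction: float = 0.5,
                seed: int = 0) -> SplitPlan:
    """Repeated stratified random splits, reproducible from the seed.

    Within each run the train/test partition is disjoint and exhaustive;
    per class, the two sides differ in size by at most one.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for sid in sample_ids:
        by_class.setdefault(labels[sid], []).append(sid)
    runs = []
    for _ in range(n_runs):
        train: list[str] = []
        test: list[str] = []
        for cls in sorted(by_class):
            ids = list(by_class[cls])
            rng.shuffle(ids)
            n_train = int(round(train_fraction * len(ids)))
            train.extend(ids[:n_train])
            test.extend(ids[n_train:])
        runs.append((sorted(train), sorted(test)))
    return SplitPlan(n_runs=n_runs, train_fraction=train_fraction,
                     seed=seed, runs=runs)


def marker_features(
    marker_tables: Mapping[str, Mapping[str, DensityTable]],
    labels: Mapping[str, str],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    md_grid=None,
    measure: str = "normalized_read_count",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Per-marker sample scores at each marker's learned density cutoff.

    For every marker the cutoff pair is optimized on the training samples
    only; the training and test feature columns are the per-sample measure
    at that marker's optimal density cutoff.  Returns
    ``(train_features, test_features, md_stars)``.
    """
    if md_grid is None:
        md_grid = DEFAULT_MD_GRID
    train_cols, test_cols, md_stars = {}, {}, {}
    for marker, tables in marker_tables.items():
        train_tables = {s: tables[s] for s in train_ids}
        train_scores = score_samples(train_tables,
                                     {s: labels[s] for s in train_ids},
                                     md_grid=md_grid, measure=measure)
        opt = optimize_cutoffs(build_cutoff_grid(train_scores))
        md_stars[marker] = float(opt.md_star)
        all_tables = {s: tables[s] for s in (*train_ids, *test_ids)}
        all_scores = score_samples(all_tables,
                                   {s: labels[s] for s in all_tables},
                                   md_grid=md_grid, measure=measure)
        at_md = {s.sample_id: s.score_at(opt.md_star) for s in all_scores}
        train_cols[marker] = [at_md[s] for s in train_ids]
        test_cols[marker] = [at_md[s] for s in test_ids]
    train_f = pd.DataFrame(train_cols, index=list(train_ids))
    test_f = pd.DataFrame(test_cols, index=list(test_ids))
    return train_f, test_f, md_stars


def train_combined(train_features: pd.DataFrame,
                   train_labels: Sequence[str],
                   seed: int = 0, C: float = 1.0) -> SVC:
    """Fit the linear-kernel SVM combining per-marker scores.

    Deterministic given the seed; the fitted model's ``decision_function``
    provides the continuous output used for ROC construction.
    """
    y = np.array([1 if l == "case" else 0 for l in train_labels])
    model = SVC(kernel="linear", random_state=seed, C=C)
    model.fit(train_features.to_numpy(dtype=float), y)
    return model


def run_combined_analysis(
    marker_tables: Mapping[str, Mapping[str, DensityTable]],
    labels: Mapping[str, str],
    plan: SplitPlan,
    md_grid=None,
    measure: str = "normalized_read_count",
    svm_seed: int = 0,
    svm_C: float = 1.0,
) -> list[dict]:
    """Full per-run pipeline: learn cutoffs, fit SVM, score the test set.

    Returns one dict per run with the test labels/scores, ROC, AUC, and
    the per-marker learned density cutoffs.
    """
    results = []
    for run_idx, (train_ids, test_ids) in enumerate(plan.runs):
        train_f, test_f, md_stars = marker_features(
            marker_tables, labels, train_ids, test_ids,
            md_grid=md_grid, measure=measure)
        model = train_combined(train_f, [labels[s] for s in train_ids],
                               seed=svm_seed, C=svm_C)
        y_test = np.array([1 if labels[s] == "case" else 0 for s in test_ids])
        x_test = model.decision_function(test_f.to_numpy(dtype=float))
        fpr, tpr, _ = roc_curve(y_test, x_test)
        results.append({
            "run": run_idx,
            "test_ids": list(test_ids),
            "y_test": y_test,
            "scores": x_test,
            "fpr": fpr,
            "tpr": tpr,
            "auc": float(roc_auc_score(y_test, x_test)),
            "md_stars": md_stars,
            "svm_C": svm_C,
            "svm_seed": svm_seed,
        })
    return results


def evaluate_runs(run_results: Sequence[dict],
                  fpr_grid: np.ndarray | None = None) -> dict:
    """Summarize repeated runs: AUC list, mean ROC, and SD band.

    The mean ROC is computed by vertical averaging of each run's curve on
    a common 101-point FPR grid.
    """
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = []
    for r in run_results:
        tprs.append(np.interp(fpr_grid, r["fpr"], r["tpr"]))
    tprs = np.stack(tprs)
    aucs = np.array([r["auc"] for r in run_results])
    return {
        "aucs": aucs,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "fpr_grid": fpr_grid,
        "mean_tpr": tprs.mean(axis=0),
        "sd_tpr": tprs.std(axis=0, ddof=0),
    }


def compare_auc_sets(aucs_a: Sequence[float],
                     aucs_b: Sequence[float]) -> float:
    """Two-sided rank-sum p value between two AUC collections."""
    a, b = np.asarray(aucs_a, float), np.asarray(aucs_b, float)
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
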