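from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidense.classifier import (
    DEFAULT_MD_GRID,
    PRESETS,
    SampleScoreSet,
    baseline_scores,
    bootstrap_auc_ci,
    build_cutoff_grid,
    classify,
    optimize_cutoffs,
    performance_profile,
    roc_at_md,
    score_samples,
)
from epidense.density import DensityTable

from tests._oracles import oracle_auc, oracle_optimum
from tests.conftest import labels_from_ids, random_micro_cohort


def make_scores(case_vals, ctrl_vals, grid=(Fraction(0),)):
    """Wrap flat per-sample scores (same value at every md) as score sets."""
    out = []
    for i, v in enumerate(case_vals):
        out.append(SampleScoreSet(f"case_{i}", "case", tuple(grid),
                                  np.full(len(grid), v)))
    for i, v in enumerate(ctrl_vals):
        out.append(SampleScoreSet(f"control_{i}", "control", tuple(grid),
                                  np.full(len(grid), v)))
    return out


# ---------------------------------------------------------------------------
# score_samples
# ---------------------------------------------------------------------------

def test_rare_dense_reads_score_by_hand_tally():
    t = DensityTable("case_0", {(0, 14): 98, (12, 14): 2})
    scores = score_samples({"case_0": t}, {"case_0": "case"})
    (s,) = scores
    for md, val in zip(s.md_grid, s.scores):
        if 0 < md <= Fraction(12, 14):
            assert val == pytest.approx(0.02)
        elif md > Fraction(12, 14):
            assert val == 0.0
    # md = 0 uses the strict rule: only methylated fragments count
    assert s.score_at(0) == pytest.approx(0.02)


def test_per_ml_count_arithmetic():
    t = DensityTable("s", {(14, 14): 2, (0, 14): 50})
    (s,) = score_samples({"s": t}, {"s": "case"}, measure="per_ml_count",
                         normalizers={"s": 0.5})
    assert s.score_at(1) == pytest.approx(4.0)  # 2 epialleles / 0.5 mL


def test_empty_grid_errors():
    t = DensityTable("s", {(1, 2): 1})
    with pytest.raises(ValueError, match="empty"):
        score_samples({"s": t}, {"s": "case"}, md_grid=[])


def test_missing_normalizer_errors():
    t = DensityTable("s", {(1, 2): 1})
    with pytest.raises(ValueError):
        score_samples({"s": t}, {"s": "case"}, measure="per_ml_count")


def test_scores_monotone_non_increasing(small_cohort):
    tables, labels, _ = small_cohort
    for s in score_samples(tables, labels):
        assert np.all(np.diff(s.scores) <= 1e-15)


def test_locality_adding_low_density_read_keeps_count_measure():
    t = DensityTable("s", {(10, 14): 3, (0, 14): 20})
    t2 = DensityTable("s", {**t.counts, (2, 14): 5})
    kw = dict(measure="per_ml_count", normalizers={"s": 1.0})
    (a,) = score_samples({"s": t}, {"s": "case"}, **kw)
    (b,) = score_samples({"s": t2}, {"s": "case"}, **kw)
    md = Fraction(3, 5)
    assert a.score_at(md) == b.score_at(md)  # 2/14 < 0.6: no effect


# ---------------------------------------------------------------------------
# cutoff grid
# ---------------------------------------------------------------------------

def test_separable_scores_give_perfect_corner():
    scores = make_scores([1.0, 1.0], [0.0, 0.0])
    grid = build_cutoff_grid(scores)
    efs, tpr, fpr = grid.ef_candidates[0], grid.tpr[0], grid.fpr[0]
    i = list(efs).index(1.0)
    assert tpr[i] == 1.0 and fpr[i] == 0.0


def test_identical_cohorts_have_tpr_equal_fpr():
    scores = make_scores([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    grid = build_cutoff_grid(scores)
    assert np.allclose(grid.tpr[0], grid.fpr[0])


def test_tpr_counts_at_least_threshold():
    scores = make_scores([0.1, 0.2, 0.3], [0.0])
    grid = build_cutoff_grid(scores)
    efs, tpr = grid.ef_candidates[0], grid.tpr[0]
    i = list(efs).index(0.2)
    assert tpr[i] == pytest.approx(2 / 3)


def test_single_class_errors():
    with pytest.raises(ValueError):
        build_cutoff_grid(make_scores([1.0], []))


def test_infinite_ef_row_gives_zero_fpr(small_cohort):
    tables, labels, _ = small_cohort
    grid = build_cutoff_grid(score_samples(tables, labels))
    for efs, fpr in zip(grid.ef_candidates, grid.fpr):
        assert efs[-1] == np.inf and fpr[-1] == 0.0


# ---------------------------------------------------------------------------
# optimizer vs brute force
# ---------------------------------------------------------------------------

def test_identical_case_control_vectors_j_zero():
    scores = make_scores([0.4], [0.4])
    opt = optimize_cutoffs(build_cutoff_grid(scores))
    assert opt.j_star == 0.0


def test_fig_style_toy_band_and_ties():
    # each case has >= 2 epialleles at density exactly 3/4, controls top
    # out at 0.5: every grid md in (0.5, 0.75] separates perfectly
    tables = {
        "case_A": DensityTable("case_A", {(3, 4): 2, (1, 14): 6, (0, 14): 10}),
        "case_B": DensityTable("case_B", {(3, 4): 3, (1, 14): 2, (0, 14): 10}),
        "control_C": DensityTable("control_C", {(2, 4): 2, (1, 14): 8,
                                                (0, 14): 10}),
        "control_D": DensityTable("control_D", {(2, 4): 1, (1, 14): 1,
                                                (0, 14): 10}),
    }
    labels = labels_from_ids(tables)
    scores = score_samples(tables, labels, measure="per_ml_count",
                           normalizers={k: 1.0 for k in tables})
    opt = optimize_cutoffs(build_cutoff_grid(scores))
    assert opt.j_star == 1.0
    tie_mds = {float(md) for md, _ in opt.ties}
    assert tie_mds == {0.55, 0.6, 0.65, 0.7, 0.75}
    assert all(ef == 2.0 for _, ef in opt.ties)
    # canonical favors sensitivity: smallest md then smallest ef
    assert (float(opt.md_star), opt.ef_star) == (0.55, 2.0)
    j, ties = oracle_optimum(scores)
    assert j == 1.0
    assert {(float(md), ef) for md, ef in opt.ties} == ties


def test_optimizer_matches_exhaustive_oracle_on_random_cohorts():
    rng = np.random.default_rng(7)
    for _ in range(25):
        tables, labels = random_micro_cohort(rng)
        scores = score_samples(tables, labels)
        opt = optimize_cutoffs(build_cutoff_grid(scores))
        j, ties = oracle_optimum(scores)
        assert opt.j_star == pytest.approx(j, abs=1e-12)
        assert {(float(md), ef) for md, ef in opt.ties} == ties
        assert (float(opt.md_star), opt.ef_star) == min(ties)


def test_j_star_invariant_under_monotone_transform(small_cohort):
    tables, labels, _ = small_cohort
    scores = score_samples(tables, labels)
    opt = optimize_cutoffs(build_cutoff_grid(scores))
    warped = [SampleScoreSet(s.sample_id, s.label, s.md_grid,
                             np.exp(3 * s.scores) - 1, s.measure)
              for s in scores]
    opt_w = optimize_cutoffs(build_cutoff_grid(warped))
    assert opt.j_star == pytest.approx(opt_w.j_star, abs=1e-12)
    assert opt.j_star >= 0.0


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def test_separable_auc_one():
    scores = make_scores([0.9, 0.8], [0.1, 0.2])
    assert roc_at_md(scores, 0)[3] == 1.0


def test_all_ties_auc_half():
    scores = make_scores([0.5, 0.5], [0.5, 0.5])
    assert roc_at_md(scores, 0)[3] == 0.5


def test_auc_matches_u_statistic_oracle_on_random_cohorts():
    rng = np.random.default_rng(11)
    for _ in range(20):
        tables, labels = random_micro_cohort(rng)
        scores = score_samples(tables, labels)
        for md in DEFAULT_MD_GRID[::5]:
            auc = roc_at_md(scores, md)[3]
            cases = [s.score_at(md) for s in scores if s.label == "case"]
            ctrls = [s.score_at(md) for s in scores if s.label == "control"]
            assert auc == pytest.approx(oracle_auc(cases, ctrls), abs=1e-12)


def test_degenerate_class_errors():
    with pytest.raises(ValueError):
        roc_at_md(make_scores([1.0], []), 0)


# ---------------------------------------------------------------------------
# performance profile
# ---------------------------------------------------------------------------

def test_profile_flat_at_one_on_separable_band():
    tables = {
        "case_0": DensityTable("case_0", {(14, 14): 5, (0, 14): 95}),
        "case_1": DensityTable("case_1", {(13, 14): 4, (0, 14): 96}),
        "control_0": DensityTable("control_0", {(1, 14): 5, (0, 14): 95}),
        "control_1": DensityTable("control_1", {(0, 14): 100}),
    }
    scores = score_samples(tables, labels_from_ids(tables))
    prof = performance_profile(scores)
    band = prof[(prof.md_cutoff > 0.1) & (prof.md_cutoff < 0.93)]
    assert (band.auc == 1.0).all() and (band.youden_j == 1.0).all()


def test_profile_consistent_with_roc_calls(small_cohort):
    tables, labels, _ = small_cohort
    scores = score_samples(tables, labels)
    prof = performance_profile(scores)
    for _, row in prof.iterrows():
        assert row.auc == pytest.approx(
            roc_at_md(scores, Fraction(row.md_cutoff).limit_denominator(20))[3])


def test_profile_marks_global_optimum(small_cohort):
    tables, labels, _ = small_cohort
    scores = score_samples(tables, labels)
    prof = performance_profile(scores)
    opt = optimize_cutoffs(build_cutoff_grid(scores))
    marked = prof[prof.is_global_optimum]
    assert not marked.empty
    assert marked.youden_j.max() == pytest.approx(opt.j_star)


# ---------------------------------------------------------------------------
# classify / baselines
# ---------------------------------------------------------------------------

def test_score_exactly_at_ef_star_is_positive():
    t = DensityTable("s", {(12, 14): 2, (0, 14): 98})
    # fraction at md 0.6 is exactly 0.02
    assert classify(t, Fraction(3, 5), 0.02) == "positive"
    assert classify(t, Fraction(3, 5), 0.0200001) == "negative"


def test_no_methylated_reads_is_negative():
    t = DensityTable("s", {(0, 14): 10})
    assert classify(t, 0.6, 1e-9) == "negative"


def test_training_positive_rate_equals_grid_tpr(small_cohort):
    tables, labels, _ = small_cohort
    scores = score_samples(tables, labels)
    grid = build_cutoff_grid(scores)
    opt = optimize_cutoffs(grid)
    calls = [classify(tables[s.sample_id], opt.md_star, opt.ef_star)
             for s in scores if s.label == "case"]
    pos_rate = np.mean([c == "positive" for c in calls])
    i_md = grid.md_grid.index(opt.md_star)
    i_ef = list(grid.ef_candidates[i_md]).index(opt.ef_star)
    assert pos_rate == pytest.approx(grid.tpr[i_md][i_ef])


def test_msp_like_baseline_tally():
    t = DensityTable("s", {(14, 14): 1, (0, 14): 99})
    assert baseline_scores(t)["msp_like"] == pytest.approx(0.01)


def test_baselines_on_degenerate_tables():
    unmeth = DensityTable("u", {(0, 10): 20})
    b = baseline_scores(unmeth)
    assert b["mean_meth"] == 0.0 and b["msp_like"] == 0.0
    half = DensityTable("h", {(7, 14): 10})
    b = baseline_scores(half)
    assert b["mean_meth"] == pytest.approx(0.5) and b["msp_like"] == 0.0


def test_md_zero_row_matches_strict_methylated_fraction():
    t = DensityTable("s", {(0, 14): 90, (7, 14): 10})
    (s,) = score_samples({"s": t}, {"s": "case"})
    # md=0 is the mean-methylation-style proxy row: all methylated fragments
    assert s.score_at(0) == pytest.approx(0.1)


# ---------------------------------------------------------------------------
# presets and bootstrap
# ---------------------------------------------------------------------------

def test_published_presets_are_data_not_code():
    assert PRESETS["ovarian_plasma_melt"]["md_star"] == Fraction(3, 5)
    assert PRESETS["ovarian_plasma_melt"]["ef_star"] == pytest.approx(6.7)
    assert PRESETS["hcc_wgbs"]["md_star"] == Fraction(9, 20)


def test_bootstrap_ci_brackets_auc_and_is_seeded(small_cohort):
    tables, labels, _ = small_cohort
    scores = score_samples(tables, labels)
    auc, lo, hi = bootstrap_auc_ci(scores, Fraction(3, 5), n_replicates=200,
                                   seed=5)
    auc2, lo2, hi2 = bootstrap_auc_ci(scores, Fraction(3, 5),
                                      n_replicates=200, seed=5)
    assert (auc, lo, hi) == (auc2, lo2, hi2)
    assert lo <= auc <= hi
    with pytest.raises(ValueError):
        bootstrap_auc_ci(scores, 0.5, seed=None)


# ---------------------------------------------------------------------------
# J properties (hypothesis)
# ---------------------------------------------------------------------------

@given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=6),
       st.lists(st.floats(0, 1, width=32), min_size=1, max_size=6))
@settings(max_examples=100, deadline=None)
def test_j_star_non_negative_and_oracle_equal(case_vals, ctrl_vals):
    scores = make_scores(case_vals, ctrl_vals)
    opt = optimize_cutoffs(build_cutoff_grid(scores))
    j, ties = oracle_optimum(scores)
    assert opt.j_star >= 0.0
    assert opt.j_star == pytest.approx(j, abs=1e-12)
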