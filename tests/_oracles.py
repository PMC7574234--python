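"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the code paths they verify: AUC is all-pairs
counting, the cutoff optimum is a plain double loop over every candidate.
"""

from __future__ import annotations

import numpy as np


def oracle_auc(case_vals, ctrl_vals) -> float:
    """All-pairs comparison count: wins + half-ties over n1*n2."""
    wins = ties = 0
    for a in case_vals:
        for b in ctrl_vals:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(case_vals) * len(ctrl_vals))


def oracle_optimum(score_sets):
    """Exhaustive double loop over (md index, observed ef) candidates.

    Returns ``(j_star, ties)`` where ties is a set of
    ``(float(md), float(ef))`` pairs attaining the maximum, with +inf
    appended to the candidate efs at each md.
    """
    cases = [s for s in score_sets if s.label == "case"]
    ctrls = [s for s in score_sets if s.label == "control"]
    grid = cases[0].md_grid
    best = -np.inf
    ties = set()
    for j, md in enumerate(grid):
        observed = sorted({float(s.scores[j]) for s in score_sets})
        for ef in observed + [np.inf]:
            tpr = np.mean([s.scores[j] >= ef for s in cases])
            fpr = np.mean([s.scores[j] >= ef for s in ctrls])
            jval = tpr - fpr
            if jval > best + 1e-12:
                best = jval
                ties = {(float(md), float(ef))}
            elif abs(jval - best) <= 1e-12:
                ties.add((float(md), float(ef)))
    return float(best), ties
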