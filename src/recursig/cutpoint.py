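"""Min-p expression cutpoints and low/high status calling.

A cutpoint for a gene is learned on one reference cohort by scanning the
midpoints between consecutive distinct expression values and choosing the
threshold whose dichotomization gives the smallest uncorrected chi-square
p against the binary recurrence outcome (min-p criterion).  Statuses are
then called on the z-score scale in every cohort: value >= c is "high"
(+).  Two markers' calls combine into a 4-level crossed status, with a
2-level collapse of (-)(-) versus the rest.

The minimized p is optimistically biased (no multiplicity correction over
candidates); reports should treat it as a selection criterion, not as an
hypothesis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import ExpressionCohort
from .stats import pearson_chi_square

log = logging.getLogger(__name__)

CROSS_LEVELS = ("(-)(-)", "(+)(-)", "(-)(+)", "(+)(+)")


class CutpointError(ValueError):
    pass


@dataclass(frozen=True)
class Cutpoint:
    gene: str
    c: float
    p_min: float
    chi2_at_c: float
    n_candidates: int
    reference_cohort: str = ""


@dataclass(frozen=True)
class StatusCall:
    sample_id: str
    gene: str
    status: str  # "low" | "high"


@dataclass(frozen=True)
class CrossedStatus:
    sample_id: str
    level: str       # one of CROSS_LEVELS over the ordered gene pair
    collapsed: str   # "reference" for (-)(-), else "other"


def candidate_cutpoints(values, min_group_fraction: float = 0.10) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, keeping only
    candidates leaving at least ``min_group_fraction`` of samples on each
    side."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise CutpointError("need >= 2 samples")
    distinct = np.unique(v)
    if len(distinct) < 2:
        raise CutpointError("all values identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(v)
    keep = []
    for c in mids:
        low = int(np.sum(v < c))
        if low >= min_group_fraction * n and (n - low) >= min_group_fraction * n:
            keep.append(c)
    return np.asarray(keep)


def minp_cutpoint(values, outcome, min_group_fraction: float = 0.10,
                  gene: str = "", reference_cohort: str = "") -> Cutpoint:
    """Threshold minimizing the uncorrected 2x2 chi-square p of the
    dichotomized marker against the binary outcome.

    Ties in p are broken toward the smaller threshold.  Always returns the
    arg-min; a non-significant p_min is flagged in the log.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise CutpointError("outcome must contain both classes, coded 0/1")
    candidates = candidate_cutpoints(v, min_group_fraction)
    if len(candidates) == 0:
        raise CutpointError("no valid candidate cutpoint")
    best = None  # (chi2, c, res); larger chi2 = smaller p at df 1
    for c in candidates:  # ascending: first win keeps the smaller threshold
        high = v >= c
        table = [
            [int(np.sum(high & (y == 1))), int(np.sum(high & (y == 0)))],
            [int(np.sum(~high & (y == 1))), int(np.sum(~high & (y == 0)))],
        ]
        res = pearson_chi_square(table)
        # compare statistics with relative tolerance so mirror-image
        # tables (equal chi2 up to rounding) tie toward the smaller c
        if best is None or res.chi2 > best[0] * (1 + 1e-9) + 1e-12:
            best = (res.chi2, c, res)
    _, c, res = best
    if res.p_asymptotic > 0.05:
        log.warning("min-p cutpoint for %s is non-significant (p=%.3g)",
                    gene or "marker", res.p_asymptotic)
    return Cutpoint(
        gene=gene, c=float(c), p_min=float(res.p_asymptotic),
        chi2_at_c=float(res.chi2), n_candidates=len(candidates),
        reference_cohort=reference_cohort,
    )


def learn_cutpoint(cohort: ExpressionCohort, gene: str,
                   min_group_fraction: float = 0.10) -> Cutpoint:
    """Learn the min-p cutpoint for ``gene`` on a reference cohort's
    z-scored values against its recurrence outcome."""
    if gene not in cohort.values.index:
        raise CutpointError(f"gene {gene} absent from cohort {cohort.name}")
    labels = cohort.recurrence_labels()
    known = labels.isin(["recurrence", "norecurrence"])
    y = (labels[known] == "recurrence").astype(int).to_numpy()
    v = cohort.values.loc[gene, known[known].index].to_numpy(dtype=float)
    return minp_cutpoint(v, y, min_group_fraction, gene=gene,
                         reference_cohort=cohort.name)


def assign_expression_status(cohort: ExpressionCohort, cutpoint: Cutpoint) -> list[StatusCall]:
    """Call low/high status per sample: high iff value >= c (boundary
    values are high)."""
    if cutpoint.gene not in cohort.values.index:
        raise CutpointError(f"gene {cutpoint.gene} absent from cohort {cohort.name}")
    row = cohort.values.loc[cutpoint.gene]
    calls = [
        StatusCall(s, cutpoint.gene, "high" if row[s] >= cutpoint.c else "low")
        for s in cohort.samples
    ]
    statuses = {c.status for c in calls}
    if len(statuses) == 1:
        log.warning("%s/%s: degenerate status (all %s)",
                    cohort.name, cutpoint.gene, statuses.pop())
    return calls


def crossed_status(calls_a: Sequence[StatusCall], calls_b: Sequence[StatusCall]) -> list[CrossedStatus]:
    """Combine two markers' calls into the 4-level crossed status, plus the
    2-level collapse used for the (-)(-)-versus-rest comparison."""
    a = {c.sample_id: c.status for c in calls_a}
    b = {c.sample_id: c.status for c in calls_b}
    if set(a) != set(b):
        raise CutpointError("sample sets differ between the two markers")
    sign = {"low": "(-)", "high": "(+)"}
    out = []
    for sid in (c.sample_id for c in calls_a):
        level = sign[a[sid]] + sign[b[sid]]
        out.append(CrossedStatus(sid, level,
                                 "reference" if level == "(-)(-)" else "other"))
    return out
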