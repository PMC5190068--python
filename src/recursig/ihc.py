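"""Immunoreactive scoring of IHC staining and cohort-level analyses.

The immunoreactive score (IRS) of a case is the product of staining
intensity (0 negative, 1 weak, 2 moderate, 3 strong) and the positive-cell
percentage category (1: 0-25%, 2: 26-50%, 3: 51-75%, 4: 76-100%).  The
attainable products are {0,1,2,3,4,6,8,9,12}; scores 0-6 are called low
(-) and 8-12 high (+).  7, 10 and 11 are unreachable products, so the gap
between the two classes is harmless.

Two-rater inputs (paired intensity/percentage columns from blinded
pathologists) are merged by the mean rounded half-up per component before
scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cutpoint import CrossedStatus, StatusCall, crossed_status
from .stats import ContingencyResult, pearson_chi_square

log = logging.getLogger(__name__)

LEGAL_IRS = frozenset({0, 1, 2, 3, 4, 6, 8, 9, 12})
HIGH_MIN = 8  # IRS >= 8 is high; <= 6 is low


class IHCError(ValueError):
    pass


@dataclass(frozen=True)
class IHCScore:
    case_id: str
    intensity: int
    pct_category: int
    irs: int
    status: str  # low | high


def immunoreactive_score(intensity: int, pct_category: int, case_id: str = "") -> IHCScore:
    """IRS = intensity x percentage category, classified low (0-6) or
    high (8-12)."""
    if intensity not in (0, 1, 2, 3):
        raise IHCError(f"intensity {intensity} out of range 0-3")
    if pct_category not in (1, 2, 3, 4):
        raise IHCError(f"pct_category {pct_category} out of range 1-4")
    irs = intensity * pct_category
    return IHCScore(case_id, intensity, pct_category, irs,
                    "high" if irs >= HIGH_MIN else "low")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def consensus_component(a: int, b: int) -> int:
    """Two-rater consensus for one score component: mean, rounded half-up."""
    return _round_half_up((a + b) / 2.0)


def score_table(table: pd.DataFrame, marker: str) -> list[IHCScore]:
    """Score one marker from a cohort table with columns
    ``{marker}_intensity`` and ``{marker}_pct`` (optionally
    ``{marker}_intensity2`` / ``{marker}_pct2`` for a second rater).
    Cases with a missing component are excluded (logged)."""
    icol, pcol = f"{marker}_intensity", f"{marker}_pct"
    if icol not in table.columns or pcol not in table.columns:
        raise IHCError(f"columns {icol}/{pcol} required")
    if table["case_id"].duplicated().any():
        dup = table.loc[table["case_id"].duplicated(), "case_id"].tolist()
        raise IHCError(f"duplicate case_id(s): {dup}")
    scores = []
    dropped = 0
    for _, row in table.iterrows():
        i, p = row[icol], row[pcol]
        if pd.isna(i) or pd.isna(p):
            dropped += 1
            continue
        i, p = int(i), int(p)
        if f"{icol}2" in table.columns and not pd.isna(row[f"{icol}2"]):
            i = consensus_component(i, int(row[f"{icol}2"]))
        if f"{pcol}2" in table.columns and not pd.isna(row[f"{pcol}2"]):
            p = consensus_component(p, int(row[f"{pcol}2"]))
        scores.append(immunoreactive_score(i, p, case_id=str(row["case_id"])))
    if dropped:
        log.info("%s: excluded %d case(s) with missing IHC components", marker, dropped)
    return scores


def status_calls(scores: Sequence[IHCScore], marker: str) -> list[StatusCall]:
    return [StatusCall(s.case_id, marker, s.status) for s in scores]


def classify_ihc_status(
    table: pd.DataFrame, markers: Sequence[str] = ("kcnn4", "s100a14")
) -> pd.DataFrame:
    """Per-case low/high status for each marker plus the 4-level crossed
    group over the ordered marker pair.  Cases missing either marker are
    excluded."""
    per_marker = {m: score_table(table, m) for m in markers}
    calls = {m: status_calls(per_marker[m], m) for m in markers}
    common = set.intersection(*(set(c.sample_id for c in calls[m]) for m in markers))
    for m in markers:
        calls[m] = [c for c in calls[m] if c.sample_id in common]
    crossed = crossed_status(calls[markers[0]], calls[markers[1]])
    by_case = {c.sample_id: c for c in crossed}
    scores_by_case = {m: {s.case_id: s for s in per_marker[m]} for m in markers}
    rows = []
    for cid in (c.sample_id for c in calls[markers[0]]):
        row = {"case_id": cid}
        for m in markers:
            s = scores_by_case[m][cid]
            row[f"{m}_irs"] = s.irs
            row[f"{m}_status"] = s.status
        row["crossed"] = by_case[cid].level
        row["collapsed"] = by_case[cid].collapsed
        rows.append(row)
    return pd.DataFrame(rows)


def association_with_covariate(
    status: pd.Series, covariate: pd.Series
) -> ContingencyResult:
    """Chi-square association of a marker's low/high status with a
    categorical covariate (covariate levels x status)."""
    tab = pd.crosstab(covariate, status)
    return pearson_chi_square(tab.to_numpy())
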