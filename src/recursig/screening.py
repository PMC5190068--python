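"""Signal-to-noise-ratio gene screening across cohorts.

For each gene the SNR between the recurrence classes is
``|mu1 - mu2| / (sigma1 + sigma2)`` with group 1 = recurrence and group 2 =
norecurrence (sample SDs, ddof=1).  The per-cohort top-k gene sets are then
intersected across cohorts to obtain the cross-cohort signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort

log = logging.getLogger(__name__)


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class GeneScore:
    gene: str
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    n1: int
    n2: int
    snr: Optional[float]  # None for degenerate genes (sigma1 + sigma2 == 0)

    @property
    def degenerate(self) -> bool:
        return self.snr is None


def snr_score(cohort: ExpressionCohort) -> list[GeneScore]:
    """Score every gene of a normalized cohort by SNR between recurrence
    classes.  Genes whose two group SDs are both zero are flagged
    degenerate and carry no SNR."""
    if not cohort.normalized:
        raise ScreeningError(f"{cohort.name}: cohort must be z-score normalized")
    labels = cohort.recurrence_labels()
    g1 = labels.index[labels == "recurrence"]
    g2 = labels.index[labels == "norecurrence"]
    if len(g1) < 2 or len(g2) < 2:
        raise ScreeningError(
            f"{cohort.name}: degenerate class (recurrence={len(g1)}, norecurrence={len(g2)})"
        )
    X1 = cohort.values[list(g1)].to_numpy(dtype=float)
    X2 = cohort.values[list(g2)].to_numpy(dtype=float)
    mu1, mu2 = X1.mean(axis=1), X2.mean(axis=1)
    s1, s2 = X1.std(axis=1, ddof=1), X2.std(axis=1, ddof=1)
    denom = s1 + s2
    scores = []
    for i, gene in enumerate(cohort.genes):
        snr = abs(mu1[i] - mu2[i]) / denom[i] if denom[i] > 0 else None
        scores.append(
            GeneScore(gene, float(mu1[i]), float(mu2[i]), float(s1[i]), float(s2[i]),
                      len(g1), len(g2), None if snr is None else float(snr))
        )
    return scores


def screen_top_k(scores: Sequence[GeneScore], k: int = 2000) -> list[str]:
    """The k genes with largest SNR (degenerate genes excluded).

    Genes tied with the k-th ranked SNR are all kept, so the returned set
    may exceed k (logged).  Fewer than k usable genes returns all of them.
    """
    if k < 1:
        raise ScreeningError("k must be >= 1")
    usable = [s for s in scores if not s.degenerate]
    if not usable:
        raise ScreeningError("no non-degenerate gene scores")
    ranked = sorted(usable, key=lambda s: (-s.snr, s.gene))
    if len(ranked) <= k:
        if len(ranked) < k:
            log.warning("only %d usable genes for top-%d request", len(ranked), k)
        return [s.gene for s in ranked]
    cutoff = ranked[k - 1].snr
    kept = [s.gene for s in ranked if s.snr >= cutoff]
    if len(kept) > k:
        log.warning("tie at rank %d: keeping %d genes", k, len(kept))
    return kept


def intersect_signatures(top_sets: Sequence[Iterable[str]]) -> list[str]:
    """Alphabetically ordered intersection of per-cohort top gene sets."""
    if len(top_sets) < 2:
        raise ScreeningError("need >= 2 gene sets to intersect")
    sets = [set(s) for s in top_sets]
    common = set.intersection(*sets)
    if not common:
        log.warning("signature intersection is empty")
    return sorted(common)


def scores_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    """Tabular view (gene, mu1, mu2, sigma1, sigma2, snr, rank)."""
    df = pd.DataFrame([s.__dict__ for s in scores])
    df["rank"] = df["snr"].rank(ascending=False, method="min")
    return df.sort_values("rank").reset_index(drop=True)


def screen_cohorts(
    cohorts: Sequence[ExpressionCohort], top_k: int = 2000
) -> tuple[list[str], dict[str, list[str]]]:
    """Full screening pass: per-cohort SNR top-k, then intersection."""
    per_cohort = {c.name: screen_top_k(snr_score(c), top_k) for c in cohorts}
    return intersect_signatures(list(per_cohort.values())), per_cohort
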