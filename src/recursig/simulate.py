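"""Synthetic multi-cohort generators.

These generators produce data with the statistical structure the analysis
assumes, so every downstream stage (screening, cutpoints, survival,
classification, network inference, IHC scoring) is testable without any
external cohort:

* several expression cohorts with a minority of "planted" recurrence
  associated genes (correlated Gaussians whose means are shifted between
  recurrence classes, in units of the within-group SD),
* right-censored recurrence and death times whose hazard is scaled for
  samples above the planted-gene median,
* copy-number (ordinal -2..+2) positively and promoter-methylation (beta in
  [0,1]) negatively coupled to expression through latent Gaussians,
* a STRING-style interaction fixture with a planted 4-gene chain, decoy
  neighbors and a sub-threshold shortcut,
* an IHC cohort with intensity / percentage-category scores and the usual
  clinicopathological covariates.

Default cohort sizes mirror the seven public serous ovarian cancer cohorts
the analysis was designed around (305, 156, 37, 77, 17, 120, 126 eligible
samples); the default recurrence prevalence of 0.57 matches their pooled
event fraction and the default median time to recurrence is 450 days.

Reproducibility: one global integer seed; each cohort draws from the
sub-stream ``default_rng([seed, cohort_index])`` so adding a cohort never
reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import ClinicalRecord, ExpressionCohort

#: eligible sample counts of the seven reference cohorts
DEFAULT_COHORT_SIZES = (305, 156, 37, 77, 17, 120, 126)
#: baseline median days from end of first-line therapy to recurrence
EVENT_MEDIAN_DAYS = 450.0
#: all generated day fields sit above the 90-day eligibility threshold
DAY_OFFSET = 91.0
#: latent standard-normal quantiles bounding the 5 CNA states, so that
#: homozygous states are rare (2.5% / 13.5% / 68% / 13.5% / 2.5%)
CNA_QUANTILES = (0.025, 0.16, 0.84, 0.975)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGene:
    """A recurrence-associated gene with target effect size delta
    (difference of group means in units of the within-group SD)."""

    name: str
    delta: float = 1.0


@dataclass
class SimulationParams:
    n_cohorts: int = 7
    n_per_cohort: Sequence[int] = DEFAULT_COHORT_SIZES
    n_genes: int = 1000
    planted_genes: Sequence[PlantedGene] = (
        PlantedGene("KCNN4", 1.0),
        PlantedGene("S100A14", 1.0),
    )
    planted_correlation: float = 0.5
    recurrence_prevalence: float = 0.57
    hazard_ratio_high: float = 2.0
    censoring_rate: float = 0.43
    cna_coupling: float = 0.6
    methylation_coupling: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cohort) != self.n_cohorts:
            raise SimulationError("n_per_cohort length must equal n_cohorts")
        for frac in (self.recurrence_prevalence, self.censoring_rate):
            if not 0 <= frac <= 1:
                raise SimulationError(f"fraction {frac} outside [0,1]")
        if not -1 < self.planted_correlation < 1:
            raise SimulationError("planted_correlation outside (-1,1)")
        if self.hazard_ratio_high <= 0:
            raise SimulationError("hazard_ratio_high must be positive")
        if len(self.planted_genes) > self.n_genes:
            raise SimulationError("more planted genes than genes")
        names = [g.name for g in self.planted_genes]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate planted gene names")


def _gene_universe(params: SimulationParams) -> list[str]:
    planted = [g.name for g in params.planted_genes]
    n_null = params.n_genes - len(planted)
    width = len(str(max(n_null, 1)))
    return planted + [f"NULL{i:0{width}d}" for i in range(n_null)]


def _planted_matrix(rng, n: int, deltas: np.ndarray, rho: float, z: np.ndarray) -> np.ndarray:
    """Correlated unit-variance Gaussians (equicorrelation rho) with the
    per-gene mean shift applied to the recurrence class."""
    p = len(deltas)
    cov = np.full((p, p), rho)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    return X + np.outer(z, deltas)


def generate_cohort(params: SimulationParams, index: int) -> ExpressionCohort:
    """Generate cohort ``index`` of the multi-cohort design."""
    n = int(params.n_per_cohort[index])
    deltas = np.array([g.delta for g in params.planted_genes], dtype=float)
    if np.any(deltas != 0) and n < 4:
        raise SimulationError("insufficient samples for a planted effect")
    rng = np.random.default_rng([params.seed, index])
    genes = _gene_universe(params)
    n_planted = len(params.planted_genes)

    z = rng.binomial(1, params.recurrence_prevalence, size=n)  # recurrence label
    planted = _planted_matrix(rng, n, deltas, params.planted_correlation, z)
    nulls = rng.standard_normal((params.n_genes - n_planted, n))
    X = np.vstack([planted.T, nulls])

    # hazard group: above the cohort median of the mean planted expression
    risk = planted.mean(axis=1)
    high = risk > np.median(risk)

    lam0 = np.log(2) / EVENT_MEDIAN_DAYS
    lam = lam0 * params.hazard_ratio_high ** high.astype(float)
    event_days = rng.exponential(1.0 / lam)
    # competing-exponentials identity: P(censor first) = lam_c/(lam_c+lam0)
    cr = min(max(params.censoring_rate, 1e-6), 1 - 1e-6)
    lam_c = lam0 * cr / (1 - cr)
    censor_days = rng.exponential(1.0 / lam_c, size=n)
    death_extra = rng.exponential(500.0, size=n)
    deceased = rng.binomial(1, 0.5, size=n)

    clinical: dict[str, ClinicalRecord] = {}
    sample_ids = [f"C{index}S{i:04d}" for i in range(n)]
    for i, sid in enumerate(sample_ids):
        recurrent = bool(z[i])
        followup = event_days[i] if recurrent else censor_days[i]
        death = DAY_OFFSET + followup + death_extra[i]
        clinical[sid] = ClinicalRecord(
            sample_id=sid,
            debulking="optimal",
            recurrence_status="recurrence" if recurrent else "norecurrence",
            days_to_tumor_recurrence=DAY_OFFSET + event_days[i] if recurrent else None,
            vital_status="deceased" if deceased[i] else "living",
            days_to_death=death,
            age=float(np.round(rng.normal(57, 9))),
            stage=int(rng.integers(1, 5)),
            grade=int(rng.integers(1, 4)),
            covariates={"days_to_last_followup": f"{DAY_OFFSET + followup:.6f}"},
        )
    values = pd.DataFrame(X, index=genes, columns=sample_ids)
    return ExpressionCohort(name=f"synthetic{index}", values=values, clinical=clinical)


def generate_multicohort(params: SimulationParams) -> list[ExpressionCohort]:
    """Generate all cohorts of the design (deterministic under seed)."""
    return [generate_cohort(params, i) for i in range(params.n_cohorts)]


def generate_genomic_covariates(
    cohort: ExpressionCohort,
    gene: str,
    cna_coupling: float,
    methylation_coupling: float,
    seed: int,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample CNA state (-2..+2) and methylation beta for one gene.

    CNA thresholds a latent Gaussian positively correlated with expression
    at ``cna_coupling`` into 5 ordinal bins with rare homozygous states;
    methylation is the logistic transform of a latent negatively correlated
    at ``methylation_coupling``.
    """
    for c in (cna_coupling, methylation_coupling):
        if not -1 < c < 1:
            raise SimulationError(f"coupling {c} outside (-1,1)")
    if gene not in cohort.values.index:
        raise SimulationError(f"gene {gene} not in cohort {cohort.name}")
    rng = np.random.default_rng(seed)
    x = cohort.values.loc[gene].to_numpy(dtype=float)
    sd = x.std()
    xs = (x - x.mean()) / (sd if sd > 0 else 1.0)
    n = len(xs)

    latent_cna = cna_coupling * xs + np.sqrt(1 - cna_coupling**2) * rng.standard_normal(n)
    cuts = norm.ppf(CNA_QUANTILES)
    cna = np.digitize(latent_cna, cuts) - 2  # -> -2..+2

    mc = methylation_coupling
    latent_me = mc * xs + np.sqrt(1 - mc**2) * rng.standard_normal(n)
    beta = expit(latent_me)
    idx = pd.Index(cohort.samples, name="sample_id")
    return (
        pd.Series(cna.astype(int), index=idx, name="cna"),
        pd.Series(beta, index=idx, name="methylation"),
    )


# ---------------------------------------------------------------------------
# interaction-network fixture

AXIS_CHAIN = ("KCNN4", "UBA52", "KLF4", "S100A14")


def generate_interaction_fixture(n_decoys: int = 3, seed: int = 0) -> pd.DataFrame:
    """STRING-style edge table with a planted high-confidence chain
    KCNN4-UBA52-KLF4-S100A14, ``n_decoys`` decoy neighbors per chain node
    and a sub-threshold KCNN4-S100A14 shortcut that a combined-score >= 600
    filter must remove."""
    if n_decoys < 0:
        raise SimulationError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    chain_scores = (900, 850, 800)
    for (a, b), s in zip(zip(AXIS_CHAIN, AXIS_CHAIN[1:]), chain_scores):
        rows.append((a, b, s))
    for node in AXIS_CHAIN:
        for j in range(n_decoys):
            rows.append((node, f"DEC_{node}_{j}", int(rng.integers(600, 1001))))
    if n_decoys > 0:
        rows.append(("KCNN4", "S100A14", int(rng.integers(100, 600))))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


# ---------------------------------------------------------------------------
# cutpoint recovery helper

def generate_bimodal_marker(
    n: int, separation: float = 2.0, within_sd: float = 0.5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Marker values from two Gaussian components tied to a binary outcome.

    Returns (values, outcome, true_threshold) where the generative
    threshold is the midpoint between the component means.
    """
    rng = np.random.default_rng(seed)
    outcome = rng.binomial(1, 0.5, size=n)
    values = rng.normal(outcome * separation, within_sd)
    return values, outcome, separation / 2.0


# ---------------------------------------------------------------------------
# IHC cohort

#: Table-3-like covariate marginals of a 127-case optimally debulked cohort
IHC_MARGINALS = {
    "age_ge60": 36 / 127,
    "stage_iii_iv": 90 / 127,
    "grade_probs": (8 / 127, 24 / 127, 95 / 127),
    "ca125_ge35": 32 / 127,
    "ascites_positive": 77 / 127,
    "size_ge5": 87 / 127,
    "lymph_positive": 26 / 127,
    "recurrence": 73 / 127,
}


def _categorize(latent: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    return np.digitize(latent, cuts)


def generate_ihc_cohort(n: int, effect: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """IHC scoring table with clinical covariates.

    Staining intensity (0-3) and percentage category (1-4) come from
    thresholded latent risks shifted by ``effect`` in recurrent cases, for
    two markers (KCNN4, S100A14).  Covariate marginals follow a 127-case
    reference cohort.  Recurrence-free follow-up days are included for
    survival analyses.
    """
    if n < 20:
        raise SimulationError("need n >= 20")
    rng = np.random.default_rng(seed)
    m = IHC_MARGINALS
    recur = rng.binomial(1, m["recurrence"], size=n)
    rows: dict = {"case_id": [f"IHC{i:04d}" for i in range(n)], "recurrence": recur}
    for marker in ("kcnn4", "s100a14"):
        latent_i = effect * recur + rng.standard_normal(n)
        latent_p = effect * recur + rng.standard_normal(n)
        rows[f"{marker}_intensity"] = _categorize(latent_i, (-0.8, 0.0, 0.8))
        rows[f"{marker}_pct"] = _categorize(latent_p, (-0.8, 0.0, 0.8)) + 1
    rows["age"] = np.where(rng.random(n) < m["age_ge60"],
                           rng.integers(60, 85, n), rng.integers(35, 60, n))
    rows["stage_iii_iv"] = rng.binomial(1, m["stage_iii_iv"], n)
    rows["grade"] = rng.choice([1, 2, 3], size=n, p=m["grade_probs"])
    rows["ca125_ge35"] = rng.binomial(1, m["ca125_ge35"], n)
    rows["ascites"] = rng.binomial(1, m["ascites_positive"], n)
    rows["size_ge5"] = rng.binomial(1, m["size_ge5"], n)
    rows["lymph_node"] = rng.binomial(1, m["lymph_positive"], n)
    lam0 = np.log(2) / EVENT_MEDIAN_DAYS
    days = np.where(
        recur == 1,
        rng.exponential(1 / (lam0 * 2.0 ** (rows["kcnn4_intensity"] >= 2)), n),
        rng.exponential(1 / lam0, n),
    )
    rows["days_to_event"] = DAY_OFFSET + days
    return pd.DataFrame(rows)
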