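"""Cohort containers and I/O.

An :class:`ExpressionCohort` couples one cohort's gene-by-sample expression
matrix with per-sample clinical annotation.  The operations here implement
the cohort preparation steps of the analysis: reading expression and
clinical TSV tables, restricting to eligible samples (optimal debulking,
known recurrence status, recurrence later than a minimum number of days
after the end of first-line therapy) and per-gene z-score normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEBULKING_VALUES = ("optimal", "suboptimal", "unknown")
RECURRENCE_VALUES = ("recurrence", "norecurrence", "unknown")
VITAL_VALUES = ("deceased", "living", "unknown")

#: clinical TSV columns parsed into typed ClinicalRecord fields
_KNOWN_COLUMNS = {
    "sample_id",
    "debulking",
    "recurrence_status",
    "days_to_tumor_recurrence",
    "vital_status",
    "days_to_death",
    "age",
    "stage",
    "grade",
}


class CohortError(ValueError):
    """Raised on malformed cohort inputs or contract violations."""


@dataclass
class ClinicalRecord:
    """Per-sample clinical annotation.

    Day fields must be non-negative when present, and a sample annotated as
    recurrent must carry its days-to-recurrence.
    """

    sample_id: str
    debulking: str = "unknown"
    recurrence_status: str = "unknown"
    days_to_tumor_recurrence: Optional[float] = None
    vital_status: str = "unknown"
    days_to_death: Optional[float] = None
    age: Optional[float] = None
    stage: Optional[int] = None
    grade: Optional[int] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.debulking not in DEBULKING_VALUES:
            raise CohortError(f"bad debulking value {self.debulking!r}")
        if self.recurrence_status not in RECURRENCE_VALUES:
            raise CohortError(f"bad recurrence_status {self.recurrence_status!r}")
        if self.vital_status not in VITAL_VALUES:
            raise CohortError(f"bad vital_status {self.vital_status!r}")
        for name in ("days_to_tumor_recurrence", "days_to_death"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise CohortError(f"{name} must be >= 0, got {v} for {self.sample_id}")
        if self.recurrence_status == "recurrence" and self.days_to_tumor_recurrence is None:
            raise CohortError(
                f"sample {self.sample_id}: recurrence without days_to_tumor_recurrence"
            )


@dataclass
class ExpressionCohort:
    """One cohort: a genes x samples matrix plus clinical records.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns; ``clinical`` maps sample_id to :class:`ClinicalRecord` (may
    be empty straight after reading an expression matrix).
    """

    name: str
    values: pd.DataFrame
    clinical: dict[str, ClinicalRecord] = field(default_factory=dict)
    normalized: bool = False
    zero_variance_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CohortError("duplicate gene symbols in matrix")
        if self.values.columns.has_duplicates:
            raise CohortError("duplicate sample ids in matrix")
        if self.clinical:
            missing = set(self.samples) - set(self.clinical)
            extra = set(self.clinical) - set(self.samples)
            if missing or extra:
                raise CohortError(
                    f"clinical records not bijective with samples "
                    f"(missing={sorted(missing)[:3]}, extra={sorted(extra)[:3]})"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def recurrence_labels(self) -> pd.Series:
        """Series of recurrence_status per sample (matrix column order)."""
        if not self.clinical:
            raise CohortError(f"cohort {self.name} has no clinical records")
        return pd.Series(
            [self.clinical[s].recurrence_status for s in self.samples],
            index=self.samples,
            name="recurrence_status",
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionCohort":
        keep = [s for s in self.samples if s in set(keep)]
        clin = {s: self.clinical[s] for s in keep} if self.clinical else {}
        return replace(self, values=self.values[keep], clinical=clin)


def read_expression_matrix(path, cohort_name: str) -> ExpressionCohort:
    """Read a genes x samples TSV (header = sample ids, first column = genes).

    Duplicate gene symbols are collapsed by keeping the highest-variance row
    (logged).  Non-numeric cells and duplicate sample ids are errors.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"{path}: no header") from exc
    # pandas mangles duplicate header names, so check the raw header line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({s for s in header if header.count(s) > 1})
    if dups:
        raise CohortError(f"{path}: duplicate sample id(s) {dups}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise CohortError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
        values[col] = parsed
    if values.index.has_duplicates:
        var = values.var(axis=1, ddof=1)
        order = np.argsort(-var.to_numpy(), kind="stable")
        values = values.iloc[order]
        dup_genes = values.index[values.index.duplicated(keep="first")].unique().tolist()
        values = values[~values.index.duplicated(keep="first")]
        # restore the input's first-appearance gene order
        values = values.loc[[g for g in raw.index.unique() if g in values.index]]
        log.info("%s: collapsed duplicate gene rows (kept max variance): %s",
                 cohort_name, dup_genes)
    return ExpressionCohort(name=cohort_name, values=values)


def write_expression_matrix(cohort: ExpressionCohort, path) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene")


_DAY_COLUMNS = ("days_to_tumor_recurrence", "days_to_death")


def _parse_optional_float(value, column, sample):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise CohortError(f"sample {sample}: bad {column} value {value!r}") from exc


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read a clinical TSV; unrecognized columns become string covariates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise CohortError(f"{path}: missing sample_id column")
    records = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        kwargs: dict = {"sample_id": sid}
        for col in ("debulking", "recurrence_status", "vital_status"):
            if col in df.columns and isinstance(row[col], str) and row[col]:
                kwargs[col] = row[col]
        for col in _DAY_COLUMNS + ("age",):
            if col in df.columns:
                kwargs[col] = _parse_optional_float(row[col], col, sid)
        for col in ("stage", "grade"):
            if col in df.columns:
                v = _parse_optional_float(row[col], col, sid)
                kwargs[col] = None if v is None else int(v)
        extra = {
            c: row[c]
            for c in df.columns
            if c not in _KNOWN_COLUMNS and isinstance(row[c], str) and row[c]
        }
        kwargs["covariates"] = extra
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "debulking": r.debulking,
            "recurrence_status": r.recurrence_status,
            "days_to_tumor_recurrence": r.days_to_tumor_recurrence,
            "vital_status": r.vital_status,
            "days_to_death": r.days_to_death,
            "age": r.age,
            "stage": r.stage,
            "grade": r.grade,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_clinical(cohort: ExpressionCohort, records: Iterable[ClinicalRecord]) -> ExpressionCohort:
    """Attach clinical records, restricting to samples present in both."""
    by_id = {r.sample_id: r for r in records}
    common = [s for s in cohort.samples if s in by_id]
    if not common:
        raise CohortError(f"{cohort.name}: no samples shared with clinical table")
    return replace(
        cohort,
        values=cohort.values[common],
        clinical={s: by_id[s] for s in common},
    )


def filter_eligible_samples(
    cohort: ExpressionCohort, min_recurrence_days: float = 90
) -> ExpressionCohort:
    """Keep optimally debulked samples with known recurrence status whose
    recurrence (if any) occurred strictly more than ``min_recurrence_days``
    after the end of first-line therapy.

    Samples relapsing at exactly the threshold are excluded (tie resolved
    toward exclusion).
    """
    if not cohort.clinical:
        raise CohortError(f"{cohort.name}: clinical records required for filtering")
    removed = {"debulking": 0, "recurrence_unknown": 0, "early_recurrence": 0}
    keep = []
    for s in cohort.samples:
        rec = cohort.clinical[s]
        if rec.debulking != "optimal":
            removed["debulking"] += 1
        elif rec.recurrence_status == "unknown":
            removed["recurrence_unknown"] += 1
        elif (
            rec.recurrence_status == "recurrence"
            and rec.days_to_tumor_recurrence <= min_recurrence_days
        ):
            removed["early_recurrence"] += 1
        else:
            keep.append(s)
    log.info("%s: eligibility filter removals %s", cohort.name, removed)
    if not keep:
        raise CohortError(f"{cohort.name}: empty cohort after filtering")
    return cohort.subset_samples(keep)


def zscore_normalize(cohort: ExpressionCohort) -> ExpressionCohort:
    """Standardize each gene row to mean 0, sample SD 1 (ddof=1).

    Zero-variance rows are left at 0 and recorded in
    ``zero_variance_genes``.
    """
    if cohort.n_samples < 2:
        raise CohortError(f"{cohort.name}: need >= 2 samples to normalize")
    X = cohort.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[flat] = 1.0
    Z = (X - mu) / sd
    Z[flat] = 0.0
    flagged = tuple(np.asarray(cohort.genes)[flat])
    if flagged:
        log.info("%s: %d zero-variance gene(s) left at 0", cohort.name, len(flagged))
    return replace(
        cohort,
        values=pd.DataFrame(Z, index=cohort.values.index, columns=cohort.values.columns),
        normalized=True,
        zero_variance_genes=flagged,
    )
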