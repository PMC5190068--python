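import numpy as np
import pandas as pd
import pytest

from recursig.cohort import ClinicalRecord, ExpressionCohort


def make_cohort(values: dict[str, list[float]], recurrence: list[str],
                name: str = "toy", normalized: bool = True) -> ExpressionCohort:
    """Small in-memory cohort; values maps gene -> per-sample expression."""
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    clinical = {}
    for s, status in zip(samples, recurrence):
        clinical[s] = ClinicalRecord(
            sample_id=s,
            debulking="optimal",
            recurrence_status=status,
            days_to_tumor_recurrence=200.0 if status == "recurrence" else None,
            covariates={"days_to_last_followup": "300.0"},
        )
    df = pd.DataFrame(values, index=samples).T
    df.columns = samples
    return ExpressionCohort(name=name, values=df, clinical=clinical,
                            normalized=normalized)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
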