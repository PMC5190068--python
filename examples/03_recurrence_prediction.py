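"""Cross-cohort recurrence prediction.

Trains a linear max-margin classifier on the two signature genes of one
cohort (5-repeat 10-fold stratified CV with an internal regularization
grid) and validates it on an independent cohort, reporting AUC with a
DeLong 95% confidence interval.
"""

import recursig as rs
from recursig.simulate import PlantedGene, SimulationParams, generate_multicohort

params = SimulationParams(
    n_cohorts=3, n_per_cohort=(305, 156, 120), n_genes=50,
    planted_genes=(PlantedGene("KCNN4", 1.0), PlantedGene("S100A14", 1.0)),
    seed=3,
)
cohorts = [rs.zscore_normalize(c) for c in generate_multicohort(params)]

spec = rs.ModelSpec(features=["KCNN4", "S100A14"], algorithm="linear_margin",
                    repeats=5, folds=10, seed=0)
model = rs.train_recurrence_model(cohorts[0], spec)
print(f"training cohort CV AUC: {model.cv_auc:.4f} "
      f"(chosen regularization {model.best_params})")

for name, res in rs.cross_cohort_validate(cohorts[0], cohorts[1:], spec).items():
    print(f"{name}: AUC={res.auc:.4f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f}, "
          f"{res.n_pos} recurrent / {res.n_neg} non-recurrent)")
# AUCs well above 0.5 in the held-out cohorts show the two-gene signature
# transfers across cohorts drawn from the same generative process.
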