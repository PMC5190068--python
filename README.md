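# recursig

Cross-cohort recurrence-signature analysis for optimally debulked serous
ovarian carcinoma (SOC).

Roughly half to three quarters of SOC patients relapse within 18 months of
first-line treatment, and clinical factors alone (age, stage, grade)
predict recurrence poorly. `recursig` implements, as a tested and reusable
Python library, the full analysis pipeline for deriving and validating a
small recurrence gene signature across many expression cohorts, for
scientists working with curated multi-cohort ovarian-cancer expression
data or their own IHC cohorts:

* **Screening** — per-gene signal-to-noise ratio between recurrence
  classes, SNR = |μ₁ − μ₂| / (σ₁ + σ₂); per-cohort top-k ranking and
  cross-cohort intersection of the top sets.
* **Status calling** — min-p expression cutpoints (threshold minimizing
  the uncorrected χ² p of the dichotomized marker against recurrence),
  low/high calls, and the 4-level crossed status of two markers.
* **Association & survival** — uncorrected Pearson χ² with an optional
  fixed-margin resampled null, Fisher's exact test with conditional-MLE
  odds ratios and exact CIs, K-sample permutation tests, TukeyHSD + BH,
  OLS, Kaplan–Meier with Greenwood errors, log-rank, and Cox
  proportional-hazards regression (Efron ties).
* **Prediction** — recurrence classifiers (linear-kernel SVM reference,
  plus RBF-SVM / random forest / neural net) with 5×10 stratified CV and
  cross-cohort validation AUCs with DeLong confidence intervals.
* **Network axis** — STRING-style graph filtered at combined score ≥ 600,
  two-seed 1-NN subnetwork, shortest "axis" path, greedy-modularity
  communities, per-cohort linear-Gaussian Bayesian networks learned by
  AIC hill climbing, cross-cohort direction consensus, and hypergeometric
  enrichment over user-supplied GMT gene sets.
* **IHC scoring** — immunoreactive score (intensity 0–3 × percentage
  category 1–4; low 0–6 / high 8–12) and the cohort-level association and
  Cox analyses.
* **Synthetic cohorts** — a first-class generator reproducing the
  statistical structure the analysis assumes (planted correlated
  recurrence genes, right-censored recurrence times, CNA/methylation
  couplings, an interaction fixture with a planted 4-gene chain, an IHC
  cohort), so every stage is testable without external data.

## Worked example

Recover a planted two-gene signature from seven synthetic cohorts and
test it (from `examples/01_snr_screening.py` and
`examples/02_cutpoints_and_survival.py`):

```python
import recursig as rs
from recursig.simulate import PlantedGene, SimulationParams, generate_multicohort

params = SimulationParams(
    n_cohorts=7, n_per_cohort=(150,) * 7, n_genes=1000,
    planted_genes=(PlantedGene("KCNN4", 1.0), PlantedGene("S100A14", 1.0)),
    seed=0,
)
cohorts = [rs.zscore_normalize(rs.filter_eligible_samples(c))
           for c in generate_multicohort(params)]
signature, _ = rs.screen_cohorts(cohorts, top_k=100)
print(signature)
```

prints

```
['KCNN4', 'S100A14']
```

— the intersection of seven top-100 SNR lists is exactly the two planted
genes (population SNR = Δ/(σ+σ) = 0.5 against a null spread of ~0.08 at
n = 150). Learning a cutpoint on a 305-sample reference cohort and testing
the resulting status prints:

```
KCNN4: cutpoint c=+0.052 (z-score), min p=3.84e-13, 244 candidates scanned
KCNN4 status vs recurrence: OR=5.96 (95% CI 3.53-10.24), p=2.31e-13
log-rank high vs low: chi2=57.82, p=2.88e-14
Cox (high vs low reference): HR=3.37 (95% CI 2.42-4.70), p=6.17e-13
```

i.e. samples above the learned z-score threshold recur substantially more
often and earlier. The other `examples/` scripts cover prediction
(`03`), the interaction axis and direction consensus (`04` — the shortest
path through the planted chain is `KCNN4 - UBA52 - KLF4 - S100A14`), IHC
scoring (`05`), and CNA/methylation correlates (`06`).

A thin CLI mirrors the library for shell-driven runs:

```sh
recursig simulate --config config.yaml   # or: screen, cutpoint, predict, network, ihc
```

Real cohorts replay through the same interface: point the YAML config at
per-cohort expression/clinical TSVs, a STRING-style edge table and an IHC
table.

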