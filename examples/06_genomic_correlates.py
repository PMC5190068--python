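"""Copy-number and methylation correlates of expression.

Generates CNA states (-2..+2, rare homozygous states) positively coupled
and promoter-methylation beta values negatively coupled to a gene's
expression, then applies the same statistics used on real cohorts: a
K-sample permutation test for expression across CNA states, TukeyHSD
pairwise comparisons with BH adjustment, and OLS of expression on
methylation.
"""

import numpy as np

import recursig as rs
from recursig.simulate import SimulationParams, generate_multicohort

params = SimulationParams(n_cohorts=1, n_per_cohort=(305,), n_genes=20, seed=2)
cohort = generate_multicohort(params)[0]

cna, meth = rs.generate_genomic_covariates(
    cohort, "KCNN4", cna_coupling=0.6, methylation_coupling=-0.5, seed=11)
expr = cohort.values.loc["KCNN4"].to_numpy()

print("CNA state counts:", dict(zip(*np.unique(cna, return_counts=True))))
levels = [l for l in np.unique(cna) if (cna == l).sum() >= 2]
mask = np.isin(cna, levels)
perm = rs.ksample_permutation_test(expr[mask], cna.to_numpy()[mask])
print(f"expression across CNA states: F={perm.statistic:.2f}, p={perm.p:.2e}")
for comp in rs.pairwise_tukey_bh(expr[mask], cna.to_numpy()[mask]):
    print(f"  {comp.group_a} vs {comp.group_b}: diff={comp.mean_diff:+.2f}, "
          f"BH-adjusted p={comp.p_adjusted:.3g}")

fit = rs.ols_regression(meth.to_numpy(), expr)
print(f"expression ~ methylation: slope={fit.slope:.2f}, r={fit.r:.2f}, "
      f"p={fit.p_slope:.2e}")
# Positive CNA coupling shows as increasing expression across states;
# negative methylation coupling as a negative regression slope.
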