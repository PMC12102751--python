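"""A ground-truthed synthetic cohort with age trends, fitted end to end.

Generates simulated infants aged 12-18 months whose generating
parameters drift with age (distractor boost and refixation bias fall,
decay rate rises, mean fixation duration shortens), fits every
individual age-blind, and shows (1) the resulting increase of target
looking with age and (2) that posterior-predictive simulations track
the individual differences in mean fixation duration.
"""

import numpy as np
from scipy import stats as sps

from lookdyn import (
    CohortConfig,
    MCMCConfig,
    cohort_pipeline,
    generate_cohort,
    prop_target_looking,
)

truth = generate_cohort(CohortConfig(n_individuals=10, master_seed=21))
ages = truth.individuals["age_months"].to_numpy()
props = [prop_target_looking(truth.sessions[s].scan_paths) for s in truth.subject_ids]
rho, p = sps.spearmanr(ages, props)
print("individual ages (months):", " ".join(f"{a:.1f}" for a in ages))
print("target-looking proportions:", " ".join(f"{x:.2f}" for x in props))
print(f"age vs target looking: Spearman rho = {rho:.2f} (p = {p:.3g})")

res = cohort_pipeline(
    truth, mcmc_config=MCMCConfig(n_walkers=24, n_steps=800), n_ppc_draws=8, seed=4
)
tab = res.comparison_table.set_index("measure")
r = tab.loc["mean_fixdur_all", "r"]
print(f"\nfitted all {len(res.chains)} individuals (failed: {len(res.failed)})")
print(f"data vs posterior-predictive mean fixation duration across "
      f"individuals: r = {r:.2f}")
cov = res.recovery_table["covered"].mean()
print(f"90% credible intervals cover the generating values for "
      f"{100 * cov:.0f}% of parameter x individual cells")
print("\nThe age trend in behaviour emerges although every fit is "
      "age-blind: it is carried by the recovered parameters.")
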