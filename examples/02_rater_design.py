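"""Rater-set assignment designs and missing-by-design data.

Builds the generalized rater-set design (cycling through all C(R, N_R)
rater subsets), checks the linking-connectivity condition, and verifies
the missing-data rate formula against the sampled records.
"""
import numpy as np

import facetlink as fl

J, I, R, N_R = 100, 10, 10, 2
design = fl.build_design(J, I, R, N_R)
print(f"{J * I} evaluation targets, each graded by exactly {N_R} of {R} raters")
print("rater loads (targets per rater):", design.rater_loads())

ok, msg = fl.connectivity_check(design)
print("connectivity:", msg)
# connectivity is what makes joint calibration (and hence linking) possible

rate = fl.missing_rate(R, N_R)
rng = np.random.default_rng(1)
params = fl.generate_parameters(J, I, R, 5, fl.DistributionSpec.standard(), rng)
data = fl.sample_dataset(params, design, rng)
empirical = (1 - data.n_records / (J * I * R)) * 100
print(f"missing rate: formula {rate:.0f}%, observed {empirical:.0f}% "
      f"({data.n_records} of {J * I * R} possible ratings)")
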