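"""The variance-ratio permutation test: exact and sampled paths.

Small arms enumerate every re-partition of the pooled differences; larger
arms draw 50 000 unique partitions and use the add-one p estimator.
"""

import numpy as np

from vesselrep import permutation_variance_test

# n = 4 per arm: C(8, 4) = 70 partitions, exact enumeration
g = np.array([10.0, -10.0, 10.0, -10.0])
u = np.array([1.0, -1.0, 1.0, -1.0])
res = permutation_variance_test(g, u, n_perm=50000, seed=0)
print(f"n=4  r_obs={res.r_obs:.0f}  p={res.p_value:.4f} "
      f"(exact over {res.n_permutations} partitions = minimal attainable 1/70)")

# n = 13 per arm: C(26, 13) = 10,400,600 partitions, sampling path
rng = np.random.default_rng(1)
g = rng.normal(0.0, 2.0, 13)   # gated differences vary twice as much
u = rng.normal(0.0, 1.0, 13)
res = permutation_variance_test(g, u, n_perm=50000, seed=2)
print(f"n=13 r_obs={res.r_obs:.2f}  p={res.p_value:.4f} "
      f"({res.n_permutations} unique sampled partitions)")
print()
print("A variance ratio near 4 with n=13 per arm typically lands p < 0.05:")
print("the test detects the gated arm's excess repeat-to-repeat variation")
print("without any distributional assumption on the differences.")
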