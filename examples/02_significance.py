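"""Compare the three P-value estimators on an enumerable problem.

On a 30-gene, 6-sample null dataset with query size 5, all C(30,5) = 142 506
subsets can be enumerated, so the exact tail probability is known. The plain
Monte Carlo and adaptive multilevel splitting estimators are run against it;
the multilevel scheme reaches small P-values that plain Monte Carlo cannot
resolve with the same budget.
"""

import numpy as np

from coregsearch import (
    exact_pvalue,
    make_null_dataset,
    multilevel_pvalue,
    preprocess_dataset,
    simple_mc_pvalue,
)
from itertools import combinations

ds = preprocess_dataset(make_null_dataset(30, 6, seed=7))
k = 5
idx = np.array(list(combinations(range(30), k)))
sums = ds.scores[idx].sum(axis=1)
all_scores = (sums**2).sum(axis=1) / (ds.total_ss * k) * 100.0

for quantile in (0.9, 0.999, 0.9999):
    s_obs = float(np.quantile(all_scores, quantile))
    exact = exact_pvalue(ds, k, s_obs)
    simple = simple_mc_pvalue(ds, k, s_obs, n_iter=10_000, rng_seed=1)
    multi = multilevel_pvalue(ds, k, s_obs, rng_seed=1)
    print(
        f"score {s_obs:7.3f}%  exact p = {exact:.3e}   "
        f"simple MC p = {simple.p:.3e}   multilevel p = {multi.p:.3e} "
        f"({multi.levels} levels)"
    )
print(
    "\nEach line: observed score, the exact subset-enumeration P-value, and the\n"
    "two Monte Carlo estimates. Agreement within sampling error is expected;\n"
    "the multilevel estimator stays accurate into the small-p regime."
)
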