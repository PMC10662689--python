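"""Permutation-based FDR on a toy matrix, checked against brute force.

For a 3-vs-3 design there are 10 distinct unordered ways to split the six
samples into two groups of three; leaving out the observed labelling gives 9
null permutations.  A feature's q-value compares how many permutation
statistics across ALL features exceed its observed |t| (expected false
positives) with how many observed |t| values exceed it (discoveries).
"""

import itertools

import numpy as np
from scipy import stats as sps

import redoxquant as rq
from redoxquant.stats import _row_t, permutation_fdr

rng = np.random.default_rng(0)
X = rng.normal(0, 1, size=(5, 6))
X[0, 3:] += 6.0   # one clearly shifted feature
X[1, 3:] += 1.0   # one borderline feature

idx1, idx2 = np.arange(3), np.arange(3, 6)
res = _row_t(X[:, idx1], X[:, idx2], min_valid=2)
q = permutation_fdr(res["t"], X, idx1, idx2, rq.PipelineConfig())

print("feature   t        p        q")
for i in range(5):
    print(f"f{i}   {res['t'][i]:+7.3f}  {res['p'][i]:.4f}  {q[i]:.4f}")

# independent brute-force q for the strongest feature
splits = [s for s in itertools.combinations(range(6), 3)
          if 0 in s and set(s) != {0, 1, 2}]
null = [abs(sps.ttest_ind([r[c] for c in range(6) if c not in s],
                          [r[c] for c in s], equal_var=True).statistic)
        for s in splits for r in X]
e_false = sum(v >= abs(res["t"][0]) for v in null) / len(splits)
print(f"\nbrute force for f0: E[false] = {e_false:.3f} over {len(splits)} "
      f"permutations -> q = {e_false / 1:.3f} (matches q[0] = {q[0]:.3f})")
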