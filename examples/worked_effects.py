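"""Relative effects on a three-subject toy dataset, by hand and by estimator.

Two conditions, three subjects, one missing cell.  The unweighted relative
effect p_i compares condition i against the plain average of both
conditions' distributions; 0.5 would mean "no tendency".  The weighted
effects r_i use a reference weighted by how often each condition was
observed, so they shift with the missingness pattern — which is why the
package bases all inference on p.
"""

import numpy as np

from nparrm import covariance_psd, unweighted_effects, worked_example

ds = worked_example()
print("values (NaN = missing):")
print(ds.values)
print(f"observations per condition: {ds.lam_per_condition}, N = {ds.n_total_obs}")

eff = unweighted_effects(ds)
print(f"\nunweighted effects p_hat = {eff.p_hat}")   # (0.375, 0.625)
print(f"weighted effects   r_hat = {eff.r_hat}")     # (0.4, 0.65)
print(f"P(value from C2 > value from C1) = {eff.pairwise[0, 1]}")  # 0.75

V = covariance_psd(ds, eff)
print(f"\ncovariance of sqrt(n)(p_hat - p):\n{V.V}")
print(f"positive semidefinite: {V.psd_checked}")
# p_hat_2 > 0.5 > p_hat_1: values under condition 2 tend to be larger than
# a draw from the pooled reference, condition 1 values tend to be smaller.
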