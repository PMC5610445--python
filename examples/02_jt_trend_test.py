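"""Jonckheere-Terpstra ordered trend test: exact vs permutation p-values.

Three small temperature groups with an upward trend in msRMR. The exact
p-value enumerates all reassignments of the pooled values to the group
sizes; the permutation p-value estimates the same tail by Monte Carlo.
"""

from thermoneutral import jt_exact_p, jt_permutation_p, jt_statistic

groups = [
    (26.0, [0.82, 0.90, 0.85]),
    (28.0, [0.88, 0.95, 0.91]),
    (30.0, [0.99, 0.93, 1.04]),
]

j = jt_statistic(groups, alternative="increasing")
exact = jt_exact_p(groups, alternative="increasing")
perm = jt_permutation_p(groups, alternative="increasing",
                        n_perm=100_000, seed=1)

print(f"JT statistic          : {j:.1f} (max possible 27 cross pairs)")
print(f"exact p (enumeration) : {exact.p_value:.5f}")
print(f"permutation p         : {perm.p_value:.5f}  (100000 shuffles)")
print("A small p supports an increasing msRMR trend across these "
      "temperatures; the two p-values agree to Monte-Carlo accuracy.")
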