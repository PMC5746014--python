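"""Rule-based 3+3 comparator: exact selection distribution vs Monte Carlo.

The 3+3 path space is small enough to enumerate exactly, which both
validates the simulator and shows how blunt the rule-based design is
compared with the model-based machinery.
"""

import numpy as np

from titecrm import enumerate_3p3_distribution, simulate_3p3_trial

true_p = (0.10, 0.25, 0.45)
dist = enumerate_3p3_distribution(true_p)

n = 20_000
rng = np.random.default_rng(0)
counts = np.zeros(len(true_p) + 1)
for _ in range(n):
    counts[simulate_3p3_trial(true_p, rng=rng).selected] += 1

print(f"true DLT probabilities: {true_p}  (target ~0.25 -> dose 2 is the MTD)")
print("dose      exact P(select)   simulated")
labels = ["none safe"] + [f"dose {d}" for d in range(1, len(true_p) + 1)]
for d, label in enumerate(labels):
    print(f"{label:>9}  {dist.selection_probs[d]:15.4f}   {counts[d] / n:9.4f}")
print(f"expected sample size: {dist.expected_n:.2f}")
print("\nEnumeration sums binomial probabilities over every cohort path; the")
print("Monte-Carlo column should match within sampling error.  Note how often")
print("the 3+3 picks a dose away from the true MTD.")
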