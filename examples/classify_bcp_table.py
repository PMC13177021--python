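"""Classify bond-critical-point records and compare property groups.

Generates a synthetic BCP table with a known class composition (89.5%
noncovalent, 10.5% partially covalent), classifies it from the sign of the
Laplacian and the total energy density H = G + V, and runs an omnibus test
showing that a property identical across conditions is not flagged as
significant.
"""

import numpy as np

from scwnet import compare_groups, summarize_classes, synthetic_bcp_table

records, truth = synthetic_bcp_table(200, mix=(0.895, 0.105, 0.0), seed=21)
labels = [r.label for r in records]
accuracy = 100.0 * sum(a == b for a, b in zip(labels, truth)) / len(labels)

print(f"records: {len(records)}, classification accuracy: {accuracy:.1f}%")
print(summarize_classes(records).round(2))

rng = np.random.default_rng(5)
rho_by_condition = [rng.normal(0.015, 0.004, 30) for _ in range(4)]
res = compare_groups(rho_by_condition, test="kruskal")
print(f"\nelectron density across 4 conditions: "
      f"p = {res.p_value:.3f} ({res.test})")
print("significant at 5%:", res.p_value < 0.05)
# Noncovalent BCPs have density depletion (Laplacian > 0) and H > 0;
# partially covalent hydrogen bonds keep Laplacian > 0 but turn H negative.
# The high p-value shows the local electronic property does not vary
# across the sampled conditions.
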