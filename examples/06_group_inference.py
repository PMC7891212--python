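"""Group-level connector hubs: one-tailed sign-flip permutation inference.

Twelve synthetic subjects share one planted connector node.  Each
subject's hubs are detected by versatility, scored by DCI, and pooled;
candidates are nodes that are hubs in at least one subject, contributing
their scaled DCI where detected and 0 elsewhere.  The sign-flip test
(exact enumeration for up to 12 subjects) asks which candidates have DCI
consistently above zero across the cohort.
"""

import numpy as np

from dcinet import generate_multilayer_fixture, run_group
from dcinet.hubs import dci_profile, hub_table
from dcinet.pipeline import SubjectOutput

subjects = []
for s in range(12):
    sup = generate_multilayer_fixture(12, 3, 0.3, 0.08, planted_hub=4, seed=900 + s)
    table = hub_table(sup)
    idx = table.hub_indices()
    prof = dci_profile(sup, idx) if idx.size else None
    subjects.append(SubjectOutput(
        labels=list(sup.labels), z_blocks=[], supra=sup,
        hub_table=table, dci=prof, layer_sparsity={},
    ))

res = run_group(subjects)
print(f"{len(subjects)} subjects, {res.candidates.size} candidate node(s), "
      f"{'exact enumeration' if res.exact else 'Monte Carlo'} test")
for c, eff, p in zip(res.candidates, res.effect_size, res.p_value):
    print(f"  node {c} ({res.labels[c]}): effect {eff:+.2f}, p = {p:.6f}")
# The planted connector should be the (typically only) candidate with a
# tiny exact p: its DCI is positive in nearly every subject, and sign
# flips can almost never reproduce such a concordant mean.
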