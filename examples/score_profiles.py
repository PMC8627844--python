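"""Score EQ-5D-5L profiles with the published Ugandan value set.

A value set maps each 5-digit profile to a societal value anchored at 1
(full health, 11111) and 0 (dead): 1 minus the sum of the profile's
dimension-level decrements. Values below 0 mean worse than dead.
"""

import pandas as pd

from cttolite import dimension_importance, published_value_set, score_dataset, score_state

vs = published_value_set("analytic")  # primary value set (N = 492)

for state in ("11111", "11112", "23514", "55555"):
    print(f"value({state}) = {score_state(state, vs):+.3f}")

profiles = pd.DataFrame({"state": ["11111", "21121", "23514", "44444", "55555"]})
scored, summary = score_dataset(profiles, vs)
print(scored.to_string(index=False))
print(f"mean = {summary['mean']:.3f}, sd = {summary['sd']:.3f}")
print("dimension importance:", " > ".join(dimension_importance(vs)))
# 23514 scores 0.276 = 1 - (0.073 + 0.110 + 0.306 + 0 + 0.235); 55555 at
# -1.116 is the floor of the value set, 11112 at 0.950 its best ill state.
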