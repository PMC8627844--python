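"""Construct a 'lite' valuation design from a standard 10x10 design.

The standard cTTO design has 10 blocks of 10 states (86 distinct: the worst
state 55555 in every block, one single-dimension mild state per block, 8
block-unique states). The lite variant merges cyclically adjacent blocks
into 10 blocks of 20 and replaces the duplicated 55555 with one of five
severe states, yielding 91 distinct states while halving the respondent
count needed for the same number of responses.
"""

from collections import Counter

from cttolite import build_lite_design, generate_synthetic_standard_design, misery_score
from cttolite.states import SEVERE_STATES

standard = generate_synthetic_standard_design(seed=0)
lite = build_lite_design(standard)

print(f"standard: {len(standard.blocks)} blocks x {len(standard.blocks[0])}, "
      f"{len(standard.distinct_states)} distinct states")
print(f"lite:     {len(lite.blocks)} blocks x {len(lite.blocks[0])}, "
      f"{len(lite.distinct_states)} distinct states")

severe_counts = Counter(s for b in lite.blocks for s in b if s in SEVERE_STATES)
print("severe substitutions:", {str(s): n for s, n in sorted(severe_counts.items())})

scores = sorted({misery_score(s) for s in lite.distinct_states})
print(f"misery scores covered: {scores[0]}..{scores[-1]} ({len(scores)} levels)")
print("block 1:", " ".join(str(s) for s in lite.block(1)))
# 91 = 86 + 5: merging adds exactly the five severe states 45555..55554,
# each placed in two blocks.
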