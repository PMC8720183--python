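"""Build an N-back session and score simulated button presses.

The session has eight 40-s blocks (two each of fixation, 0-, 1-, and
2-back), 16 letter trials per block, four targets per active block.
Responses are scored hit / miss / false alarm / correct rejection with
a 1.5-s window from stimulus onset.
"""

import pupilfmri as pf
from pupilfmri.simulate import simulate_behavior

schedule = pf.build_schedule(seed=1)
print(f"blocks: {len(schedule.blocks)}, session span: {schedule.span:.0f} s")
print("block order:", [b.condition.value for b in schedule.blocks])

log = simulate_behavior(schedule, seed=2)
outcomes = pf.score_responses(schedule, log)
summary = pf.summarize_behavior(outcomes)
print(summary.to_string(index=False))
print("accuracy = (hits + correct rejections) / 16 trials x 2 blocks;"
      " mean RT averages hits only.")
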