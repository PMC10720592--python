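"""Extract salient events and match forward vs time-reversed presentations.

Event onsets are local maxima of the salience derivative; a backward
presentation of the same scene is analyzed on its own time axis, its events
reversed back, and each forward event labeled matched/mismatched by >50%
interval overlap.  Events missing from the reversed presentation (here, two
planted events the backward cohort does not respond to) come out mismatched.
"""

import numpy as np

from audisal import (
    GroundTruth,
    ResponseSpec,
    assign_strengths,
    average_behavioral_salience,
    extract_events,
    make_response_set,
    match_events,
    reverse_events,
)

duration = 90.0
onsets = [10.0, 30.0, 50.0, 70.0]
truth_fwd = GroundTruth(planted_onsets=onsets, planted_offsets=[o + 2 for o in onsets])
# backward scene: events mirrored in time; the cohort ignores two of them
# (their salience depended on forward context)
bwd_onsets = sorted(duration - (o + 2.0) for o in onsets)
truth_bwd = GroundTruth(planted_onsets=bwd_onsets)
bwd_consensus = [0.5, 0.0, 0.5, 0.0]  # aligned with bwd_onsets order

fwd_trials = make_response_set(
    truth_fwd, ResponseSpec(n_participants=120, consensus=0.5, seed=2), duration, direction="fwd"
)
bwd_trials = make_response_set(
    truth_bwd, ResponseSpec(n_participants=120, consensus=bwd_consensus, seed=3),
    duration, direction="bwd",
)

fwd_map = average_behavioral_salience(fwd_trials)
bwd_map = average_behavioral_salience(bwd_trials)
fwd_events = assign_strengths(extract_events(fwd_map))
bwd_events = reverse_events(extract_events(bwd_map), bwd_map.duration)

print(f"{len(fwd_events)} fwd events, {len(bwd_events)} bwd events (reversed to fwd axis)")
for m in match_events(fwd_events, bwd_events):
    e = m.event
    print(f"  onset {e.onset:5.1f} s  slope {e.slope:.4f}  consensus {e.consensus:.2f}  "
          f"strength {e.strength:.4f}  overlap {m.overlap_score:.2f} -> {m.label}")
print("matched events recur under time reversal (acoustically driven);")
print("mismatched events lost their salience without forward context.")
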