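"""Ring-attractor cue fusion vs the weighted circular-mean prediction.

Two desired-heading bumps with different amplitudes are injected into
the integration ring; the settled bump decodes to a compromise direction
pulled toward the stronger cue — the optimal (amplitude-weighted
vector-sum) combination, computed here independently as a check.
"""

import math

from cxnav import decode_ring, encode_heading, ring_attractor_integrate

cue_a_dir, cue_b_dir = 0.0, math.pi / 2
print(f"cue A at 0 deg, cue B at 90 deg")
for amp_a in (1.0, 2.0, 0.5):
    fused = ring_attractor_integrate(
        [encode_heading(cue_a_dir, amp_a), encode_heading(cue_b_dir, 1.0)]
    )
    got = math.degrees(decode_ring(fused)[0])
    want = math.degrees(math.atan2(math.sin(cue_b_dir), amp_a + math.cos(cue_b_dir)))
    print(f"  amplitudes {amp_a}:1 -> attractor {got:6.2f} deg, "
          f"weighted vector mean {want:6.2f} deg")
# equal cues settle halfway (45 deg); doubling one amplitude pulls the
# bump toward it, matching the closed-form weighted mean within ~1 deg
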