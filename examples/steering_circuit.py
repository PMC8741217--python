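"""The CPU1 steering circuit: desired vs current heading -> signed turn.

The desired bump is projected into left/right banks with opposite
rotations; each bank subtracts the compass bump and rectifies.  The
left-right imbalance, scaled by the motor gain, is the turn command:
zero at alignment, antisymmetric, and monotone on (-90, +90) deg.
"""

import math

from cxnav import encode_heading, steer

current = encode_heading(0.0)
for offset in (-90, -45, -10, 0, 10, 45, 90):
    desired = encode_heading(math.radians(offset))
    out = steer(desired, current, k_motor=1.0)
    print(f"desired {offset:+4d} deg off current -> turn {out.turn_angle:+.4f} rad")
# positive turn = counter-clockwise, toward the desired heading; the
# command grows smoothly with the offset, so tracking is stable
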