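"""The 8-column heading code and the copy-and-shift operator.

Every directional signal in the model is a cosine activity bump over 8
azimuthal columns (45 deg apart).  Copy-and-shift converts the current
heading into a desired heading by laterally shifting the bump through an
80-column interpolation, giving a 4.5 deg shift resolution.
"""

import math

from cxnav import copy_and_shift, decode_ring, encode_heading

ring = encode_heading(math.radians(30), amplitude=1.0)
theta, mag = decode_ring(ring)
print(f"encode 30 deg -> decode {math.degrees(theta):.3f} deg (magnitude {mag:.2f})")

for shift_deg in (45.0, 4.5, 70.0):
    shifted = copy_and_shift(ring, math.radians(shift_deg))
    theta, _ = decode_ring(shifted)
    print(f"shift by {shift_deg:5.1f} deg -> decodes to {math.degrees(theta):8.3f} deg")
# one native column is 45 deg; one interpolated column is 4.5 deg, so a
# 70 deg request lands on the nearest representable value, 72 deg
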