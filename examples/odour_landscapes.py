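"""Build the three analytic odour landscapes and query them.

The 'volcano' gradient peaks on a ring around the source, the 'linear'
variant keeps the outer slope but only dips slightly inside the rim, and
the plume is carried by a constant wind with exactly zero concentration
on the upwind side.
"""

from cxnav import GradientField, PlumeField, concentration_at, plume_geometry

volcano = GradientField(kind="volcano", k=10.0, tau=0.1, r=6.0)
linear = GradientField(kind="linear", k=10.0, tau=0.1, r=6.0)
plume = PlumeField(q=10.0, wind_speed=10.0, wind_dir=-1.5708, ks=0.2)

print("volcano on the rim  (d=3):", concentration_at(volcano, (3.0, 0.0)))
print("volcano at centre   (d=0):", round(concentration_at(volcano, (0.0, 0.0)), 4))
print("volcano far outside (d=20):", round(concentration_at(volcano, (20.0, 0.0)), 4))
print("linear  at centre   (d=0):", round(concentration_at(linear, (0.0, 0.0)), 4))
# the rim value equals k exactly; the centre keeps ~74% of it for the
# volcano but ~98% for the 'linear' shape — the two test different
# gradient-ascent regimes with an identical outer slope

print("\nplume on the centreline, 5 downwind:", round(concentration_at(plume, (0.0, -5.0)), 4))
print("plume 1 crosswind at 5 downwind:    ", round(concentration_at(plume, (1.0, -5.0)), 6))
print("plume strictly upwind:              ", concentration_at(plume, (0.0, 5.0)))
theta, cross, down = plume_geometry(plume, (1.0, -5.0))
print(f"geometry at (1,-5): angle off axis {theta:.3f} rad, "
      f"crosswind {cross:.3f}, downwind {down:.3f}")
# the upwind half-plane is exactly zero: odour is only carried downwind
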