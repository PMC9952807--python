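"""Predict preferred cell-alignment angles for the groove/stretch scenarios.

Runs the four canonical configurations (2D monolayer / 3D hydrogel seeding,
grooves parallel / perpendicular to a 15% cyclic stretch), solving the
peak-stretch and self-condensation strain states and combining them through
the nonlinear strain-avoidance law with n = 4.
"""

from strainavoid import run_scenario

for name in ("2d_parallel", "2d_perpendicular", "3d_parallel", "3d_perpendicular"):
    res = run_scenario(name)
    print(f"{name:18s} -> {res.angle:5.1f} deg from the stretch axis")

print(
    "\nAngles near 90 deg mean the cyclic-stretch cue dominates (alignment"
    "\nperpendicular to stretch); the oblique 3d_parallel angle arises because"
    "\nthe groove-condensation cue (favouring 0 deg) competes with the stretch"
    "\ncue at comparable strain magnitude in the soft hydrogel."
)
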