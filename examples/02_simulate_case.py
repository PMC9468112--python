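"""Simulate a complete two-view registration test case.

A case bundles: the baseline volume, per-vertebra intraoperative pose
perturbations (up to 5 deg about x, 2 mm along z), 5-9 radiopaque skin
markers in a 15x15 cm dorsal frame, and two noisy fluoroscopy-like views
at an opposed C-arm angulation pair.
"""

import spinereg as sr

config = sr.CaseConfig(angulation_pair=(-30.0, 30.0), marker_count=8)
case = sr.make_test_case(config, seed=42)

print(f"nominal RAD {case.rad_deg:.0f} deg, realized {case.realized_rad_deg:.2f} deg "
      "(the second view's angulation is jittered like a hand-positioned C-arm)")
print(f"{case.markers.count} markers, radius {case.markers.radius} mm")
for v in case.vertebrae:
    q = v.true_pose.params
    print(f"  {v.label}: true intraoperative pose "
          f"tz {q[2]:+.2f} mm, wx {q[3]:+.2f} deg")
print(f"fluoro 1: {case.fluoro1.values.shape}, "
      f"intensities {case.fluoro1.values.min():.2f}..{case.fluoro1.values.max():.2f} "
      "(affine detector response + noise applied)")
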