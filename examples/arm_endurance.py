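"""Arm-extension endurance: hold time, downward drift, and the fatigue flag.

The arm-torso angle is tracked for up to two minutes of shoulder abduction.
A drift more negative than the control threshold (-0.12 rad under 70 years,
-0.24 over) marks shoulder weakness; an early abrupt drop is its own pattern.
"""

from mgce import (
    ArmSpec,
    SyntheticSpec,
    analyze_arm,
    gen_arm_session,
    load_config,
    paper_implied_norms,
)

cfg = load_config()
norms = paper_implied_norms()["arm.drift_total"]["under_70"]

# a patient drifting at -0.0015 rad/s: -0.18 rad over the full 120 s hold
series, _ = gen_arm_session(SyntheticSpec(seed=8, arm=ArmSpec(true_slope_rad_s=-0.0015)))
result = analyze_arm(series, cfg, abnormal_threshold=norms.threshold)

for side, arm in (("left", result.left), ("right", result.right)):
    print(f"{side} arm: held {arm.hold_time:.1f} s, drift {arm.drift_total:+.3f} rad "
          f"({arm.drift_slope:+.5f} rad/s), pattern: {arm.pattern}")
print(f"control threshold {norms.threshold:+.2f} rad (mean {norms.mean:+.2f} - 1 SD); "
      "a more negative drift indicates shoulder muscle fatigue")
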