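"""Time the ascending phase of the sit-to-stand exercise from hip landmarks.

The ascending phase is the interval where upward hip velocity exceeds 10%
of its peak; inability to stand is detected from the total hip rise
relative to trunk length.
"""

from mgce import StsSpec, SyntheticSpec, detect_ascend, gen_sts_session

series, truth = gen_sts_session(SyntheticSpec(seed=5, sts=StsSpec(true_ascend_s=1.6)))
result = detect_ascend(series)
print(f"able to stand: {result.able_to_stand}; ascending time "
      f"{result.ascend_time:.2f} s (truth {truth.sts.true_ascend_s} s); "
      f"partial head view: {result.partial_view}")

flat, _ = gen_sts_session(SyntheticSpec(seed=6, sts=StsSpec(able=False)))
print(f"flat hip trajectory -> able to stand: {detect_ascend(flat).able_to_stand} "
      "(longer ascents than controls indicate leg weakness)")
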