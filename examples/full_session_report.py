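"""Analyze a complete six-exercise synthetic exam and print the flag summary.

QC runs first; each exercise's metrics are flagged against the shipped
control norms (age-stratified at 70 years). The JSON report is byte-stable
across reruns.
"""

from mgce import Participant, SyntheticSpec, gen_full_session, run_session

session = gen_full_session(SyntheticSpec(seed=11))
inputs = {ex: (p if isinstance(p, dict) else {"landmarks": p}) for ex, p in session.items()}
participant = Participant(id="demo-01", age_years=58, group="patient")

report = run_session(inputs, participant=participant)
for block in report.exercises:
    qc = "passed" if (block.qc is None or block.qc.passed) else f"EXCLUDED {block.qc.reasons}"
    print(f"[{block.exercise}] QC {qc}")
    for name in sorted(block.values):
        unit = block.units.get(name, "")
        flag = block.flags.get(name, "")
        print(f"   {name} = {block.values[name]:.3f} {unit} {('<' + flag + '>') if flag else ''}")
print(f"report hash-stable config: {report.config_hash}; tool {report.tool_version}")
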