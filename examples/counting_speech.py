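"""Segment the count-to-50 and single-breath exercises from ASR word timings.

Number words (including compounds and counting homophones) are parsed from
the transcript, the longest increasing counting run is located despite
misrecognitions, and breath pauses split the single-breath count.
"""

from mgce import (
    SpeechSpec,
    SyntheticSpec,
    count_rate_metrics,
    gen_count_transcript,
    locate_count_segment,
    parse_number_words,
    single_breath_metrics,
)

# count-to-50 with two numbers lost by the recognizer
tr, _ = gen_count_transcript(SyntheticSpec(seed=1, speech=SpeechSpec(skip_errors=2)))
segment = locate_count_segment(parse_number_words(tr))
mean_iv, cv_iv = count_rate_metrics(segment)
print(f"count-to-50: reached {segment.max_value} in {segment.elapsed:.1f} s, "
      f"mean interval {mean_iv:.2f} s (cv {cv_iv:.2f}), "
      f"{len(segment.tokens)} numbers recognized")

# single-breath count with a breath taken after 22
tr, _ = gen_count_transcript(SyntheticSpec(
    seed=2, speech=SpeechSpec(max_count=30, pause_after=22)))
segment = locate_count_segment(parse_number_words(tr))
count, span, pauses = single_breath_metrics(segment.tokens)
print(f"single breath: counted to {count} in {span:.1f} s before the first pause "
      f"({pauses} breath pause(s) in the whole segment)")
print("(the first-breath count is a bedside respiratory proxy)")
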