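"""Number parsing, counting-segment location and breath metrics."""

import numpy as np
import pytest

from mgce import (
    SpeechSpec,
    SyntheticSpec,
    TranscriptWords,
    Word,
    count_rate_metrics,
    gen_count_transcript,
    locate_count_segment,
    parse_number_words,
    single_breath_metrics,
)
from mgce.errors import InsufficientDataError, SegmentNotFoundError
from mgce.speech import NumberToken


def _tr(items):
    return TranscriptWords(words=tuple(Word(text=w, start=s, end=e) for w, s, e in items))


def _tokens(values, rate=0.8, dur=0.3, start=0.0):
    out = []
    t = start
    for v in values:
        out.append(NumberToken(value=v, start=round(t, 6), end=round(t + dur, 6), raw_text=str(v)))
        t += rate
    return out


class TestParseNumberWords:
    def test_compound_spans_both_words(self):
        toks = parse_number_words(_tr([("twenty", 3.0, 3.3), ("one", 3.3, 3.5)]))
        assert len(toks) == 1
        tk = toks[0]
        assert (tk.value, tk.start, tk.end) == (21, 3.0, 3.5)

    def test_hyphenated_compound(self):
        toks = parse_number_words(_tr([("twenty-one", 3.0, 3.5)]))
        assert toks[0].value == 21

    def test_digits_recognized(self):
        assert parse_number_words(_tr([("27", 0.0, 0.3)]))[0].value == 27

    def test_non_numbers_skipped(self):
        assert parse_number_words(_tr([("hello", 0.0, 0.3), ("world", 0.4, 0.6)])) == []

    def test_homophone_accepted_between_numbers(self):
        toks = parse_number_words(_tr([
            ("three", 8.0, 8.2), ("for", 9.0, 9.2), ("five", 10.0, 10.2)]))
        assert [t.value for t in toks] == [3, 4, 5]

    def test_homophone_rejected_without_number_context(self):
        toks = parse_number_words(_tr([("thanks", 0.0, 0.2), ("for", 0.3, 0.5), ("coming", 0.6, 0.9)]))
        assert toks == []

    @pytest.mark.parametrize("word,value", [("to", 2), ("too", 2), ("ate", 8), ("won", 1)])
    def test_homophone_table(self, word, value):
        toks = parse_number_words(_tr([("one", 0.0, 0.2), (word, 0.8, 1.0)]))
        assert value in [t.value for t in toks]

    def test_values_above_fifty_ignored(self):
        assert parse_number_words(_tr([("99", 0.0, 0.3), ("sixty", 1.0, 1.3)])) == []


def _oracle_locate(values, target=50, max_skips=3):
    """Exhaustive best increasing subsequence with bounded skip budget.

    Maximizes accepted-token count; ties broken by the lexicographically
    smallest index tuple. Independent of the package's memoized search.
    """
    n = len(values)
    best = None

    def rec(last_idx, budget, chain):
        nonlocal best
        if chain and chain[0] is not None:
            cand = tuple(chain)
            if best is None or len(cand) > len(best) or (len(cand) == len(best) and cand < best):
                best = cand
        for j in range((last_idx + 1) if last_idx is not None else 0, n):
            if last_idx is None:
                if values[j] <= 2:
                    rec(j, budget, chain + [j])
            else:
                if values[j] <= values[last_idx] or values[j] > target:
                    continue
                cost = (j - last_idx - 1) + (values[j] - values[last_idx] - 1)
                if cost <= budget:
                    rec(j, budget - cost, chain + [j])

    rec(None, max_skips, [])
    return best


class TestLocateCountSegment:
    def test_clean_run_elapsed_and_max(self):
        toks = _tokens(range(1, 51))
        seg = locate_count_segment(toks)
        assert seg.max_value == 50
        assert seg.elapsed == pytest.approx(49 * 0.8 + 0.3)
        assert seg.intervals == tuple([pytest.approx(0.8)] * 49)

    def test_one_missing_value_consumes_skip(self):
        toks = _tokens([v for v in range(1, 51) if v != 4])
        seg = locate_count_segment(toks)
        assert seg.max_value == 50 and len(seg.tokens) == 49

    def test_unrelated_numbers_not_a_segment(self):
        with pytest.raises(SegmentNotFoundError):
            locate_count_segment(_tokens([7, 3, 9]))

    def test_budget_exhausted_truncates_run(self):
        toks = _tokens([1, 2, 3, 10, 11, 12])  # jump of 6 > default budget 3
        seg = locate_count_segment(toks, min_run=3)
        assert [t.value for t in seg.tokens] == [1, 2, 3]

    def test_equals_bruteforce_oracle_on_corrupted_transcripts(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = int(rng.integers(8, 31))
            values = list(range(1, n + 1))
            for _ in range(int(rng.integers(0, 4))):  # up to 3 corruptions
                kind = rng.integers(0, 2)
                if kind == 0 and len(values) > 6:
                    values.pop(int(rng.integers(2, len(values) - 1)))
                else:
                    values.insert(int(rng.integers(1, len(values))), int(rng.integers(1, 51)))
            toks = _tokens(values)
            oracle = _oracle_locate(values)
            try:
                seg = locate_count_segment(toks, min_run=5)
            except SegmentNotFoundError:
                assert oracle is None or len(oracle) < 5
                continue
            got = tuple(toks.index(t) for t in seg.tokens)
            assert got == oracle, f"trial {trial}: {values}"

    def test_time_translation_invariance(self):
        a = locate_count_segment(_tokens(range(1, 21), start=0.0), min_run=5)
        b = locate_count_segment(_tokens(range(1, 21), start=137.5), min_run=5)
        assert a.elapsed == pytest.approx(b.elapsed)
        assert a.intervals == pytest.approx(b.intervals)
        assert b.tokens[0].start == pytest.approx(a.tokens[0].start + 137.5)


class TestCountRateMetrics:
    def test_uniform_intervals(self):
        seg = locate_count_segment(_tokens(range(1, 21)), min_run=5)
        mean, cv = count_rate_metrics(seg)
        assert mean == pytest.approx(0.8)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_alternating_intervals_mean_one(self):
        toks, t = [], 0.0
        for i, v in enumerate(range(1, 21)):
            toks.append(NumberToken(value=v, start=t, end=t + 0.3, raw_text=str(v)))
            t += 0.5 if i % 2 == 0 else 1.5
        seg = locate_count_segment(toks, min_run=5)
        mean, cv = count_rate_metrics(seg)
        assert mean == pytest.approx(1.0, abs=0.03)

    def test_cv_equals_two_pass_oracle(self):
        rng = np.random.default_rng(8)
        toks, t = [], 0.0
        for v in range(1, 31):
            toks.append(NumberToken(value=v, start=t, end=t + 0.2, raw_text=str(v)))
            t += float(rng.uniform(0.4, 1.4))
        seg = locate_count_segment(toks, min_run=5)
        mean, cv = count_rate_metrics(seg)
        iv = np.diff([tk.start for tk in seg.tokens])
        assert mean == pytest.approx(iv.mean())
        assert cv == pytest.approx(iv.std() / iv.mean())

    def test_single_token_errors(self):
        from mgce.speech import CountSegment

        seg = CountSegment(tokens=tuple(_tokens([1])), elapsed=0.3, intervals=(),
                           max_value=1, breath_pauses=())
        with pytest.raises(InsufficientDataError):
            count_rate_metrics(seg)


class TestSingleBreath:
    def test_no_pause_reaches_30(self):
        toks = _tokens(range(1, 31))
        count, span, pauses = single_breath_metrics(toks)
        assert (count, pauses) == (30, 0)
        assert span == pytest.approx(29 * 0.8 + 0.3)

    def test_pause_after_22(self):
        toks = _tokens(range(1, 23)) + _tokens(range(23, 31), start=22 * 0.8 + 1.8)
        count, span, pauses = single_breath_metrics(toks)
        assert count == 22 and pauses == 1
        assert span == pytest.approx(21 * 0.8 + 0.3)

    def test_multiple_pauses_counted_over_full_segment(self):
        toks = (_tokens(range(1, 11)) + _tokens(range(11, 21), start=10 * 0.8 + 2.0)
                + _tokens(range(21, 31), start=20 * 0.8 + 4.5))
        count, _, pauses = single_breath_metrics(toks)
        assert count == 10 and pauses == 2

    def test_empty_tokens_error(self):
        with pytest.raises(InsufficientDataError):
            single_breath_metrics([])


class TestTranscriptGenerator:
    def test_clean_transcript_round_trip(self):
        tr, _ = gen_count_transcript(SyntheticSpec(seed=20))
        seg = locate_count_segment(parse_number_words(tr))
        assert seg.max_value == 50 and len(seg.tokens) == 50

    def test_pause_round_trip(self):
        spec = SyntheticSpec(seed=21, speech=SpeechSpec(max_count=30, pause_after=22))
        tr, _ = gen_count_transcript(spec)
        seg = locate_count_segment(parse_number_words(tr))
        count, _, pauses = single_breath_metrics(seg.tokens)
        assert count == 22 and pauses == 1

    def test_determinism(self):
        a, _ = gen_count_transcript(SyntheticSpec(seed=22))
        b, _ = gen_count_transcript(SyntheticSpec(seed=22))
        assert a == b

    def test_pipeline_deterministic_over_corruptions(self):
        for seed in range(20):
            spec = SyntheticSpec(seed=seed, speech=SpeechSpec(skip_errors=2, misrecognitions=1))
            tr, _ = gen_count_transcript(spec)
            seg = locate_count_segment(parse_number_words(tr))
            assert seg.max_value == 50
            assert len(seg.tokens) == 47  # two deleted, one junked
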