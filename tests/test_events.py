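"""The temporal map: parsing, state windows, rates, and intervals."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iotalearn.events import (
    Event,
    EventRecord,
    FormatError,
    NoEvidenceError,
    PairingError,
    StateWindow,
    VocabularyError,
    backward_intervals,
    complement_windows,
    conditional_rate,
    contextual_rate_iti,
    forward_intervals,
    load_events,
    scale_times,
    state_windows,
    write_events,
)


class TestLoadEvents:
    def test_absolute_time_parse(self):
        text = "time_s,event\n0,context_on\n10,cs_on:A\n12,reinf:food\n12,cs_off:A\n"
        rec = load_events(text)
        assert len(rec) == 4
        assert rec.t_end == 12.0
        assert [ev.code for ev in rec.events][0] == "context_on"

    def test_duration_stamp_dialect_cumsums(self):
        text = "# stamps=duration\ntime_s,event\n5,cs_on:A\n5,cs_off:A\n"
        rec = load_events(text)
        assert [ev.time for ev in rec.events] == [5.0, 10.0]

    def test_empty_stream_gives_empty_record(self):
        rec = load_events(io.StringIO("time_s,event\n"))
        assert len(rec) == 0
        with pytest.raises(NoEvidenceError):
            conditional_rate(rec, "reinf:food")

    def test_unknown_code_rejected(self):
        with pytest.raises(VocabularyError):
            load_events("time_s,event\n1,banana\n")
        with pytest.raises(VocabularyError):
            load_events("time_s,event\n1,reinf:food\n", vocabulary={"cs_on:A"})

    @pytest.mark.parametrize(
        "text", ["time_s,event\n-1,context_on\n", "time_s,event\n5,context_on\n3,cs_on:A\n"]
    )
    def test_bad_times_rejected(self, text):
        with pytest.raises(FormatError):
            load_events(text)

    def test_round_trip(self, six_hour_record):
        text = write_events(six_hour_record)
        again = load_events(text)
        assert [(e.time, e.code) for e in again.events] == [
            (e.time, e.code) for e in six_hour_record.events
        ]

    def test_duration_dialect_normalizes_to_absolute_on_write(self):
        rec = load_events("# stamps=duration\n5,cs_on:A\n5,cs_off:A\n")
        text = write_events(rec)
        assert "10,cs_off:A" in text


class TestStateWindows:
    def test_single_presentation(self):
        rec = load_events("10,cs_on:A\n12,cs_off:A\n")
        w = state_windows(rec, "cs:A")
        assert w.intervals == [(10.0, 12.0)]
        assert w.duration == 2.0

    def test_unclosed_state_closes_at_t_end(self):
        rec = EventRecord([Event(10.0, "cs_on:A")], t_end=15.0)
        assert state_windows(rec, "cs:A").intervals == [(10.0, 15.0)]

    def test_cumulative_duration_adds(self):
        rec = load_events("1,cs_on:A\n3,cs_off:A\n7,cs_on:A\n9,cs_off:A\n")
        assert state_windows(rec, "cs:A").duration == 4.0

    def test_unpaired_off_raises(self):
        rec = load_events("3,cs_off:A\n")
        with pytest.raises(PairingError):
            state_windows(rec, "cs:A")

    def test_double_on_raises(self):
        rec = load_events("1,cs_on:A\n2,cs_on:A\n3,cs_off:A\n")
        with pytest.raises(PairingError):
            state_windows(rec, "cs:A")


class TestConditionalRate:
    def test_shock_during_one_second_cs(self, six_hour_record):
        cs = state_windows(six_hour_record, "cs:noise")
        est = conditional_rate(six_hour_record, "reinf:shock", cs)
        assert est.count == 1 and est.duration == 1.0 and est.rate == 1.0

    def test_contextual_rate_over_six_hours(self, six_hour_record):
        est = conditional_rate(six_hour_record, "reinf:shock", None)
        assert est.count == 1 and est.duration == 21600.0
        assert est.rate == pytest.approx(1 / 21600)

    def test_zero_events_is_rate_zero(self):
        rec = EventRecord([Event(0.0, "context_on"), Event(100.0, "context_off")])
        assert conditional_rate(rec, "reinf:food").rate == 0.0

    def test_reinforcement_at_cs_offset_counts_inside_cs(self):
        rec = load_events("0,context_on\n10,cs_on:A\n12,reinf:food\n12,cs_off:A\n100,context_off\n")
        cs = state_windows(rec, "cs:A")
        assert conditional_rate(rec, "reinf:food", cs).count == 1

    def test_partition_additivity(self):
        # events at boundaries and interiors: CS + complement = context
        rows = [
            "0,context_on", "5,reinf:food", "10,cs_on:A", "11,reinf:food",
            "12,reinf:food", "12,cs_off:A", "20,reinf:food", "30,context_off",
        ]
        rec = load_events("\n".join(rows) + "\n")
        cs = state_windows(rec, "cs:A")
        ctx = state_windows(rec, "context")
        comp = complement_windows(cs, ctx)
        n_cs = conditional_rate(rec, "reinf:food", cs).count
        n_comp = conditional_rate(rec, "reinf:food", comp).count
        n_ctx = conditional_rate(rec, "reinf:food", ctx).count
        assert n_cs + n_comp == n_ctx == 4
        assert cs.duration + comp.duration == pytest.approx(ctx.duration)

    def test_zero_duration_state_raises(self):
        rec = load_events("0,context_on\n10,context_off\n")
        with pytest.raises((NoEvidenceError, ValueError)):
            conditional_rate(rec, "reinf:food", StateWindow("x", []))

    def test_iti_only_contextual_rate(self):
        rec = load_events(
            "0,context_on\n80,cs_on:A\n90,cs_off:A\n95,reinf:food\n100,context_off\n"
        )
        est = contextual_rate_iti(rec, "reinf:food", ["cs:A"])
        assert est.count == 1 and est.duration == pytest.approx(90.0)


class TestIntervals:
    def test_forward_direct(self):
        rec = load_events("1,response:r\n4,response:r\n5,reinf:food\n")
        assert forward_intervals(rec, "response:r", "reinf:food") == [4.0, 1.0]

    def test_forward_trailing_censored_dropped(self):
        rec = load_events("1,response:r\n4,response:r\n5,reinf:food\n6,response:r\n")
        assert forward_intervals(rec, "response:r", "reinf:food") == [4.0, 1.0]

    def test_forward_censored_closed_at_t_end_when_asked(self):
        rec = EventRecord(
            [Event(1.0, "response:r"), Event(5.0, "reinf:food"), Event(6.0, "response:r")],
            t_end=10.0,
        )
        assert forward_intervals(rec, "response:r", "reinf:food", close_at_end=True) == [
            4.0, 4.0,
        ]

    def test_co_timed_interval_is_zero(self):
        rec = load_events("5,response:r\n5,reinf:food\n")
        assert forward_intervals(rec, "response:r", "reinf:food") == [0.0]
        assert backward_intervals(rec, "reinf:food", "response:r") == [0.0]

    def test_backward_most_recent(self):
        rec = load_events("1,response:r\n4,response:r\n5,reinf:food\n")
        assert backward_intervals(rec, "reinf:food", "response:r") == [1.0]

    def test_backward_leading_censored_dropped(self):
        rec = load_events("3,reinf:food\n")
        assert backward_intervals(rec, "reinf:food", "response:r") == []


@settings(max_examples=30, deadline=None)
@given(c=st.floats(min_value=0.01, max_value=1e3))
def test_time_scale_invariance(c):
    """Scaling every stamp by c scales durations by c, rates by 1/c, and
    leaves all counts unchanged."""
    rec = load_events(
        "0,context_on\n10,cs_on:A\n12,reinf:food\n12,cs_off:A\n100,context_off\n"
    )
    scaled = scale_times(rec, c)
    cs0 = conditional_rate(rec, "reinf:food", state_windows(rec, "cs:A"))
    cs1 = conditional_rate(scaled, "reinf:food", state_windows(scaled, "cs:A"))
    assert cs1.count == cs0.count
    assert cs1.duration == pytest.approx(cs0.duration * c)
    assert cs1.rate == pytest.approx(cs0.rate / c)
    ctx0 = conditional_rate(rec, "reinf:food")
    ctx1 = conditional_rate(scaled, "reinf:food")
    assert (cs1.rate / ctx1.rate) == pytest.approx(cs0.rate / ctx0.rate)


def test_tie_order_is_stable():
    rec = load_events("5,response:r\n5,reinf:food\n")
    assert [e.code for e in rec.events] == ["response:r", "reinf:food"]


def test_scale_times_rejects_nonpositive():
    rec = load_events("1,response:r\n")
    with pytest.raises(ValueError):
        scale_times(rec, 0.0)
    assert not math.isnan(rec.duration)
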