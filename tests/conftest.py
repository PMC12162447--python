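import pytest

from iotalearn.events import Event, EventRecord


@pytest.fixture
def six_hour_record():
    """The canonical worked scenario: 6 hr (21,600 s) in the chamber,
    then a 1-s noise CS terminating in a shock."""
    events = [
        Event(0.0, "context_on"),
        Event(21599.0, "cs_on:noise"),
        Event(21600.0, "reinf:shock"),
        Event(21600.0, "cs_off:noise"),
        Event(21600.0, "context_off"),
    ]
    return EventRecord(events=events, t0=0.0, t_end=21600.0)


@pytest.fixture
def vi_like_record():
    """Responses at a steady clip; each reinforcement co-timed with the
    response that triggered it."""
    events = [Event(0.0, "context_on")]
    for t in range(10, 1000, 10):
        events.append(Event(float(t), "response:peck"))
        if t % 100 == 0:
            events.append(Event(float(t), "reinf:food"))
    events.append(Event(1000.0, "context_off"))
    return EventRecord(events=events, t0=0.0, t_end=1000.0)
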