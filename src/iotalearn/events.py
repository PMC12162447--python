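"""The temporal map: time-stamped event records and the counts, durations
and intervals extracted from them.

An :class:`EventRecord` is an ordered two-column structure (time stamp,
event code).  Every quantity downstream -- rates, informativeness, nDKL,
the credit-assignment matrix -- is a count, a cumulative duration, or a
ratio of such quantities read off this record.

Event-code vocabulary
---------------------
``context_on`` / ``context_off``
    entry into / exit from the experimental context (chamber);
``cs_on:<label>`` / ``cs_off:<label>``
    onset / offset of the conditional stimulus named ``<label>``;
``gap_on:<label>`` / ``gap_off:<label>``
    the trace-conditioning gap state following CS offset;
``enter:<label>`` / ``exit:<label>``
    arrival at / departure from a location (concurrent schedules);
``response:<label>``, ``reinf:<label>``
    point events: a response and a reinforcement.

State labels used by :func:`state_windows` are ``"context"``,
``"cs:<label>"``, ``"gap:<label>"`` and ``"loc:<label>"``.

Boundary convention
-------------------
A named state's intervals are closed at both ends for event *counting*:
an event stamped exactly at CS offset belongs to the CS.  This is the
delay-conditioning convention in which the reinforcement that coincides
with CS termination is the CS's reinforcement (retrospective contingency
1).  Complement windows (context time outside a state) are open at both
ends, so state + complement partition the context's events exactly.
Durations are unaffected: duration = sum(end - start).
"""

from __future__ import annotations

import io
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, TextIO


class FormatError(ValueError):
    """Malformed event file: bad row, negative or decreasing times."""


class VocabularyError(ValueError):
    """An event code outside the declared vocabulary."""


class PairingError(ValueError):
    """State on/off events that do not pair up."""


class NoEvidenceError(ValueError):
    """A rate or ratio queried before any event defines it."""


_CODE_RE = re.compile(
    r"^(?:context_on|context_off|(?:cs_on|cs_off|gap_on|gap_off|enter|exit|response|reinf):[\w.\-]+)$"
)


def _check_code(code: str, vocabulary: set[str] | None) -> None:
    if vocabulary is not None:
        if code not in vocabulary:
            raise VocabularyError(f"event code {code!r} not in declared vocabulary")
    elif not _CODE_RE.match(code):
        raise VocabularyError(f"event code {code!r} not in the recognized vocabulary")


@dataclass(frozen=True, order=False)
class Event:
    """One row of the temporal map: a time stamp (s) and an event code."""

    time: float
    code: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FormatError(f"negative event time {self.time}")


@dataclass
class EventRecord:
    """Ordered time-stamped event log; ties keep input order (stable sort).

    ``t0`` is the session origin and ``t_end`` the current time; both
    default to the first/last event time when not given explicitly.
    """

    events: list[Event] = field(default_factory=list)
    t0: float = 0.0
    t_end: float | None = None
    vocabulary: set[str] | None = None

    def __post_init__(self) -> None:
        for ev in self.events:
            _check_code(ev.code, self.vocabulary)
        times = [ev.time for ev in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            # stable sort preserves input order among ties
            self.events = sorted(self.events, key=lambda ev: ev.time)
            times = [ev.time for ev in self.events]
        if self.t_end is None:
            self.t_end = times[-1] if times else self.t0
        if times and times[-1] > self.t_end:
            raise FormatError("t_end earlier than the last event")

    def __len__(self) -> int:
        return len(self.events)

    def times_of(self, code: str) -> list[float]:
        """Time stamps of all events carrying exactly this code."""
        return [ev.time for ev in self.events if ev.code == code]

    @property
    def duration(self) -> float:
        return self.t_end - self.t0


@dataclass
class StateWindow:
    """Disjoint sorted ``(start, end)`` intervals of one state.

    ``open_boundaries`` marks complement windows, whose intervals do not
    claim their endpoints for event counting (see module docstring).
    """

    label: str
    intervals: list[tuple[float, float]]
    open_boundaries: bool = False

    def __post_init__(self) -> None:
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty or inverted interval ({s}, {e}) in {self.label}")
        starts = [s for s, _ in self.intervals]
        if starts != sorted(starts):
            self.intervals = sorted(self.intervals)
        for (_, e1), (s2, _) in zip(self.intervals, self.intervals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping intervals in state {self.label}")

    @property
    def duration(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def contains(self, t: float) -> bool:
        for s, e in self.intervals:
            if self.open_boundaries:
                if s < t < e:
                    return True
            elif s <= t <= e:
                return True
        return False


@dataclass
class RateEstimate:
    """A count, the duration over which it was made, and their ratio."""

    count: int
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise NoEvidenceError("rate undefined over non-positive duration")
        if self.count < 0:
            raise ValueError("negative count")

    @property
    def rate(self) -> float:
        """Events per second."""
        return self.count / self.duration


# ---------------------------------------------------------------------------
# file I/O


def _open_source(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return io.StringIO(str(source)) if "\n" in str(source) else open(source, "r")


def load_events(source, vocabulary: set[str] | None = None) -> EventRecord:
    """Read a delimited event file into an :class:`EventRecord`.

    Format: UTF-8 text, optional header ``time_s,event``, ``#`` comment
    lines.  The default dialect stamps absolute times; a header comment
    ``# stamps=duration`` switches to duration stamps, which are
    converted to absolute times by cumulative summation.

    ``source`` may be a path, an open text stream, or a string
    containing newlines (treated as file content).
    """
    stream = _open_source(source)
    duration_dialect = False
    rows: list[tuple[float, str]] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if re.search(r"stamps\s*=\s*duration", line):
                    duration_dialect = True
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] in ("time_s", "time"):
                continue
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'time,code', got {line!r}")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad time {parts[0]!r}") from exc
            if t < 0:
                raise FormatError(f"line {lineno}: negative time {t}")
            rows.append((t, parts[1]))
    finally:
        if stream is not source:
            stream.close()

    if duration_dialect:
        acc = 0.0
        abs_rows = []
        for dt, code in rows:
            acc += dt
            abs_rows.append((acc, code))
        rows = abs_rows
    else:
        for (t1, _), (t2, _) in zip(rows, rows[1:]):
            if t2 < t1:
                raise FormatError("decreasing absolute time stamps")

    events = []
    for t, code in rows:
        _check_code(code, vocabulary)
        events.append(Event(t, code))
    return EventRecord(events=events, vocabulary=vocabulary)


def write_events(record: EventRecord, dest=None) -> str:
    """Emit the record as absolute-time delimited text; returns the text.

    ``dest`` may be a path or writable stream; when None only the string
    is returned.
    """
    lines = ["time_s,event"]
    for ev in record.events:
        lines.append(f"{ev.time:.10g},{ev.code}")
    text = "\n".join(lines) + "\n"
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# state extraction


def _on_off_codes(label: str) -> tuple[str, str]:
    if label == "context":
        return "context_on", "context_off"
    if ":" in label:
        kind, name = label.split(":", 1)
        if kind == "cs":
            return f"cs_on:{name}", f"cs_off:{name}"
        if kind == "gap":
            return f"gap_on:{name}", f"gap_off:{name}"
        if kind == "loc":
            return f"enter:{name}", f"exit:{name}"
    raise ValueError(f"unknown state label {label!r}")


def state_windows(record: EventRecord, label: str) -> StateWindow:
    """Pair on/off events of a state into disjoint ``[on, off)`` intervals.

    An unclosed final state is closed at ``t_end``.  An off event with no
    matching on, or a second on before the off, raises
    :class:`PairingError`.
    """
    on_code, off_code = _on_off_codes(label)
    intervals: list[tuple[float, float]] = []
    open_start: float | None = None
    for ev in record.events:
        if ev.code == on_code:
            if open_start is not None:
                raise PairingError(f"{on_code} at {ev.time} before previous {off_code}")
            open_start = ev.time
        elif ev.code == off_code:
            if open_start is None:
                raise PairingError(f"{off_code} at {ev.time} without matching {on_code}")
            intervals.append((open_start, ev.time))
            open_start = None
    if open_start is not None:
        if record.t_end > open_start:
            intervals.append((open_start, record.t_end))
        else:
            raise PairingError(f"state {label} opens at t_end with zero duration")
    return StateWindow(label=label, intervals=intervals)


def complement_windows(state: StateWindow, within: StateWindow) -> StateWindow:
    """Time inside ``within`` but outside ``state``, with open boundaries.

    Together with ``state`` this partitions the events of ``within``:
    an event at a shared boundary counts toward the named state only.
    """
    result: list[tuple[float, float]] = []
    for ws, we in within.intervals:
        cursor = ws
        for s, e in state.intervals:
            s, e = max(s, ws), min(e, we)
            if e <= s:
                continue
            if s > cursor:
                result.append((cursor, s))
            cursor = max(cursor, e)
        if we > cursor:
            result.append((cursor, we))
    return StateWindow(
        label=f"{within.label}~{state.label}", intervals=result, open_boundaries=True
    )


def conditional_rate(
    record: EventRecord,
    event_code: str,
    state: StateWindow | None = None,
) -> RateEstimate:
    """Count of ``event_code`` events inside ``state``, over its duration.

    With ``state=None`` the whole-context rate is returned: all events of
    the code over the total context duration (context windows when
    context on/off events exist, else ``t_end - t0``) -- without regard
    to whether any CS is present.
    """
    if state is None:
        if any(ev.code == "context_on" for ev in record.events):
            state = state_windows(record, "context")
        else:
            if record.duration <= 0:
                raise NoEvidenceError("record has zero duration")
            state = StateWindow("context", [(record.t0, record.t_end)])
    dur = state.duration
    if dur <= 0:
        raise NoEvidenceError(f"state {state.label} has zero cumulative duration")
    count = sum(
        1 for ev in record.events if ev.code == event_code and state.contains(ev.time)
    )
    return RateEstimate(count=count, duration=dur)


# ---------------------------------------------------------------------------
# interval extraction (Fig. 3 geometry)


def forward_intervals(
    record: EventRecord,
    from_code: str,
    to_code: str,
    close_at_end: bool = False,
) -> list[float]:
    """For each ``from_code`` event, the wait to the next ``to_code`` event
    at or after it (0 for co-timed events).

    Trailing censored intervals (no later ``to_code`` event) are dropped
    unless ``close_at_end``, in which case they are closed at ``t_end``.
    """
    to_times = record.times_of(to_code)
    out = []
    for t in record.times_of(from_code):
        idx = bisect_left(to_times, t)
        if idx < len(to_times):
            out.append(to_times[idx] - t)
        elif close_at_end:
            out.append(record.t_end - t)
    return out


def backward_intervals(
    record: EventRecord,
    from_code: str,
    to_code: str,
    close_at_start: bool = False,
) -> list[float]:
    """For each ``from_code`` event, the interval back to the most recent
    ``to_code`` event at or before it.

    Leading censored intervals (a ``from_code`` event before any
    ``to_code`` event) are dropped unless ``close_at_start``, in which
    case they are closed at ``t0``.
    """
    to_times = record.times_of(to_code)
    out = []
    for t in record.times_of(from_code):
        idx = bisect_right(to_times, t) - 1
        if idx >= 0:
            out.append(t - to_times[idx])
        elif close_at_start:
            out.append(t - record.t0)
    return out


def contextual_rate_iti(
    record: EventRecord,
    event_code: str,
    exclude_labels: Iterable[str],
) -> RateEstimate:
    """Contextual rate with the intertrial-interval denominator.

    The count is the record's full event count for ``event_code``; the
    duration is context time minus the cumulative durations of the
    excluded states (CSs and, for trace protocols, gap states).  This is
    the contextual-rate variant in which only ITI time carries the
    context's predictive burden.
    """
    if any(ev.code == "context_on" for ev in record.events):
        context = state_windows(record, "context")
    else:
        context = StateWindow("context", [(record.t0, record.t_end)])
    window = context
    for lab in exclude_labels:
        window = complement_windows(state_windows(record, lab), window)
    dur = window.duration
    if dur <= 0:
        raise NoEvidenceError("no intertrial time remains after exclusions")
    count = sum(
        1 for ev in record.events
        if ev.code == event_code and context.contains(ev.time)
    )
    return RateEstimate(count=count, duration=dur)


def scale_times(record: EventRecord, c: float) -> EventRecord:
    """A copy of the record with all times multiplied by ``c > 0``.

    Durations scale by ``c``, rates by ``1/c``, and every count -- hence
    every informativeness ratio -- is unchanged (time-scale invariance).
    """
    if c <= 0:
        raise ValueError("scale factor must be positive")
    return EventRecord(
        events=[Event(ev.time * c, ev.code) for ev in record.events],
        t0=record.t0 * c,
        t_end=record.t_end * c,
        vocabulary=record.vocabulary,
    )
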