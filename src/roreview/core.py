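"""Core domain model: events, labeled intervals, domain sequences, episodes.

A resuscitation episode is represented as two run-length encoded label
timelines. The *therapy* domain records what rescuers did — chest
compression sequences (``C``), hands-off intervals (``H``) and
defibrillation shocks (``D``). The *response* domain records the patient's
cardiac rhythm — ventricular fibrillation (``VF``), ventricular tachycardia
(``VT``), asystole (``AS``), pulseless electrical activity (``PE``), a
pulse-giving rhythm (``PR``) or unknown (``UN``). Both timelines are built
from minimal event annotations: ``c1``/``c2`` and ``d1``/``d2`` mark the
start/end of compressions and defibrillations; lower-case rhythm codes mark
transitions into the corresponding rhythm state.

Intervals are half-open ``[start, end)`` so that every time point inside a
sequence's span maps to exactly one state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence, Tuple

from .errors import (
    EmptyDomainError,
    OutOfSpanError,
    OverlapError,
    PairingError,
    RoreviewError,
)

#: Therapy event codes: compression start/stop, defibrillation start/stop.
THERAPY_EVENT_CODES = frozenset({"c1", "c2", "d1", "d2"})
#: Rhythm transition codes (``un`` marks a transition into unknown rhythm).
RHYTHM_EVENT_CODES = frozenset({"vf", "vt", "as", "pe", "pr", "un"})

THERAPY_STATES = ("C", "H", "D")
RHYTHM_STATES = ("VF", "VT", "AS", "PE", "PR", "UN")

#: Numeric slop for contiguity checks; times carry millisecond resolution.
TIME_EPS = 1e-9
#: Tolerance for matching annotated d1 times against log shock times.
SHOCK_MATCH_TOL_S = 1e-3


@dataclass(frozen=True)
class Event:
    """A timestamped primary information object (therapy or rhythm event).

    Parameters
    ----------
    code:
        One of ``c1 c2 d1 d2`` (therapeutic) or ``vf vt as pe pr un``
        (rhythmic).
    time:
        Elapsed seconds since episode start (device power-on); finite, >= 0.
    """

    code: str
    time: float

    def __post_init__(self) -> None:
        if self.code not in THERAPY_EVENT_CODES | RHYTHM_EVENT_CODES:
            raise RoreviewError(f"unknown event code {self.code!r}")
        if not (math.isfinite(self.time) and self.time >= 0):
            raise RoreviewError(
                f"event time must be finite and >= 0, got {self.time!r}"
            )

    @property
    def is_therapeutic(self) -> bool:
        return self.code in THERAPY_EVENT_CODES


@dataclass(frozen=True)
class StateInterval:
    """A labeled half-open time interval ``[start, end)`` holding one state."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise RoreviewError(
                f"zero/negative-length interval [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def _check_labels(domain: str, intervals: Sequence[StateInterval]) -> None:
    if domain == "therapy":
        allowed = set(THERAPY_STATES)
    elif domain == "response":
        allowed = set(RHYTHM_STATES)
    elif domain == "combined":
        allowed = {t + r for t in THERAPY_STATES for r in RHYTHM_STATES}
    else:
        raise RoreviewError(f"unknown domain {domain!r}")
    for iv in intervals:
        if iv.label not in allowed:
            raise RoreviewError(
                f"label {iv.label!r} not valid in {domain} domain"
            )


@dataclass(frozen=True)
class DomainSequence:
    """An ordered, contiguous sequence of labeled intervals for one domain.

    Invariants (checked on construction): intervals are contiguous with no
    gaps or overlaps; in the therapy and response domains adjacent intervals
    never repeat a label (maximal runs); the span equals the first interval's
    start through the last interval's end. An *empty* sequence (no covered
    time, e.g. the result of restricting to a disjoint window) carries no
    intervals and a ``None`` span.
    """

    domain: str
    intervals: Tuple[StateInterval, ...]
    span_start: Optional[float]
    span_end: Optional[float]

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            if self.span_start is not None or self.span_end is not None:
                raise RoreviewError("empty sequence must have a None span")
            _check_labels(self.domain, ivs)
            return
        _check_labels(self.domain, ivs)
        for a, b in zip(ivs, ivs[1:]):
            if abs(a.end - b.start) > TIME_EPS:
                raise RoreviewError(
                    f"intervals not contiguous at {a.end} -> {b.start}"
                )
            if self.domain in ("therapy", "response") and a.label == b.label:
                raise RoreviewError(
                    f"adjacent intervals share label {a.label!r} at {a.end}"
                )
        if (
            abs(self.span_start - ivs[0].start) > TIME_EPS
            or abs(self.span_end - ivs[-1].end) > TIME_EPS
        ):
            raise RoreviewError("span does not match interval extent")

    # -- constructors ----------------------------------------------------

    @classmethod
    def empty(cls, domain: str) -> "DomainSequence":
        return cls(domain=domain, intervals=(), span_start=None, span_end=None)

    @classmethod
    def from_intervals(
        cls, domain: str, intervals: Iterable[StateInterval]
    ) -> "DomainSequence":
        ivs = tuple(intervals)
        if not ivs:
            return cls.empty(domain)
        return cls(domain, ivs, ivs[0].start, ivs[-1].end)

    # -- views -----------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)

    @property
    def transition_times(self) -> Tuple[float, ...]:
        """All boundary times, span edges included."""
        if self.is_empty:
            return ()
        return tuple(iv.start for iv in self.intervals) + (self.span_end,)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    # convenience delegates (implementations live in roreview.algebra)
    def state_at(self, t: float) -> Optional[str]:
        from .algebra import state_at

        return state_at(self, t)

    def restrict(self, start: float, end: float) -> "DomainSequence":
        from .algebra import restrict

        return restrict(self, start, end)


def _merge_adjacent(pieces: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
    merged: list[tuple[float, float, str]] = []
    for s, e, lab in pieces:
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - s) <= TIME_EPS:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


def build_therapy_sequence(
    events: Sequence[Event], span_start: float, span_end: float
) -> DomainSequence:
    """Build the therapy timeline from c1/c2/d1/d2 events.

    Every ``c1``–``c2`` pair becomes a ``C`` interval and every ``d1``–``d2``
    pair a ``D`` interval; all uncovered time in ``[span_start, span_end)``
    is hands-off (``H``). Unpaired or overlapping events raise
    :class:`PairingError` / :class:`OverlapError` — these signal corrupt
    annotations, never recoverable data.
    """
    if not span_start < span_end:
        raise RoreviewError("span_start must precede span_end")
    covered: list[tuple[float, float, str]] = []
    open_c: Optional[float] = None
    open_d: Optional[float] = None
    last_t = -math.inf
    for ev in events:
        if ev.code not in THERAPY_EVENT_CODES:
            raise RoreviewError(f"non-therapeutic event {ev.code!r} in therapy build")
        if ev.time < last_t:
            raise RoreviewError(f"therapy events not sorted at t={ev.time}")
        last_t = ev.time
        if ev.time < span_start - TIME_EPS or ev.time > span_end + TIME_EPS:
            raise OutOfSpanError(
                f"therapy event {ev.code}@{ev.time} outside span "
                f"[{span_start}, {span_end}]"
            )
        if ev.code == "c1":
            if open_c is not None:
                raise PairingError(f"c1@{ev.time} before previous c1@{open_c} closed")
            if open_d is not None:
                raise OverlapError(f"c1@{ev.time} inside open defibrillation @{open_d}")
            open_c = ev.time
        elif ev.code == "c2":
            if open_c is None:
                raise PairingError(f"c2@{ev.time} without a preceding c1")
            if not open_c < ev.time:
                raise PairingError(f"c2@{ev.time} not after its c1@{open_c}")
            covered.append((open_c, ev.time, "C"))
            open_c = None
        elif ev.code == "d1":
            if open_d is not None:
                raise PairingError(f"d1@{ev.time} before previous d1@{open_d} closed")
            if open_c is not None:
                raise OverlapError(f"d1@{ev.time} inside open compression @{open_c}")
            open_d = ev.time
        else:  # d2
            if open_d is None:
                raise PairingError(f"d2@{ev.time} without a preceding d1")
            if not open_d < ev.time:
                raise PairingError(f"d2@{ev.time} not after its d1@{open_d}")
            covered.append((open_d, ev.time, "D"))
            open_d = None
    if open_c is not None:
        raise PairingError(f"unclosed c1@{open_c}")
    if open_d is not None:
        raise PairingError(f"unclosed d1@{open_d}")

    covered.sort(key=lambda p: p[0])
    for a, b in zip(covered, covered[1:]):
        if b[0] < a[1] - TIME_EPS:
            raise OverlapError(
                f"{a[2]} interval ending {a[1]} overlaps {b[2]} starting {b[0]}"
            )

    pieces: list[tuple[float, float, str]] = []
    cursor = span_start
    for s, e, lab in covered:
        if s > cursor + TIME_EPS:
            pieces.append((cursor, s, "H"))
        pieces.append((max(s, cursor), e, lab))
        cursor = e
    if cursor < span_end - TIME_EPS:
        pieces.append((cursor, span_end, "H"))
    pieces = _merge_adjacent(pieces)
    return DomainSequence.from_intervals(
        "therapy", (StateInterval(s, e, lab) for s, e, lab in pieces)
    )


def build_response_sequence(
    events: Sequence[Event], span_end: float
) -> DomainSequence:
    """Build the rhythm timeline from transition events.

    Each rhythm code opens its upper-case state, lasting until the next
    transition or ``span_end``. The sequence starts at the first event's
    time: the response domain is *undefined* before its first annotation.
    Simultaneous transitions are rejected (physically meaningless).
    """
    if not events:
        raise EmptyDomainError("no rhythm events: response domain undefined")
    last_t = -math.inf
    for ev in events:
        if ev.code not in RHYTHM_EVENT_CODES:
            raise RoreviewError(f"non-rhythmic event {ev.code!r} in response build")
        if ev.time <= last_t:
            raise RoreviewError(
                f"rhythm events must be strictly increasing (t={ev.time})"
            )
        last_t = ev.time
        if ev.time >= span_end:
            raise OutOfSpanError(
                f"rhythm event {ev.code}@{ev.time} at/after span end {span_end}"
            )
    pieces = []
    for ev, nxt in zip(events, list(events[1:]) + [None]):
        end = span_end if nxt is None else nxt.time
        pieces.append((ev.time, end, ev.code.upper()))
    pieces = _merge_adjacent(pieces)
    return DomainSequence.from_intervals(
        "response", (StateInterval(s, e, lab) for s, e, lab in pieces)
    )


@dataclass(frozen=True)
class ShockRecord:
    """One delivered shock as logged by the defibrillator."""

    time: float
    energy_j: Optional[float] = None
    impedance_ohm: Optional[float] = None


@dataclass(frozen=True)
class ModeSwitch:
    """A device mode change; ``mode`` is ``manual`` or ``advisory``."""

    time: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "advisory"):
            raise RoreviewError(f"unknown device mode {self.mode!r}")


@dataclass(frozen=True)
class Episode:
    """A fully assembled episode: timelines plus device log facts.

    ``power_on`` is the absolute wall-clock time the device was switched on
    (``None`` when unknown); all sequence times are elapsed seconds from it.
    """

    therapy: DomainSequence
    response: DomainSequence
    shocks: Tuple[ShockRecord, ...] = ()
    mode_switches: Tuple[ModeSwitch, ...] = ()
    power_on: Optional[datetime] = None
    episode_id: str = "episode"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shocks", tuple(self.shocks))
        object.__setattr__(self, "mode_switches", tuple(self.mode_switches))
        times = [s.time for s in self.shocks]
        if times != sorted(times):
            raise RoreviewError("shock records must be sorted by time")
        d_starts = [
            iv.start for iv in self.therapy.intervals if iv.label == "D"
        ]
        if len(d_starts) != len(times):
            raise RoreviewError(
                f"{len(d_starts)} D intervals vs {len(times)} shock records"
            )
        for d, t in zip(d_starts, times):
            if abs(d - t) > SHOCK_MATCH_TOL_S:
                raise RoreviewError(
                    f"D interval at {d} has no shock record within 1 ms (got {t})"
                )

    @property
    def span_start(self) -> float:
        return self.therapy.span_start

    @property
    def span_end(self) -> float:
        return self.therapy.span_end
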