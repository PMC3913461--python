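"""Interval algebra over domain sequences.

The combined episode representation is the join of the therapy and response
timelines: a change in either domain is a change of the combined state, and
the combined label is the therapy label concatenated with the rhythm label
(therapy first, e.g. ``HVF``, ``CUN``). The remaining primitives —
restriction to a window, point query, label search — are the vocabulary the
review engine reasons with.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Optional

from .core import DomainSequence, StateInterval, TIME_EPS
from .errors import DisjointDomainsError, RoreviewError


def state_at(seq: DomainSequence, t: float) -> Optional[str]:
    """Label of the interval with ``start <= t < end``; None outside span."""
    if seq.is_empty or t < seq.span_start or t >= seq.span_end:
        return None
    starts = [iv.start for iv in seq.intervals]
    i = bisect_right(starts, t) - 1
    return seq.intervals[i].label


def restrict(
    seq: DomainSequence, window_start: float, window_end: float
) -> DomainSequence:
    """Clip a sequence to ``[window_start, window_end)``.

    Partially overlapping intervals are truncated with their labels kept.
    An empty overlap is a valid outcome and yields an empty sequence.
    """
    if not window_start < window_end:
        raise RoreviewError("window_start must precede window_end")
    if seq.is_empty:
        return DomainSequence.empty(seq.domain)
    lo = max(window_start, seq.span_start)
    hi = min(window_end, seq.span_end)
    if lo >= hi - TIME_EPS:
        return DomainSequence.empty(seq.domain)
    out = []
    for iv in seq.intervals:
        s = max(iv.start, lo)
        e = min(iv.end, hi)
        if e - s > TIME_EPS:
            out.append(StateInterval(s, e, iv.label))
    return DomainSequence.from_intervals(seq.domain, out)


def find_label(
    seq: DomainSequence, label: str, which: str = "first"
) -> Optional[StateInterval]:
    """First or last interval carrying exactly ``label``; None if absent."""
    if which not in ("first", "last"):
        raise RoreviewError("which must be 'first' or 'last'")
    ivs = seq.intervals if which == "first" else reversed(seq.intervals)
    for iv in ivs:
        if iv.label == label:
            return iv
    return None


def combine(
    therapy: DomainSequence, response: DomainSequence
) -> DomainSequence:
    """Join the two domains over their common window.

    The result spans the intersection of the two domains' spans; its
    transition times are the union of both domains' transition times inside
    that window, and each piece is labeled with the concatenation of the two
    point-query labels. Coincident boundaries collapse to one transition;
    zero-length pieces are discarded.
    """
    if therapy.is_empty or response.is_empty:
        raise RoreviewError("combine requires two non-empty sequences")
    lo = max(therapy.span_start, response.span_start)
    hi = min(therapy.span_end, response.span_end)
    if lo >= hi - TIME_EPS:
        raise DisjointDomainsError(
            f"domains share no time: [{therapy.span_start},{therapy.span_end}) "
            f"vs [{response.span_start},{response.span_end})"
        )
    cuts = sorted(
        t
        for t in set(therapy.transition_times) | set(response.transition_times)
        if lo - TIME_EPS < t < hi + TIME_EPS
    )
    # collapse boundary coincidences (numerically identical within eps)
    times = [lo]
    for t in cuts:
        if t - times[-1] > TIME_EPS:
            times.append(t)
    if hi - times[-1] > TIME_EPS:
        times.append(hi)
    else:
        times[-1] = hi
    pieces = []
    for a, b in zip(times, times[1:]):
        mid = 0.5 * (a + b)
        lab = state_at(therapy, mid) + state_at(response, mid)
        pieces.append((a, b, lab))
    # adjacent pieces with equal labels cannot arise from maximal inputs,
    # but merge defensively so the invariant holds for any caller
    merged: list[tuple[float, float, str]] = []
    for s, e, lab in pieces:
        if merged and merged[-1][2] == lab:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return DomainSequence.from_intervals(
        "combined", (StateInterval(s, e, lab) for s, e, lab in merged)
    )
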