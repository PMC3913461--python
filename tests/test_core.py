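"""Therapy/response sequence construction and its invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import roreview as rv
from roreview.core import Event
from roreview.errors import (
    EmptyDomainError,
    OutOfSpanError,
    OverlapError,
    PairingError,
    RoreviewError,
)

from conftest import EQ4_RESPONSE, EQ4_THERAPY, as_tuples, grid_labels


class TestTherapyBuild:
    def test_published_tracing(self, eq4_therapy):
        assert as_tuples(eq4_therapy) == EQ4_THERAPY

    def test_no_events_is_all_hands_off(self):
        seq = rv.build_therapy_sequence([], 0.0, 10.0)
        assert as_tuples(seq) == ((0.0, 10.0, "H"),)

    def test_adjacent_compressions_merge(self):
        # back-to-back c-pairs collapse into one maximal C run
        ev = [Event("c1", 1.0), Event("c2", 2.0), Event("c1", 2.0), Event("c2", 3.0)]
        seq = rv.build_therapy_sequence(ev, 0.0, 4.0)
        assert seq.labels == ("H", "C", "H")

    @pytest.mark.parametrize(
        "events,exc",
        [
            ([Event("c1", 1.0)], PairingError),
            ([Event("c2", 1.0)], PairingError),
            ([Event("c1", 1.0), Event("c1", 2.0)], PairingError),
            ([Event("d1", 1.0), Event("d1", 2.0)], PairingError),
            ([Event("d2", 1.0)], PairingError),
            ([Event("c1", 1.0), Event("d1", 2.0)], OverlapError),
            ([Event("d1", 1.0), Event("c1", 2.0)], OverlapError),
            ([Event("c1", 5.0), Event("c2", 20.0)], OutOfSpanError),
        ],
    )
    def test_corrupt_annotations_rejected(self, events, exc):
        with pytest.raises(exc):
            rv.build_therapy_sequence(events, 0.0, 10.0)

    def test_error_names_offending_time(self):
        with pytest.raises(PairingError, match="3.7"):
            rv.build_therapy_sequence([Event("c1", 3.7)], 0.0, 10.0)

    def test_grid_oracle_on_random_pairings(self):
        """Per-timepoint label equals a brute-force point classifier."""
        rng = np.random.default_rng(20140112)
        for _ in range(500):
            n_c = int(rng.integers(0, 4))
            n_d = int(rng.integers(0, 3))
            bounds = np.sort(rng.uniform(0, 60, 2 * (n_c + n_d)).round(2))
            if len(set(bounds)) != len(bounds):
                continue
            pairs = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_c + n_d)]
            kinds = ["c"] * n_c + ["d"] * n_d
            rng.shuffle(kinds)
            events = []
            for (a, b), kind in zip(pairs, kinds):
                events.append(Event(f"{kind}1", float(a)))
                events.append(Event(f"{kind}2", float(b)))
            events.sort(key=lambda e: e.time)
            seq = rv.build_therapy_sequence(events, 0.0, 60.0)
            grid = np.arange(0.0, 60.0, 0.01)
            expected = np.array(["H"] * len(grid), dtype=object)
            for (a, b), kind in zip(pairs, kinds):
                expected[(grid >= a) & (grid < b)] = "C" if kind == "c" else "D"
            got = grid_labels(seq, grid)
            assert (got == expected).all()


class TestResponseBuild:
    @pytest.mark.parametrize(
        "events,span_end,expected",
        [
            (
                [Event("vf", 793.6), Event("pe", 908.3), Event("vf", 944.0)],
                1062.0,
                EQ4_RESPONSE,
            ),
            (
                [Event("vf", 46.0), Event("as", 208.0), Event("pe", 258.0), Event("vf", 283.0)],
                343.0,
                (
                    (46.0, 208.0, "VF"),
                    (208.0, 258.0, "AS"),
                    (258.0, 283.0, "PE"),
                    (283.0, 343.0, "VF"),
                ),
            ),
            ([Event("as", 0.0)], 5.0, ((0.0, 5.0, "AS"),)),
        ],
    )
    def test_examples(self, events, span_end, expected):
        assert as_tuples(rv.build_response_sequence(events, span_end)) == expected

    def test_consecutive_identical_codes_merge(self):
        seq = rv.build_response_sequence(
            [Event("vf", 0.0), Event("vf", 2.0), Event("as", 5.0)], 10.0
        )
        assert as_tuples(seq) == ((0.0, 5.0, "VF"), (5.0, 10.0, "AS"))

    def test_empty_events_rejected(self):
        with pytest.raises(EmptyDomainError):
            rv.build_response_sequence([], 10.0)

    def test_event_at_span_end_rejected(self):
        with pytest.raises(OutOfSpanError):
            rv.build_response_sequence([Event("vf", 0.0), Event("as", 10.0)], 10.0)

    def test_simultaneous_transitions_rejected(self):
        with pytest.raises(RoreviewError):
            rv.build_response_sequence([Event("vf", 1.0), Event("as", 1.0)], 10.0)


@given(st.integers(0, 10_000))
def test_sequence_invariants_on_random_episodes(seed):
    """Conservation of time, maximality, and rebuild idempotence."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))
    events = []
    t = 0.0
    for _ in range(n):
        t = round(t + float(rng.uniform(0.5, 5.0)), 2)
        a = t
        t = round(t + float(rng.uniform(0.5, 5.0)), 2)
        kind = "c" if rng.uniform() < 0.7 else "d"
        events += [Event(f"{kind}1", a), Event(f"{kind}2", t)]
    span_end = round(t + 1.0, 2)
    seq = rv.build_therapy_sequence(events, 0.0, span_end)
    # conservation of time
    assert abs(sum(iv.duration for iv in seq) - span_end) < 1e-9
    # maximality
    for a, b in zip(seq.intervals, seq.intervals[1:]):
        assert a.label != b.label
    # idempotence: rebuild from the sequence's own transition points
    rebuilt = []
    for iv in seq.intervals:
        if iv.label in ("C", "D"):
            k = iv.label.lower()
            rebuilt += [Event(f"{k}1", iv.start), Event(f"{k}2", iv.end)]
    assert rv.build_therapy_sequence(rebuilt, 0.0, span_end) == seq


def test_episode_requires_matching_shock_records(eq4_therapy, eq4_response):
    with pytest.raises(RoreviewError, match="shock record"):
        rv.Episode(
            therapy=eq4_therapy,
            response=eq4_response,
            shocks=(rv.ShockRecord(900.0, 200.0, 80.0),),  # no D starts at 900
        )
    with pytest.raises(RoreviewError, match="D intervals"):
        rv.Episode(therapy=eq4_therapy, response=eq4_response, shocks=())
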