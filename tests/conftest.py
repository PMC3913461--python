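"""Shared fixtures: the published worked example and random-sequence helpers."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roreview as rv
from roreview.core import Event

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


EQ4_THERAPY = (
    (740.8, 805.2, "H"),
    (805.2, 887.2, "C"),
    (887.2, 903.3, "H"),
    (903.3, 908.3, "D"),
    (908.3, 938.8, "H"),
    (938.8, 1062.0, "C"),
)
EQ4_RESPONSE = (
    (793.6, 908.3, "VF"),
    (908.3, 944.0, "PE"),
    (944.0, 1062.0, "VF"),
)
EQ5_COMBINED = (
    (793.6, 805.2, "HVF"),
    (805.2, 887.2, "CVF"),
    (887.2, 903.3, "HVF"),
    (903.3, 908.3, "DVF"),
    (908.3, 938.8, "HPE"),
    (938.8, 944.0, "CPE"),
    (944.0, 1062.0, "CVF"),
)


def as_tuples(seq: rv.DomainSequence):
    return tuple((iv.start, iv.end, iv.label) for iv in seq.intervals)


@pytest.fixture
def eq4_therapy_events():
    return [
        Event("c1", 805.2),
        Event("c2", 887.2),
        Event("d1", 903.3),
        Event("d2", 908.3),
        Event("c1", 938.8),
        Event("c2", 1062.0),
    ]


@pytest.fixture
def eq4_response_events():
    return [Event("vf", 793.6), Event("pe", 908.3), Event("vf", 944.0)]


@pytest.fixture
def eq4_therapy(eq4_therapy_events):
    return rv.build_therapy_sequence(eq4_therapy_events, 740.8, 1062.0)


@pytest.fixture
def eq4_response(eq4_response_events):
    return rv.build_response_sequence(eq4_response_events, 1062.0)


@pytest.fixture
def eq4_episode(eq4_therapy, eq4_response):
    """The tracing's episode with its single shock at 903.3 s."""
    return rv.Episode(
        therapy=eq4_therapy,
        response=eq4_response,
        shocks=(rv.ShockRecord(903.3, 200.0, 85.0),),
        power_on=datetime(2011, 3, 14, 14, 30, 0),
        episode_id="tracing",
    )


@pytest.fixture
def narrative_episode():
    """The single-shock episode of the 180-330 s walkthrough.

    Shock delivered at 198 s; rhythm VF from 46 s, asystole at 208 s, an
    organized rhythm at 258 s and VF recurring at 283 s; compressions from
    205 to 322 s; recording ends at 343 s.
    """
    therapy = rv.build_therapy_sequence(
        [
            Event("d1", 198.0),
            Event("d2", 203.0),
            Event("c1", 205.0),
            Event("c2", 322.0),
        ],
        0.0,
        343.0,
    )
    response = rv.build_response_sequence(
        [
            Event("vf", 46.0),
            Event("as", 208.0),
            Event("pe", 258.0),
            Event("vf", 283.0),
        ],
        343.0,
    )
    return rv.Episode(
        therapy=therapy,
        response=response,
        shocks=(rv.ShockRecord(198.0, 150.0, 85.0),),
        power_on=datetime(2011, 3, 14, 14, 30, 0),
        episode_id="walkthrough",
    )


# -- random sequence helpers (used by oracle-backed property tests) -------


def random_domain_sequence(
    rng: np.random.Generator, domain: str, span_start: float = 0.0
) -> rv.DomainSequence:
    labels = ("C", "H", "D") if domain == "therapy" else ("VF", "VT", "AS", "PE", "PR", "UN")
    n = int(rng.integers(1, 9))
    t = round(span_start + float(rng.uniform(0, 3)), 2)
    ivs = []
    prev = None
    for _ in range(n):
        dur = round(float(rng.uniform(0.1, 4.0)), 2)
        lab = rng.choice([l for l in labels if l != prev])
        ivs.append(rv.StateInterval(t, round(t + dur, 10), str(lab)))
        prev = str(lab)
        t = round(t + dur, 10)
    return rv.DomainSequence.from_intervals(domain, ivs)


def grid_labels(seq: rv.DomainSequence, grid: np.ndarray) -> np.ndarray:
    """Independent point classifier: linear interval-mask assignment."""
    out = np.array([None] * len(grid), dtype=object)
    for iv in seq.intervals:
        out[(grid >= iv.start) & (grid < iv.end)] = iv.label
    return out
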