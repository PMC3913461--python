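"""Wall-clock arithmetic and the sentinel-code system for hr/mn/sc triplets.

The manual registry stores every time variable as three integer columns
(hour, minute, second of day). Besides valid times the columns carry
sentinel triplets: ``99:99:99`` (unknown / no VF onset, patient remained in
VF), ``88:88:88`` (no CPR administered) and ``66:66:66`` (no data
available). Manual records are occasionally blanked to the literals
``00:00:00`` or ``12:00:00``; those are treated as missing only when the
source marks them as such.

Elapsed device times are reconciled with wall-clock times through a serial
day number — fractional days since January 1 of year 0 in the proleptic
Gregorian calendar (January 1 of year 1 maps to 367). Only differences and
round trips are observable, and both are exact to 1 ms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional

from .errors import MalformedCodeError

#: Offset such that day numbers count from Jan 1 of year 0.
_SERIAL_OFFSET_DAYS = 366


@dataclass(frozen=True)
class ClockTriplet:
    """An hour/minute/second triplet as stored in the registry."""

    hr: int
    mn: int
    sc: int

    def __str__(self) -> str:  # 14:33:18 style
        return f"{self.hr:02d}:{self.mn:02d}:{self.sc:02d}"

    def seconds_of_day(self) -> int:
        """Seconds since midnight; only meaningful for valid triplets."""
        return self.hr * 3600 + self.mn * 60 + self.sc


UNKNOWN_99 = ClockTriplet(99, 99, 99)
NO_CPR_88 = ClockTriplet(88, 88, 88)
NO_DATA_66 = ClockTriplet(66, 66, 66)
_SENTINELS = {UNKNOWN_99, NO_CPR_88, NO_DATA_66}
_SUSPECT_LITERALS = {ClockTriplet(0, 0, 0), ClockTriplet(12, 0, 0)}


class SentinelClass(enum.Enum):
    """Total classification of a triplet; every triplet maps to one class."""

    VALID = "valid"
    UNKNOWN_99 = "unknown_99"
    NO_CPR_88 = "no_cpr_88"
    NO_DATA_66 = "no_data_66"
    SUSPECT_LITERAL = "suspect_literal"


def classify_triplet(
    t: ClockTriplet, literal_flagged: bool = False
) -> SentinelClass:
    """Classify a triplet as valid, a sentinel, or a flagged literal.

    ``literal_flagged`` marks that the source database flags ``00:00:00`` /
    ``12:00:00`` entries as blanked-out values; without the flag those are
    ordinary valid times. Out-of-range non-sentinel values raise
    :class:`MalformedCodeError`.
    """
    if t == UNKNOWN_99:
        return SentinelClass.UNKNOWN_99
    if t == NO_CPR_88:
        return SentinelClass.NO_CPR_88
    if t == NO_DATA_66:
        return SentinelClass.NO_DATA_66
    if not (0 <= t.hr <= 23 and 0 <= t.mn <= 59 and 0 <= t.sc <= 59):
        raise MalformedCodeError(f"triplet {t} is neither a time nor a sentinel")
    if literal_flagged and t in _SUSPECT_LITERALS:
        return SentinelClass.SUSPECT_LITERAL
    return SentinelClass.VALID


def is_missing(cls: SentinelClass) -> bool:
    return cls is not SentinelClass.VALID


# -- serial day numbers --------------------------------------------------


def to_serial_day_number(ts: datetime) -> float:
    """Fractional days from January 1 of year 0 (proleptic Gregorian)."""
    day_frac = (
        ts.hour * 3600 + ts.minute * 60 + ts.second + ts.microsecond / 1e6
    ) / 86400.0
    return ts.toordinal() + _SERIAL_OFFSET_DAYS + day_frac


def from_serial_day_number(serial: float) -> datetime:
    """Inverse of :func:`to_serial_day_number`, exact to 1 ms."""
    days = serial - _SERIAL_OFFSET_DAYS
    ordinal = int(days)
    frac = days - ordinal
    base = datetime.fromordinal(ordinal)
    # round to the nearest millisecond to absorb float dust
    us = round(frac * 86400.0 * 1e3) * 1000
    return base + timedelta(microseconds=us)


def _round_half_up_seconds(ts: datetime) -> datetime:
    if ts.microsecond >= 500_000:
        ts = ts + timedelta(seconds=1)
    return ts.replace(microsecond=0)


def elapsed_to_absolute(
    elapsed: float, power_on: Optional[datetime]
) -> ClockTriplet:
    """Time-of-day triplet of ``power_on + elapsed`` seconds.

    The conversion runs through the serial day number: power-on is turned
    into fractional days, the elapsed seconds are added, and the sum is
    converted back to a calendar time rounded half-up to whole seconds.
    Day rollover yields the time of the following day. When ``power_on``
    is unknown the sentinel ``99:99:99`` propagates.
    """
    if power_on is None:
        return UNKNOWN_99
    if elapsed < 0:
        raise MalformedCodeError(f"elapsed time must be >= 0, got {elapsed}")
    serial = to_serial_day_number(power_on) + elapsed / 86400.0
    abs_ts = _round_half_up_seconds(from_serial_day_number(serial))
    return ClockTriplet(abs_ts.hour, abs_ts.minute, abs_ts.second)


def absolute_to_elapsed(t: ClockTriplet, power_on: datetime) -> float:
    """Elapsed seconds from power-on to the first occurrence of triplet ``t``.

    The triplet carries no date, so the earliest non-negative elapsed time
    is returned (cross-midnight handled modulo 24 h).
    """
    if classify_triplet(t) is not SentinelClass.VALID:
        raise MalformedCodeError(f"cannot convert sentinel {t} to elapsed time")
    on = power_on.hour * 3600 + power_on.minute * 60 + power_on.second
    return float((t.seconds_of_day() - on) % 86400)


def triplet_delta_seconds(a: ClockTriplet, b: ClockTriplet) -> int:
    """Minimal absolute difference between two valid triplets, modulo 24 h."""
    d = abs(a.seconds_of_day() - b.seconds_of_day())
    return min(d, 86400 - d)
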