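"""Concordance audit between a manual and a derived review database.

Every compared cell receives exactly one of three codes: correct (1),
wrong (2) or missing (3). Time variables are correct when the absolute
deviation is within the tolerance (default 1 s; deviations are computed
modulo 24 h so a midnight rollover cannot produce a day-sized error) and
missing when *either* side carries a sentinel code (66/88/99) or a flagged
blank literal. Categorical codes are correct only when identical; the
device readings ``imp`` and ``enrgy`` are compared as integers with zero
allowed deviation.

The summary reports, per variable, the three counts, the match rate
correct/(correct+wrong) and — for time variables — the share of missing
cells where both sides used the same missing code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import AlignmentError
from .episode_io import (
    CATEGORICAL_VARIABLES,
    NUMERIC_VARIABLES,
    TIME_VARIABLE_COLUMNS,
)
from .timecodes import (
    ClockTriplet,
    SentinelClass,
    classify_triplet,
    is_missing,
    triplet_delta_seconds,
)

CORRECT, WRONG, MISSING = 1, 2, 3


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing one cell of the two databases."""

    variable: str
    episode_id: str
    shkn: int
    code: int  # 1 correct / 2 wrong / 3 missing
    deviation: Optional[float] = None
    manual_class: Optional[SentinelClass] = None
    derived_class: Optional[SentinelClass] = None


def compare_time(
    manual: ClockTriplet,
    derived: ClockTriplet,
    tolerance: float = 1.0,
    manual_literal_flagged: bool = False,
    derived_literal_flagged: bool = False,
    variable: str = "",
    episode_id: str = "",
    shkn: int = 0,
) -> ComparisonResult:
    """Compare two time triplets under the missing-code taxonomy."""
    m_cls = classify_triplet(manual, manual_literal_flagged)
    d_cls = classify_triplet(derived, derived_literal_flagged)
    if is_missing(m_cls) or is_missing(d_cls):
        return ComparisonResult(
            variable, episode_id, shkn, MISSING, None, m_cls, d_cls
        )
    delta = triplet_delta_seconds(manual, derived)
    code = CORRECT if delta <= tolerance else WRONG
    return ComparisonResult(
        variable, episode_id, shkn, code, float(delta), m_cls, d_cls
    )


def compare_categorical(
    manual: int,
    derived: int,
    variable: str = "",
    episode_id: str = "",
    shkn: int = 0,
) -> ComparisonResult:
    """Identity comparison for coded categoricals and device readings."""
    deviation = float(derived - manual)
    code = CORRECT if manual == derived else WRONG
    return ComparisonResult(variable, episode_id, shkn, code, deviation)


def _row_triplet(row: pd.Series, var: str) -> ClockTriplet:
    hr, mn, sc = TIME_VARIABLE_COLUMNS[var]
    return ClockTriplet(int(row[hr]), int(row[mn]), int(row[sc]))


def compare_databases(
    manual: pd.DataFrame,
    derived: pd.DataFrame,
    tolerance: float = 1.0,
    manual_literals_flagged: bool = True,
) -> list[ComparisonResult]:
    """Compare two databases cell by cell, aligned on (episode_id, shkn).

    ``manual_literals_flagged`` states that the manual source marks blanked
    ``00:00:00`` / ``12:00:00`` entries, so those are coded missing on the
    manual side. Misaligned keys raise :class:`AlignmentError` rather than
    silently comparing the wrong shocks.
    """
    m_keys = list(zip(manual["episode_id"], manual["shkn"]))
    d_keys = list(zip(derived["episode_id"], derived["shkn"]))
    if len(set(m_keys)) != len(m_keys) or len(set(d_keys)) != len(d_keys):
        raise AlignmentError("duplicate (episode_id, shkn) keys")
    if set(m_keys) != set(d_keys):
        only_m = sorted(set(m_keys) - set(d_keys))[:5]
        only_d = sorted(set(d_keys) - set(m_keys))[:5]
        raise AlignmentError(
            f"databases do not align: manual-only {only_m}, derived-only {only_d}"
        )
    m = manual.set_index(["episode_id", "shkn"]).sort_index()
    d = derived.set_index(["episode_id", "shkn"]).sort_index()
    results: list[ComparisonResult] = []
    for key in m.index:
        mrow, drow = m.loc[key], d.loc[key]
        eid, shkn = key
        for var in TIME_VARIABLE_COLUMNS:
            results.append(
                compare_time(
                    _row_triplet(mrow, var),
                    _row_triplet(drow, var),
                    tolerance=tolerance,
                    manual_literal_flagged=manual_literals_flagged,
                    variable=var,
                    episode_id=eid,
                    shkn=int(shkn),
                )
            )
        for var in CATEGORICAL_VARIABLES + NUMERIC_VARIABLES:
            results.append(
                compare_categorical(
                    int(mrow[var]), int(drow[var]), var, eid, int(shkn)
                )
            )
    return results


def summarize(results: Iterable[ComparisonResult]) -> pd.DataFrame:
    """Per-variable counts and rates.

    Columns: correct, wrong, missing, match_rate_pct (correct over
    correct+wrong, NaN when nothing was comparable) and
    missing_agreement_pct (share of missing cells where both sides carry
    the same missing code, NaN when nothing is missing).
    """
    order: list[str] = []
    acc: dict[str, dict[str, int]] = {}
    for r in results:
        if r.variable not in acc:
            acc[r.variable] = {
                "correct": 0,
                "wrong": 0,
                "missing": 0,
                "missing_matched": 0,
            }
            order.append(r.variable)
        slot = acc[r.variable]
        if r.code == CORRECT:
            slot["correct"] += 1
        elif r.code == WRONG:
            slot["wrong"] += 1
        else:
            slot["missing"] += 1
            if (
                r.manual_class is not None
                and r.manual_class is r.derived_class
            ):
                slot["missing_matched"] += 1
    rows = []
    for var in order:
        s = acc[var]
        comparable = s["correct"] + s["wrong"]
        rows.append(
            {
                "variable": var,
                "correct": s["correct"],
                "wrong": s["wrong"],
                "missing": s["missing"],
                "match_rate_pct": (
                    100.0 * s["correct"] / comparable if comparable else float("nan")
                ),
                "missing_agreement_pct": (
                    100.0 * s["missing_matched"] / s["missing"]
                    if s["missing"]
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "correct",
            "wrong",
            "missing",
            "match_rate_pct",
            "missing_agreement_pct",
        ],
    )
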