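"""The automated review engine.

For each delivered shock the episode is segmented into a pre-shock window
(back to the previous shock, or the beginning of episode) and a post-shock
window (forward to the next shock, or the end of episode). Every registry
review variable is then derived from the state-sequence representation by
rule-based reasoning:

* time variables — ECG start, shock time, first/last compression before
  the shock, VF-onset and ROSC times after it, emitted as hour/minute/
  second triplets with sentinel codes where undefined;
* patient-response variables — initial and pre-shock rhythms, the rhythm
  at fixed checkpoints after the shock (10/30/60/120 s, read within a
  ±5 s discretion window), and whether VF, an organized rhythm or ROSC
  occurred before the next shock;
* device variables — shock ordinal and counts, stacked-shock run size,
  device mode, CPR-before-shock, delivered energy and impedance.

Derivation is a pure function of (episode, config): identical inputs give
identical rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .algebra import find_label, restrict, state_at
from .core import DomainSequence, Episode, StateInterval
from .errors import RoreviewError
from .episode_io import (
    CATEGORICAL_VARIABLES,
    DB_COLUMNS,
    NUMERIC_VARIABLES,
    TIME_VARIABLE_COLUMNS,
)
from .timecodes import (
    ClockTriplet,
    NO_CPR_88,
    NO_DATA_66,
    UNKNOWN_99,
    elapsed_to_absolute,
)

#: registry rhythm codes: asystole 1, VF 2, VT 3, organized 4, unknown 9.
#: PE and PR share the organized code; PR is distinguished only in the
#: ROSC variables.
RHYTHM_CODE = {"AS": 1, "VF": 2, "VT": 3, "PE": 4, "PR": 4, "UN": 9}
CODE_YES, CODE_NO, CODE_UNKNOWN = 1, 2, 9
MODE_MANUAL, MODE_ADVISORY = 1, 2
IMP_ENRGY_UNKNOWN = 999


@dataclass(frozen=True)
class ReviewConfig:
    """Tunable parameters of the review rules.

    ``shock_end_offset_s`` is added to the shock time before the rhythm
    checkpoints are measured: 0 s treats the checkpoints as offsets from
    shock delivery (the convention of the worked examples); 3 s treats the
    end of shock as three seconds after delivery. ``window_halfwidth_s``
    is the ±discretion window around each checkpoint. ``time_tolerance_s``
    is the audit tolerance for time variables.
    """

    shock_end_offset_s: float = 0.0
    checkpoint_offsets_s: Tuple[float, ...] = (10.0, 30.0, 60.0, 120.0)
    window_halfwidth_s: float = 5.0
    time_tolerance_s: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "ReviewConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise RoreviewError(f"unknown config keys: {sorted(bad)}")
        if "checkpoint_offsets_s" in d:
            d = dict(d, checkpoint_offsets_s=tuple(d["checkpoint_offsets_s"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ReviewConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class ShockContext:
    """One shock with its pre- and post-shock windows.

    Windows tile the episode: ``[pre_start, shock_time)`` reaches back to
    the previous shock (or the beginning of episode for the first shock),
    ``[shock_time, post_end)`` forward to the next shock (or the end of
    episode). ``is_first`` / ``is_last`` mark where the BOE/EOE markers
    stand in for neighbouring shocks.
    """

    shock_index: int  # 1-based
    shock_time: float
    pre_start: float
    post_end: float
    is_first: bool
    is_last: bool
    pre_therapy: DomainSequence
    post_therapy: DomainSequence
    pre_response: DomainSequence
    post_response: DomainSequence

    @property
    def pre_window(self) -> Tuple[float, float]:
        return (self.pre_start, self.shock_time)

    @property
    def post_window(self) -> Tuple[float, float]:
        return (self.shock_time, self.post_end)


def segment_shocks(episode: Episode) -> list[ShockContext]:
    """Split the episode into per-shock contexts (empty list if no shocks)."""
    times = [s.time for s in episode.shocks]
    if not times:
        return []
    boe, eoe = episode.span_start, episode.span_end
    contexts = []
    for k, t in enumerate(times):
        pre_start = times[k - 1] if k > 0 else boe
        post_end = times[k + 1] if k + 1 < len(times) else eoe
        contexts.append(
            ShockContext(
                shock_index=k + 1,
                shock_time=t,
                pre_start=pre_start,
                post_end=post_end,
                is_first=(k == 0),
                is_last=(k + 1 == len(times)),
                pre_therapy=restrict(episode.therapy, pre_start, t),
                post_therapy=restrict(episode.therapy, t, post_end),
                pre_response=(
                    DomainSequence.empty("response")
                    if episode.response.is_empty
                    else restrict(episode.response, pre_start, t)
                ),
                post_response=(
                    DomainSequence.empty("response")
                    if episode.response.is_empty
                    else restrict(episode.response, t, post_end)
                ),
            )
        )
    return contexts


# -- rhythm checkpoint rule ----------------------------------------------


def _state_just_before(seq: DomainSequence, t: float) -> Optional[str]:
    """Label of the interval with start < t <= end (state at t-epsilon)."""
    if seq.is_empty or t <= seq.span_start or t > seq.span_end:
        return None
    for iv in reversed(seq.intervals):
        if iv.start < t <= iv.end:
            return iv.label
    return None


def _vf_transition_in(
    response: DomainSequence, lo: float, hi: float
) -> Optional[float]:
    """Earliest transition into VF with start time in [lo, hi], else None."""
    for iv in response.intervals:
        if iv.label == "VF" and lo <= iv.start <= hi:
            return iv.start
    return None


def checkpoint_rhythm_code(
    response: DomainSequence,
    shock_time: float,
    post_end: float,
    q: float,
    halfwidth: float,
) -> int:
    """Registry code of the rhythm at checkpoint time ``q``.

    The rhythm is read from the post-shock restriction of the response
    domain with two discretion rules applied within ±``halfwidth`` of
    ``q``: a transition into VF inside the window overrides the reading to
    VF, and an unknown state at ``q`` falls back to the last known rhythm
    provided it was still present inside the window. A checkpoint beyond
    the recorded domain (recording ended, or next shock reached) reads
    unknown.
    """
    window = restrict(response, shock_time, post_end) if not response.is_empty else response
    if window.is_empty or q < window.span_start or q >= window.span_end:
        return CODE_UNKNOWN
    vf_at = _vf_transition_in(
        response, max(q - halfwidth, shock_time), min(q + halfwidth, post_end)
    )
    if vf_at is not None:
        return RHYTHM_CODE["VF"]
    lab = state_at(window, q)
    if lab != "UN":
        return RHYTHM_CODE[lab]
    # fall back to the last known rhythm if still present within the window
    for iv in reversed(window.intervals):
        if iv.end <= q and iv.label != "UN":
            if iv.end >= q - halfwidth:
                return RHYTHM_CODE[iv.label]
            break
    return CODE_UNKNOWN


# -- time variables ------------------------------------------------------


@dataclass(frozen=True)
class TimeVariables:
    """Derived absolute times for one shock, with their elapsed origins."""

    ecgtm: ClockTriplet
    shktm: ClockTriplet
    fctm: ClockTriplet
    lctm: ClockTriplet
    vfonsettm: ClockTriplet
    rsctm: ClockTriplet
    fc_elapsed: Optional[float] = None
    lc_elapsed: Optional[float] = None
    vfonset_elapsed: Optional[float] = None
    rsc_elapsed: Optional[float] = None
    fc_ongoing_at_start: bool = False

    def as_columns(self) -> Dict[str, int]:
        out = {}
        for var, trip in (
            ("ecgtm", self.ecgtm),
            ("shktm", self.shktm),
            ("fctm", self.fctm),
            ("lctm", self.lctm),
            ("vfonsettm", self.vfonsettm),
            ("rsctm", self.rsctm),
        ):
            hr_col, mn_col, sc_col = TIME_VARIABLE_COLUMNS[var]
            out[hr_col], out[mn_col], out[sc_col] = trip.hr, trip.mn, trip.sc
        return out


def derive_time_variables(
    ctx: ShockContext, episode: Episode, config: ReviewConfig = ReviewConfig()
) -> TimeVariables:
    """Derive the six registry time variables for one shock.

    First compression is the start of the first ``C`` in the pre-shock
    window (``88:88:88`` when no CPR was given); last compression is the
    end of the last ``C`` — the start of the final hands-off interval
    before the shock. VF onset is the first transition into VF after the
    shock, with the persistent-VF rule: when the pre-shock rhythm and the
    10/30/60 s checkpoint rhythms are all VF the onset is coded
    ``99:99:99`` (no onset — the patient remained in VF). ROSC time is
    the first transition into a pulse-giving rhythm after the shock.
    """
    power_on = episode.power_on

    fc = find_label(ctx.pre_therapy, "C", "first")
    lc = find_label(ctx.pre_therapy, "C", "last")
    fc_elapsed = fc.start if fc else None
    lc_elapsed = lc.end if lc else None
    ongoing = fc is not None and ctx.is_first and abs(fc.start - episode.span_start) < 1e-9

    if ctx.post_response.is_empty:
        vfonsettm, rsctm = NO_DATA_66, NO_DATA_66
        vf_elapsed = rsc_elapsed = None
    else:
        rhyb4 = _preshock_rhythm_code(episode.response, ctx.shock_time)
        checks = [
            checkpoint_rhythm_code(
                episode.response,
                ctx.shock_time,
                ctx.post_end,
                ctx.shock_time + config.shock_end_offset_s + d,
                config.window_halfwidth_s,
            )
            for d in (10.0, 30.0, 60.0)
        ]
        persistent_vf = rhyb4 == RHYTHM_CODE["VF"] and all(
            c == RHYTHM_CODE["VF"] for c in checks
        )
        vf_elapsed = None
        if not persistent_vf:
            vf_elapsed = _vf_transition_in(
                episode.response, ctx.shock_time, ctx.post_end
            )
            if vf_elapsed is not None and vf_elapsed >= ctx.post_end:
                vf_elapsed = None
        rsc_elapsed = None
        for iv in episode.response.intervals:
            if iv.label == "PR" and ctx.shock_time <= iv.start < ctx.post_end:
                rsc_elapsed = iv.start
                break
        vfonsettm = (
            elapsed_to_absolute(vf_elapsed, power_on)
            if vf_elapsed is not None
            else UNKNOWN_99
        )
        rsctm = (
            elapsed_to_absolute(rsc_elapsed, power_on)
            if rsc_elapsed is not None
            else UNKNOWN_99
        )

    return TimeVariables(
        ecgtm=elapsed_to_absolute(0.0, power_on),
        shktm=elapsed_to_absolute(ctx.shock_time, power_on),
        fctm=elapsed_to_absolute(fc_elapsed, power_on) if fc else NO_CPR_88,
        lctm=elapsed_to_absolute(lc_elapsed, power_on) if lc else NO_CPR_88,
        vfonsettm=vfonsettm,
        rsctm=rsctm,
        fc_elapsed=fc_elapsed,
        lc_elapsed=lc_elapsed,
        vfonset_elapsed=vf_elapsed if not ctx.post_response.is_empty else None,
        rsc_elapsed=rsc_elapsed if not ctx.post_response.is_empty else None,
        fc_ongoing_at_start=ongoing,
    )


def _preshock_rhythm_code(response: DomainSequence, shock_time: float) -> int:
    lab = _state_just_before(response, shock_time)
    return CODE_UNKNOWN if lab is None else RHYTHM_CODE[lab]


# -- response variables --------------------------------------------------


@dataclass(frozen=True)
class ResponseVariables:
    init_rhy: int
    rhyb4: int
    r10: int
    r30: int
    r60: int
    r120: int
    vfpr: int
    orgpr: int
    rosc: int

    def as_columns(self) -> Dict[str, int]:
        return {
            "init_rhy": self.init_rhy,
            "rhyb4": self.rhyb4,
            "r10": self.r10,
            "r30": self.r30,
            "r60": self.r60,
            "r120": self.r120,
            "vfpr": self.vfpr,
            "orgpr": self.orgpr,
            "rosc": self.rosc,
        }


def _presence_code(
    response: DomainSequence,
    shock_time: float,
    post_end: float,
    labels: Sequence[str],
) -> int:
    """Yes/no/unknown for 'did any of ``labels`` occur before the next shock'.

    Yes when such an interval intersects the window strictly after the
    shock. No only when the whole window is covered by known (non-UN)
    rhythm; otherwise the answer is unknowable and coded 9.
    """
    if response.is_empty:
        return CODE_UNKNOWN
    for iv in response.intervals:
        if iv.label in labels and iv.end > shock_time and iv.start < post_end:
            return CODE_YES
    window = restrict(response, shock_time, post_end)
    if window.is_empty:
        return CODE_UNKNOWN
    fully_known = (
        abs(window.span_start - shock_time) < 1e-9
        and abs(window.span_end - post_end) < 1e-9
        and all(iv.label != "UN" for iv in window.intervals)
    )
    return CODE_NO if fully_known else CODE_UNKNOWN


def derive_response_variables(
    ctx: ShockContext, episode: Episode, config: ReviewConfig = ReviewConfig()
) -> ResponseVariables:
    """Derive the nine patient-response codes for one shock."""
    response = episode.response
    if response.is_empty:
        u = CODE_UNKNOWN
        return ResponseVariables(u, u, u, u, u, u, u, u, u)
    init_rhy = RHYTHM_CODE[response.intervals[0].label]
    rhyb4 = _preshock_rhythm_code(response, ctx.shock_time)
    checks = {}
    for d in config.checkpoint_offsets_s:
        q = ctx.shock_time + config.shock_end_offset_s + d
        checks[d] = checkpoint_rhythm_code(
            response, ctx.shock_time, ctx.post_end, q, config.window_halfwidth_s
        )
    vfpr = _presence_code(response, ctx.shock_time, ctx.post_end, ("VF",))
    orgpr = _presence_code(response, ctx.shock_time, ctx.post_end, ("PE", "PR"))
    # ROSC: yes iff a pulse-giving rhythm appears in the post window;
    # unknown only when the response domain is undefined over the window
    if ctx.post_response.is_empty:
        rosc = CODE_UNKNOWN
    else:
        rosc = CODE_NO
        for iv in response.intervals:
            if iv.label == "PR" and iv.end > ctx.shock_time and iv.start < ctx.post_end:
                rosc = CODE_YES
                break
    return ResponseVariables(
        init_rhy=init_rhy,
        rhyb4=rhyb4,
        r10=checks.get(10.0, CODE_UNKNOWN),
        r30=checks.get(30.0, CODE_UNKNOWN),
        r60=checks.get(60.0, CODE_UNKNOWN),
        r120=checks.get(120.0, CODE_UNKNOWN),
        vfpr=vfpr,
        orgpr=orgpr,
        rosc=rosc,
    )


# -- device variables ----------------------------------------------------


@dataclass(frozen=True)
class DeviceVariables:
    shkn: int
    ssrecord: int
    shks: int
    mode: int
    cpr: int
    imp: int
    enrgy: int

    def as_columns(self) -> Dict[str, int]:
        return {
            "shkn": self.shkn,
            "ssrecord": self.ssrecord,
            "shks": self.shks,
            "mode": self.mode,
            "cpr": self.cpr,
            "imp": self.imp,
            "enrgy": self.enrgy,
        }


def stacked_run_sizes(episode: Episode) -> list[int]:
    """Size of the stacked-shock run each shock belongs to.

    Two consecutive shocks are stacked when no compression interval lies
    between them; a run is a maximal chain of stacked shocks, and every
    shock in a run of size n reports n (1 = no stacked shocks).
    """
    times = [s.time for s in episode.shocks]
    if not times:
        return []
    c_intervals = [iv for iv in episode.therapy.intervals if iv.label == "C"]

    def compressions_between(a: float, b: float) -> bool:
        return any(iv.start < b and iv.end > a for iv in c_intervals)

    runs: list[list[int]] = [[0]]
    for k in range(1, len(times)):
        if compressions_between(times[k - 1], times[k]):
            runs.append([k])
        else:
            runs[-1].append(k)
    sizes = [0] * len(times)
    for run in runs:
        for k in run:
            sizes[k] = len(run)
    return sizes


def derive_device_variables(
    ctx: ShockContext,
    episode: Episode,
    config: ReviewConfig = ReviewConfig(),
    manual_fc_lc_unknown: bool = False,
) -> DeviceVariables:
    """Derive the device-operation and therapy codes for one shock.

    ``manual_fc_lc_unknown`` reflects the reconciliation convention for a
    manual source whose first- and last-compression times are both coded
    unknown: that situation is interpreted as CPR being present.
    """
    record = episode.shocks[ctx.shock_index - 1]
    mode = MODE_ADVISORY
    for sw in episode.mode_switches:
        if sw.time < ctx.shock_time:
            mode = MODE_MANUAL if sw.mode == "manual" else MODE_ADVISORY
    if manual_fc_lc_unknown:
        cpr = CODE_YES
    else:
        cpr = (
            CODE_YES
            if find_label(ctx.pre_therapy, "C", "first") is not None
            else CODE_NO
        )
    return DeviceVariables(
        shkn=ctx.shock_index,
        ssrecord=len(episode.shocks),
        shks=stacked_run_sizes(episode)[ctx.shock_index - 1],
        mode=mode,
        cpr=cpr,
        imp=(
            int(round(record.impedance_ohm))
            if record.impedance_ohm is not None
            else IMP_ENRGY_UNKNOWN
        ),
        enrgy=(
            int(round(record.energy_j))
            if record.energy_j is not None
            else IMP_ENRGY_UNKNOWN
        ),
    )


# -- full pipeline -------------------------------------------------------


def derive_database(
    episode: Episode, config: ReviewConfig = ReviewConfig()
) -> pd.DataFrame:
    """Derive the complete review database (one row per shock)."""
    rows = []
    for ctx in segment_shocks(episode):
        row: Dict[str, object] = {
            "episode_id": episode.episode_id,
            "shkn": ctx.shock_index,
        }
        row.update(derive_time_variables(ctx, episode, config).as_columns())
        row.update(derive_response_variables(ctx, episode, config).as_columns())
        row.update(derive_device_variables(ctx, episode, config).as_columns())
        rows.append(row)
    return pd.DataFrame(rows, columns=DB_COLUMNS)
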