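"""Seeded generator of synthetic resuscitation episodes with ground truth.

No public registry of annotated resuscitation episodes exists, so this
module emulates one: each synthetic episode carries a device event log
(power-on, shocks with energy and impedance, mode switches), rhythm and
compression annotations, and the *true* review-database row for every
shock. Episodes interleave compression sequences with hands-off
intervals, place shocks (optionally stacked) inside hands-off intervals,
and draw the rhythm timeline from a semi-Markov chain over
VF/VT/AS/PE/PR/UN with exponential dwell times; a shock may trigger an
extra rhythm transition shortly after delivery.

Ground truth is computed analytically from the generated raw timeline by
plain scans over the segment lists — an independent code path from the
review engine, so recovery tests are a genuine oracle check, not a
self-comparison. All times are quantized to the 0.1 s grid; every episode
is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Episode, Event, ModeSwitch, ShockRecord
from .episode_io import (
    DB_COLUMNS,
    DeviceLog,
    KIND_MODE_AED,
    KIND_MODE_MONITOR,
    KIND_POWER_ON,
    KIND_SHOCK,
    KIND_STOP,
    LogEntry,
    TIME_VARIABLE_COLUMNS,
    assemble_episode,
    write_annotations,
    write_database,
    write_event_log,
)
from .errors import ParameterError

_RHYTHMS = ("VF", "VT", "AS", "PE", "PR", "UN")


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic episodes.

    Defaults emulate out-of-hospital VF arrest as seen in AED downloads:
    episodes of 10–30 minutes, compressions in ~1 minute sequences broken
    by short hands-off intervals, 1–5 shocks of 150–360 J delivered during
    hands-off periods, and rhythm dwell times of one to a few minutes.
    """

    duration_range_s: Tuple[float, float] = (600.0, 1800.0)
    rhythm_start_delay_range_s: Tuple[float, float] = (20.0, 60.0)
    first_compression_delay_range_s: Tuple[float, float] = (30.0, 90.0)
    compression_mean_s: float = 60.0
    compression_min_s: float = 10.0
    handsoff_mean_s: float = 12.0
    handsoff_min_s: float = 4.0
    shock_count_range: Tuple[int, int] = (1, 5)
    stacked_shock_prob: float = 0.15
    shock_duration_s: float = 5.0
    shock_margin_s: float = 1.0
    post_shock_transition_prob: float = 0.6
    post_shock_delay_range_s: Tuple[float, float] = (2.0, 8.0)
    rhythm_dwell_mean_s: Dict[str, float] = field(
        default_factory=lambda: {
            "VF": 120.0,
            "VT": 60.0,
            "AS": 90.0,
            "PE": 80.0,
            "PR": 150.0,
            "UN": 40.0,
        }
    )
    rhythm_dwell_min_s: float = 6.0
    initial_rhythm_probs: Dict[str, float] = field(
        default_factory=lambda: {"VF": 0.7, "AS": 0.15, "PE": 0.1, "VT": 0.05}
    )
    unknown_rhythm_prob: float = 0.05
    energy_choices_j: Tuple[int, ...] = (150, 200, 360)
    impedance_range_ohm: Tuple[int, int] = (50, 120)
    manual_mode_prob: float = 0.2
    power_on_year: int = 2011
    force_persistent_vf: bool = False


@dataclass(frozen=True)
class SyntheticEpisode:
    """One generated episode: raw timeline, file dialect views, and truth."""

    episode_id: str
    duration_s: float
    power_on: datetime
    rhythm_segments: Tuple[Tuple[float, float, str], ...]
    c_intervals: Tuple[Tuple[float, float], ...]
    d_intervals: Tuple[Tuple[float, float], ...]
    shocks: Tuple[ShockRecord, ...]
    mode_switches: Tuple[ModeSwitch, ...]
    log: DeviceLog
    annotations: Tuple[Event, ...]
    truth: pd.DataFrame

    def episode(self) -> Episode:
        """Assemble the full model object the review engine consumes."""
        return assemble_episode(self.log, self.annotations, self.episode_id)

    def write_bundle(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_event_log(self.log, d / f"{self.episode_id}_log.jsonl")
        write_annotations(self.annotations, d / f"{self.episode_id}_annotations.csv")
        write_database(self.truth, d / f"{self.episode_id}_truth.csv")


def _q(x: float) -> float:
    return round(float(x), 1)


def _draw_rhythm_timeline(
    rng: np.random.Generator, p: SimParams, duration: float
) -> List[Tuple[float, float, str]]:
    start = _q(rng.uniform(*p.rhythm_start_delay_range_s))
    if p.force_persistent_vf:
        return [(start, duration, "VF")]
    states = list(p.initial_rhythm_probs)
    probs = np.array([p.initial_rhythm_probs[s] for s in states])
    state = rng.choice(states, p=probs / probs.sum())
    segments: List[Tuple[float, float, str]] = []
    t = start
    while t < duration:
        dwell = max(
            p.rhythm_dwell_min_s, rng.exponential(p.rhythm_dwell_mean_s[state])
        )
        end = min(_q(t + dwell), duration)
        if end <= t:
            break
        segments.append((t, end, state))
        t = end
        if rng.uniform() < p.unknown_rhythm_prob:
            nxt = "UN"
        else:
            choices = [s for s in _RHYTHMS if s not in (state, "UN")]
            nxt = rng.choice(choices)
        state = nxt
    return segments


def _draw_compressions(
    rng: np.random.Generator, p: SimParams, duration: float
) -> List[Tuple[float, float]]:
    t = _q(rng.uniform(*p.first_compression_delay_range_s))
    out = []
    while t < duration - p.compression_min_s:
        length = max(p.compression_min_s, rng.exponential(p.compression_mean_s))
        end = min(_q(t + length), duration)
        if end - t >= p.compression_min_s:
            out.append((t, end))
        gap = max(p.handsoff_min_s, rng.exponential(p.handsoff_mean_s))
        t = _q(end + gap)
    return out


def _place_shocks(
    rng: np.random.Generator,
    p: SimParams,
    duration: float,
    c_intervals: Sequence[Tuple[float, float]],
) -> List[Tuple[float, float]]:
    """Carve defibrillation intervals out of hands-off gaps."""
    lo, hi = p.shock_count_range
    want = int(rng.integers(lo, hi + 1))
    gaps = []
    edges = [0.0] + [t for c in c_intervals for t in c] + [duration]
    for a, b in zip(edges[::2], edges[1::2]):
        gaps.append((a, b))
    need = p.shock_duration_s + 2 * p.shock_margin_s
    feasible = [g for g in gaps if g[1] - g[0] >= need]
    if len(feasible) < lo:
        raise ParameterError(
            f"only {len(feasible)} hands-off gaps can host a shock; "
            f"at least {lo} requested"
        )
    d_intervals: List[Tuple[float, float]] = []
    order = rng.permutation(len(feasible))
    for gi in order:
        if len(d_intervals) >= want:
            break
        a, b = feasible[gi]
        stacked = (
            rng.uniform() < p.stacked_shock_prob
            and len(d_intervals) + 2 <= want
            and (b - a) >= 2 * p.shock_duration_s + 3 * p.shock_margin_s
        )
        n_here = 2 if stacked else 1
        total = n_here * p.shock_duration_s + (n_here + 1) * p.shock_margin_s
        slack = (b - a) - total
        offset = _q(a + p.shock_margin_s + rng.uniform(0, slack))
        t = offset
        for _ in range(n_here):
            d_intervals.append((t, _q(t + p.shock_duration_s)))
            t = _q(t + p.shock_duration_s + p.shock_margin_s)
    d_intervals.sort()
    return d_intervals


def _insert_transition(
    segments: List[Tuple[float, float, str]], tau: float, new_state: str
) -> List[Tuple[float, float, str]]:
    out: List[Tuple[float, float, str]] = []
    for s, e, lab in segments:
        if s <= tau < e and lab != new_state:
            if tau > s:
                out.append((s, tau, lab))
            out.append((tau, e, new_state))
        else:
            out.append((s, e, lab))
    merged: List[Tuple[float, float, str]] = []
    for s, e, lab in out:
        if merged and merged[-1][2] == lab and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged


# -- analytic ground truth (independent of the review engine) ------------


def _truth_checkpoint_code(
    segments: Sequence[Tuple[float, float, str]],
    shock_time: float,
    post_end: float,
    q: float,
    halfwidth: float,
) -> int:
    from .reasoning import CODE_UNKNOWN, RHYTHM_CODE  # constants only

    if not segments:
        return CODE_UNKNOWN
    lo_w = max(shock_time, segments[0][0])
    hi_w = min(post_end, segments[-1][1])
    if lo_w >= hi_w or q < lo_w or q >= hi_w:
        return CODE_UNKNOWN
    lo = max(q - halfwidth, shock_time)
    hi = min(q + halfwidth, post_end)
    for s, _e, lab in segments:
        if lab == "VF" and lo <= s <= hi:
            return RHYTHM_CODE["VF"]
    clipped = [
        (max(s, lo_w), min(e, hi_w), lab)
        for s, e, lab in segments
        if min(e, hi_w) - max(s, lo_w) > 1e-9
    ]
    at_q = None
    for s, e, lab in clipped:
        if s <= q < e:
            at_q = lab
            break
    if at_q is None:
        return CODE_UNKNOWN
    if at_q != "UN":
        return RHYTHM_CODE[at_q]
    for s, e, lab in reversed(clipped):
        if e <= q and lab != "UN":
            if e >= q - halfwidth:
                return RHYTHM_CODE[lab]
            break
    return CODE_UNKNOWN


def _truth_triplet(elapsed: Optional[float], power_on: datetime) -> Tuple[int, int, int]:
    if elapsed is None:
        return (99, 99, 99)
    base = power_on.hour * 3600 + power_on.minute * 60 + power_on.second
    total = (base + int(elapsed + 0.5)) % 86400
    return (total // 3600, (total % 3600) // 60, total % 60)


def _compute_truth(
    episode_id: str,
    power_on: datetime,
    duration: float,
    segments: Sequence[Tuple[float, float, str]],
    c_intervals: Sequence[Tuple[float, float]],
    shocks: Sequence[ShockRecord],
    mode_switches: Sequence[ModeSwitch],
    shock_end_offset_s: float = 0.0,
    halfwidth: float = 5.0,
) -> pd.DataFrame:
    from .reasoning import (  # shared code tables, not shared logic
        CODE_NO,
        CODE_UNKNOWN,
        CODE_YES,
        MODE_ADVISORY,
        MODE_MANUAL,
        RHYTHM_CODE,
    )

    times = [s.time for s in shocks]
    # stacked runs: consecutive shocks with no compressions between them
    run_sizes = [1] * len(times)
    if times:
        runs = [[0]]
        for k in range(1, len(times)):
            between = any(
                cs < times[k] and ce > times[k - 1] for cs, ce in c_intervals
            )
            if between:
                runs.append([k])
            else:
                runs[-1].append(k)
        for run in runs:
            for k in run:
                run_sizes[k] = len(run)

    resp_start = segments[0][0] if segments else None
    resp_end = segments[-1][1] if segments else None
    rows = []
    for k, t in enumerate(times):
        pre_start = times[k - 1] if k > 0 else 0.0
        post_end = times[k + 1] if k + 1 < len(times) else duration

        fc = min((cs for cs, ce in c_intervals if pre_start <= cs < t), default=None)
        lc = max(
            (ce for cs, ce in c_intervals if pre_start < ce <= t), default=None
        )
        cpr = (
            CODE_YES
            if any(cs < t and ce > pre_start for cs, ce in c_intervals)
            else CODE_NO
        )

        window_defined = (
            segments
            and max(t, resp_start) < min(post_end, resp_end)
        )
        if not window_defined:
            rhyb4 = CODE_UNKNOWN
            checks = {d: CODE_UNKNOWN for d in (10.0, 30.0, 60.0, 120.0)}
            vfonset = rsc = None
            vf_trip = rsc_trip = (66, 66, 66)
            vfpr = orgpr = rosc = CODE_UNKNOWN
        else:
            rhyb4 = CODE_UNKNOWN
            for s, e, lab in segments:
                if s < t <= e:
                    rhyb4 = RHYTHM_CODE[lab]
                    break
            checks = {
                d: _truth_checkpoint_code(
                    segments, t, post_end, t + shock_end_offset_s + d, halfwidth
                )
                for d in (10.0, 30.0, 60.0, 120.0)
            }
            persistent = rhyb4 == RHYTHM_CODE["VF"] and all(
                checks[d] == RHYTHM_CODE["VF"] for d in (10.0, 30.0, 60.0)
            )
            vfonset = None
            if not persistent:
                vfonset = min(
                    (s for s, e, lab in segments if lab == "VF" and t <= s < post_end),
                    default=None,
                )
            rsc = min(
                (s for s, e, lab in segments if lab == "PR" and t <= s < post_end),
                default=None,
            )
            vf_trip = _truth_triplet(vfonset, power_on)
            rsc_trip = _truth_triplet(rsc, power_on)

            def presence(labels) -> int:
                if any(
                    lab in labels and e > t and s < post_end
                    for s, e, lab in segments
                ):
                    return CODE_YES
                covered = resp_start <= t and resp_end >= post_end
                un_inside = any(
                    lab == "UN" and e > t and s < post_end
                    for s, e, lab in segments
                )
                return CODE_NO if covered and not un_inside else CODE_UNKNOWN

            vfpr = presence(("VF",))
            orgpr = presence(("PE", "PR"))
            rosc = (
                CODE_YES
                if any(
                    lab == "PR" and e > t and s < post_end
                    for s, e, lab in segments
                )
                else CODE_NO
            )

        mode = MODE_ADVISORY
        for sw in mode_switches:
            if sw.time < t:
                mode = MODE_MANUAL if sw.mode == "manual" else MODE_ADVISORY

        row: Dict[str, object] = {"episode_id": episode_id, "shkn": k + 1}
        trips = {
            "ecgtm": _truth_triplet(0.0, power_on),
            "shktm": _truth_triplet(t, power_on),
            "fctm": _truth_triplet(fc, power_on) if fc is not None else (88, 88, 88),
            "lctm": _truth_triplet(lc, power_on) if lc is not None else (88, 88, 88),
            "vfonsettm": vf_trip,
            "rsctm": rsc_trip,
        }
        for var, (h, m, s) in trips.items():
            ch, cm, cs = TIME_VARIABLE_COLUMNS[var]
            row[ch], row[cm], row[cs] = h, m, s
        row.update(
            init_rhy=RHYTHM_CODE[segments[0][2]] if segments else CODE_UNKNOWN,
            rhyb4=rhyb4,
            r10=checks[10.0],
            r30=checks[30.0],
            r60=checks[60.0],
            r120=checks[120.0],
            vfpr=vfpr,
            orgpr=orgpr,
            rosc=rosc,
            ssrecord=len(times),
            shks=run_sizes[k],
            mode=mode,
            cpr=cpr,
            imp=int(round(shocks[k].impedance_ohm)),
            enrgy=int(round(shocks[k].energy_j)),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=DB_COLUMNS)


# -- episode assembly ----------------------------------------------------


def generate_episode(
    params: SimParams = SimParams(),
    seed: int = 0,
    episode_id: Optional[str] = None,
) -> SyntheticEpisode:
    """Generate one internally consistent episode with ground truth.

    Shocks occur only inside hands-off intervals long enough to host
    them; rhythm transitions are independent of therapy except for an
    optional extra transition shortly after a shock. The returned truth
    rows are computed analytically from the raw timeline.
    """
    rng = np.random.default_rng(seed)
    episode_id = episode_id or f"sim{seed:08d}"
    duration = _q(rng.uniform(*params.duration_range_s))
    power_on = datetime(
        params.power_on_year,
        int(rng.integers(1, 13)),
        int(rng.integers(1, 29)),
        int(rng.integers(0, 24)),
        int(rng.integers(0, 60)),
        int(rng.integers(0, 60)),
    )
    segments = _draw_rhythm_timeline(rng, params, duration)
    c_intervals = _draw_compressions(rng, params, duration)
    d_intervals = _place_shocks(rng, params, duration, c_intervals)

    shocks = tuple(
        ShockRecord(
            time=s,
            energy_j=float(rng.choice(params.energy_choices_j)),
            impedance_ohm=float(
                rng.integers(
                    params.impedance_range_ohm[0], params.impedance_range_ohm[1] + 1
                )
            ),
        )
        for s, _e in d_intervals
    )

    if not params.force_persistent_vf:
        for rec in shocks:
            if rng.uniform() < params.post_shock_transition_prob:
                tau = _q(rec.time + rng.uniform(*params.post_shock_delay_range_s))
                if tau < duration - 1.0:
                    new_state = rng.choice(["AS", "PE", "PR"])
                    segments = _insert_transition(segments, tau, new_state)

    switches = []
    if rng.uniform() < params.manual_mode_prob:
        switches.append(ModeSwitch(_q(rng.uniform(0.0, duration / 2)), "manual"))
    mode_switches = tuple(switches)

    entries = [LogEntry(0, KIND_POWER_ON, timestamp=power_on)]
    for sw in mode_switches:
        kind = KIND_MODE_MONITOR if sw.mode == "manual" else KIND_MODE_AED
        entries.append(LogEntry(int(round(sw.time * 1000)), kind))
    for rec in shocks:
        entries.append(
            LogEntry(
                int(round(rec.time * 1000)),
                KIND_SHOCK,
                energy_j=rec.energy_j,
                impedance_ohm=rec.impedance_ohm,
            )
        )
    entries.append(LogEntry(int(round(duration * 1000)), KIND_STOP))
    entries.sort(key=lambda e: e.time_ms)
    # power-on header must stay first even if a switch lands at 0 ms
    entries = [e for e in entries if e.kind == KIND_POWER_ON] + [
        e for e in entries if e.kind != KIND_POWER_ON
    ]
    log = DeviceLog(power_on, shocks, mode_switches, tuple(entries))

    annotations: List[Event] = []
    for cs, ce in c_intervals:
        annotations.append(Event("c1", cs))
        annotations.append(Event("c2", ce))
    for ds, de in d_intervals:
        annotations.append(Event("d1", ds))
        annotations.append(Event("d2", de))
    for s, _e, lab in segments:
        annotations.append(Event(lab.lower(), s))
    annotations.sort(key=lambda e: e.time)

    truth = _compute_truth(
        episode_id,
        power_on,
        duration,
        segments,
        c_intervals,
        shocks,
        mode_switches,
    )
    syn = SyntheticEpisode(
        episode_id=episode_id,
        duration_s=duration,
        power_on=power_on,
        rhythm_segments=tuple(segments),
        c_intervals=tuple(c_intervals),
        d_intervals=tuple(d_intervals),
        shocks=shocks,
        mode_switches=mode_switches,
        log=log,
        annotations=tuple(annotations),
        truth=truth,
    )
    syn.episode()  # validates every core-model invariant on emission
    return syn


def generate_study(
    n_episodes: int, params: SimParams = SimParams(), seed: int = 0
) -> List[SyntheticEpisode]:
    """Generate a cohort of episodes with independent child seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(n_episodes, dtype=np.uint32)
    return [
        generate_episode(params, int(child), episode_id=f"sim{seed}_{i:03d}")
        for i, child in enumerate(children)
    ]


# -- missingness injection ----------------------------------------------

_SENTINEL_TRIPLETS = {
    "unknown_99": (99, 99, 99),
    "no_cpr_88": (88, 88, 88),
    "no_data_66": (66, 66, 66),
    "literal_00": (0, 0, 0),
    "literal_12": (12, 0, 0),
}


def corrupt(
    rows: pd.DataFrame,
    rates: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, List[Tuple[str, int, str, str]]]:
    """Inject sentinel/literal codes into time-variable cells.

    ``rates`` maps sentinel names (``unknown_99``, ``no_cpr_88``,
    ``no_data_66``, ``literal_00``, ``literal_12``) to per-cell injection
    probabilities. Returns the corrupted copy and the list of injections
    as ``(episode_id, shkn, variable, sentinel_name)`` records. Only cells
    currently holding valid times are touched, so the injected positions
    are exactly the cells that flip to a missing code.
    """
    rates = rates or {"unknown_99": 0.1, "no_cpr_88": 0.05, "no_data_66": 0.05}
    bad = set(rates) - set(_SENTINEL_TRIPLETS)
    if bad:
        raise ParameterError(f"unknown sentinel names: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    out = rows.copy()
    injected: List[Tuple[str, int, str, str]] = []
    names = list(rates)
    probs = [rates[n] for n in names]
    if sum(probs) > 1.0:
        raise ParameterError("injection rates must sum to <= 1")
    for idx in out.index:
        for var, (ch, cm, cs) in TIME_VARIABLE_COLUMNS.items():
            vals = (int(out.at[idx, ch]), int(out.at[idx, cm]), int(out.at[idx, cs]))
            if vals in set(_SENTINEL_TRIPLETS.values()):
                continue  # already a sentinel/literal; leave it alone
            u = rng.uniform()
            acc = 0.0
            for name, p in zip(names, probs):
                acc += p
                if u < acc:
                    h, m, s = _SENTINEL_TRIPLETS[name]
                    out.at[idx, ch], out.at[idx, cm], out.at[idx, cs] = h, m, s
                    injected.append(
                        (str(out.at[idx, "episode_id"]), int(out.at[idx, "shkn"]), var, name)
                    )
                    break
    return out, injected
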