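"""Readers and writers for the package's open file dialects.

The original device and registry formats (vendor binary logs, Access/Excel
exports) are proprietary; this module defines open equivalents that carry
the same information:

* **Device event log** — JSONL (one object per line) or CSV. The first
  entry must be the power-on header (``kind: "power on"``) carrying the
  wall-clock ``timestamp`` (ISO 8601, or null when unknown). Entries have
  integer ``time_ms`` since power-on; ``shock delivered`` entries carry
  ``energy_j`` and ``impedance_ohm``; ``modeSwitchMonitor`` /
  ``modeSwitchAED`` mark mode changes; an optional ``recording stopped``
  entry closes the episode. Kinds are matched case-insensitively after
  trimming; unknown kinds are logged and skipped.
* **Annotation file** — CSV with columns ``time_s,code`` where code is one
  of ``c1 c2 d1 d2 vf vt as pe pr un``.
* **Review database** — CSV with one row per shock, columns named exactly
  as the registry variables (hr/mn/sc triplets plus coded categoricals).
* **Episode rendering** — a three-block plain-text rendering of the
  therapy domain, response domain and combined episode representation,
  one ``start–end: LABEL`` line per state, times at 0.1 s; parseable back
  with an exact round trip.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import pandas as pd

from .core import (
    DomainSequence,
    Episode,
    Event,
    ModeSwitch,
    RHYTHM_EVENT_CODES,
    ShockRecord,
    StateInterval,
    THERAPY_EVENT_CODES,
    build_response_sequence,
    build_therapy_sequence,
)
from .algebra import combine
from .errors import SchemaError

logger = logging.getLogger(__name__)

Source = Union[str, Path, io.TextIOBase]

# -- device event log ----------------------------------------------------

KIND_POWER_ON = "power on"
KIND_SHOCK = "shock delivered"
KIND_MODE_MONITOR = "modeswitchmonitor"  # manual mode
KIND_MODE_AED = "modeswitchaed"  # advisory mode
KIND_STOP = "recording stopped"
_KNOWN_KINDS = {KIND_POWER_ON, KIND_SHOCK, KIND_MODE_MONITOR, KIND_MODE_AED, KIND_STOP}


@dataclass(frozen=True)
class LogEntry:
    """One device log line: a kind, milliseconds since power-on, attributes."""

    time_ms: int
    kind: str
    timestamp: Optional[datetime] = None
    energy_j: Optional[float] = None
    impedance_ohm: Optional[float] = None


@dataclass(frozen=True)
class DeviceLog:
    """Episode skeleton parsed from an event log."""

    power_on: Optional[datetime]
    shocks: Tuple[ShockRecord, ...]
    mode_switches: Tuple[ModeSwitch, ...]
    entries: Tuple[LogEntry, ...]

    @property
    def stop_time_s(self) -> Optional[float]:
        for e in self.entries:
            if e.kind == KIND_STOP:
                return e.time_ms / 1000.0
        return None


def _norm_kind(kind: str) -> str:
    return kind.strip().lower()


def _parse_timestamp(raw, lineno: int) -> Optional[datetime]:
    if raw is None or raw == "" or (isinstance(raw, str) and raw.lower() == "unknown"):
        return None
    try:
        return datetime.fromisoformat(str(raw))
    except ValueError as exc:
        raise SchemaError(f"line {lineno}: bad timestamp {raw!r}: {exc}") from exc


def _read_text(source: Source) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text(encoding="utf-8")
    return source.read()


def _log_entries_from_jsonl(text: str) -> list[LogEntry]:
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"line {lineno}: invalid JSON: {exc}") from exc
        if not isinstance(obj, dict) or "kind" not in obj or "time_ms" not in obj:
            raise SchemaError(f"line {lineno}: entry needs 'kind' and 'time_ms'")
        entries.append(
            LogEntry(
                time_ms=int(obj["time_ms"]),
                kind=_norm_kind(str(obj["kind"])),
                timestamp=_parse_timestamp(obj.get("timestamp"), lineno),
                energy_j=None if obj.get("energy_j") is None else float(obj["energy_j"]),
                impedance_ohm=(
                    None
                    if obj.get("impedance_ohm") is None
                    else float(obj["impedance_ohm"])
                ),
            )
        )
    return entries


def _log_entries_from_csv(text: str) -> list[LogEntry]:
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    required = {"time_ms", "kind"}
    if not required.issubset(df.columns):
        raise SchemaError(f"event-log CSV needs columns {sorted(required)}")
    entries = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            time_ms = int(float(row["time_ms"]))
        except ValueError as exc:
            raise SchemaError(f"line {lineno}: bad time_ms {row['time_ms']!r}") from exc
        energy = row.get("energy_j", "")
        imp = row.get("impedance_ohm", "")
        entries.append(
            LogEntry(
                time_ms=time_ms,
                kind=_norm_kind(row["kind"]),
                timestamp=_parse_timestamp(row.get("timestamp", "") or None, lineno),
                energy_j=float(energy) if energy != "" else None,
                impedance_ohm=float(imp) if imp != "" else None,
            )
        )
    return entries


def read_event_log(source: Source) -> DeviceLog:
    """Parse a device event log (JSONL or CSV, auto-detected).

    Raises :class:`SchemaError` when the power-on header is missing or a
    line violates the dialect; unknown entry kinds are skipped with a log
    message (forward compatibility).
    """
    text = _read_text(source)
    stripped = text.lstrip()
    if stripped.startswith("{"):
        entries = _log_entries_from_jsonl(text)
    else:
        entries = _log_entries_from_csv(text)
    if not entries or entries[0].kind != KIND_POWER_ON:
        raise SchemaError("event log must start with a 'power on' header entry")
    times = [e.time_ms for e in entries]
    if any(t < 0 for t in times) or times != sorted(times):
        raise SchemaError("event-log entries must have sorted, non-negative time_ms")
    power_on = entries[0].timestamp
    shocks = []
    switches = []
    for e in entries[1:]:
        if e.kind == KIND_SHOCK:
            if e.energy_j is None or e.impedance_ohm is None:
                raise SchemaError(
                    f"'shock delivered' at {e.time_ms} ms lacks energy/impedance"
                )
            shocks.append(
                ShockRecord(e.time_ms / 1000.0, e.energy_j, e.impedance_ohm)
            )
        elif e.kind == KIND_MODE_MONITOR:
            switches.append(ModeSwitch(e.time_ms / 1000.0, "manual"))
        elif e.kind == KIND_MODE_AED:
            switches.append(ModeSwitch(e.time_ms / 1000.0, "advisory"))
        elif e.kind not in _KNOWN_KINDS:
            logger.info("skipping unknown log entry kind %r", e.kind)
    return DeviceLog(power_on, tuple(shocks), tuple(switches), tuple(entries))


def write_event_log(log: DeviceLog, sink: Source) -> None:
    """Serialize a device log back to JSONL."""
    lines = []
    for e in log.entries:
        obj: dict = {"time_ms": e.time_ms, "kind": e.kind}
        if e.kind == KIND_POWER_ON:
            obj["timestamp"] = e.timestamp.isoformat() if e.timestamp else None
        if e.energy_j is not None:
            obj["energy_j"] = e.energy_j
        if e.impedance_ohm is not None:
            obj["impedance_ohm"] = e.impedance_ohm
        lines.append(json.dumps(obj))
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


# -- annotations ---------------------------------------------------------

_ALL_CODES = THERAPY_EVENT_CODES | RHYTHM_EVENT_CODES


def read_annotations(source: Source) -> Tuple[Event, ...]:
    """Read a ``time_s,code`` annotation CSV into ordered events."""
    text = _read_text(source)
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    if not {"time_s", "code"}.issubset(df.columns):
        raise SchemaError("annotation CSV needs columns time_s,code")
    events = []
    for i, row in df.iterrows():
        lineno = i + 2
        code = row["code"].strip().lower()
        if code not in _ALL_CODES:
            raise SchemaError(f"line {lineno}: unknown annotation code {row['code']!r}")
        try:
            t = float(row["time_s"])
        except ValueError as exc:
            raise SchemaError(f"line {lineno}: bad time_s {row['time_s']!r}") from exc
        events.append(Event(code, t))
    if [e.time for e in events] != sorted(e.time for e in events):
        raise SchemaError("annotation events must be sorted by time_s")
    return tuple(events)


def write_annotations(events: Sequence[Event], sink: Source) -> None:
    df = pd.DataFrame(
        {"time_s": [e.time for e in events], "code": [e.code for e in events]}
    )
    if isinstance(sink, (str, Path)):
        df.to_csv(sink, index=False)
    else:
        df.to_csv(sink, index=False)


def assemble_episode(
    log: DeviceLog,
    annotations: Sequence[Event],
    episode_id: str = "episode",
    span_end: Optional[float] = None,
) -> Episode:
    """Build a full :class:`Episode` from a device log and annotations.

    The therapy domain spans from power-on (elapsed 0) to ``span_end``,
    taken from the log's ``recording stopped`` entry when present, else
    the latest time seen in the log or annotations.
    """
    therapy_events = [e for e in annotations if e.code in THERAPY_EVENT_CODES]
    rhythm_events = [e for e in annotations if e.code in RHYTHM_EVENT_CODES]
    if span_end is None:
        span_end = log.stop_time_s
    if span_end is None:
        candidates = [e.time_ms / 1000.0 for e in log.entries]
        candidates += [e.time for e in annotations]
        span_end = max(candidates) if candidates else 0.0
    therapy = build_therapy_sequence(therapy_events, 0.0, span_end)
    if rhythm_events:
        response = build_response_sequence(rhythm_events, span_end)
    else:
        response = DomainSequence.empty("response")
    return Episode(
        therapy=therapy,
        response=response,
        shocks=log.shocks,
        mode_switches=log.mode_switches,
        power_on=log.power_on,
        episode_id=episode_id,
    )


# -- review database -----------------------------------------------------

#: time variable -> its three database columns (names follow the registry)
TIME_VARIABLE_COLUMNS = {
    "ecgtm": ("ecghr", "ecgmn", "ecgsc"),
    "shktm": ("shkhr", "shkmn", "shksc"),
    "fctm": ("fchr", "fcmn", "fcsc"),
    "lctm": ("lchr", "lcmn", "lcsc"),
    "vfonsettm": ("vfonsethr", "vfonsetmm", "vfonsetss"),
    "rsctm": ("rschr", "rscmn", "rscsc"),
}
#: coded categoricals compared by identity
CATEGORICAL_VARIABLES = (
    "init_rhy",
    "rhyb4",
    "r10",
    "r30",
    "r60",
    "r120",
    "vfpr",
    "orgpr",
    "rosc",
    "ssrecord",
    "shks",
    "mode",
    "cpr",
)
#: integer device readings compared with zero allowed deviation
NUMERIC_VARIABLES = ("imp", "enrgy")

DB_COLUMNS = (
    ["episode_id", "shkn"]
    + [c for cols in TIME_VARIABLE_COLUMNS.values() for c in cols]
    + list(CATEGORICAL_VARIABLES)
    + list(NUMERIC_VARIABLES)
)


def read_database(source: Source) -> pd.DataFrame:
    """Read a review-database CSV, validating the column contract."""
    text = _read_text(source)
    df = pd.read_csv(io.StringIO(text))
    missing = [c for c in DB_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"database CSV missing columns: {missing}")
    df = df[DB_COLUMNS].copy()
    int_cols = [c for c in DB_COLUMNS if c != "episode_id"]
    try:
        df[int_cols] = df[int_cols].astype(int)
    except ValueError as exc:
        raise SchemaError(f"non-integer value in database: {exc}") from exc
    if (df["shkn"] < 1).any():
        raise SchemaError("shkn must be >= 1")
    return df


def write_database(rows: pd.DataFrame, sink: Source) -> None:
    missing = [c for c in DB_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"database frame missing columns: {missing}")
    rows[DB_COLUMNS].to_csv(sink, index=False)


# -- plain-text episode rendering ----------------------------------------

_BLOCK_THERAPY = "Therapy domain:"
_BLOCK_RESPONSE = "Response domain:"
_BLOCK_EPISODE = "Episode:"
_UNDEFINED = "(undefined)"
_DASH = "–"  # en dash between start and end times


def _format_block(seq: DomainSequence) -> str:
    return "\n".join(
        f"{iv.start:.1f}{_DASH}{iv.end:.1f}: {iv.label}" for iv in seq.intervals
    )


def write_rore(episode: Episode) -> str:
    """Render the three-block episode representation as text.

    Times are printed at 0.1 s; the rendering round-trips exactly through
    :func:`read_rore` when all boundaries lie on the 0.1 s grid. With an
    undefined (empty) response domain only two blocks are emitted and the
    response block holds an explicit ``(undefined)`` marker.
    """
    parts = [_BLOCK_THERAPY, _format_block(episode.therapy)]
    if episode.response.is_empty:
        parts += ["", _BLOCK_RESPONSE, _UNDEFINED]
    else:
        parts += ["", _BLOCK_RESPONSE, _format_block(episode.response)]
        parts += ["", _BLOCK_EPISODE, _format_block(combine(episode.therapy, episode.response))]
    return "\n".join(parts) + "\n"


def _parse_block(lines: list[str], domain: str) -> DomainSequence:
    ivs = []
    for line in lines:
        body = line.strip()
        if not body:
            continue
        try:
            times, label = body.split(":", 1)
            a, b = times.replace(_DASH, "-").split("-", 1)
            ivs.append(StateInterval(float(a), float(b), label.strip()))
        except (ValueError, IndexError) as exc:
            raise SchemaError(f"bad rendering line {body!r}: {exc}") from exc
    return DomainSequence.from_intervals(domain, ivs)


def read_rore(
    text: str,
) -> tuple[DomainSequence, DomainSequence, Optional[DomainSequence]]:
    """Parse a rendering back into (therapy, response, combined) sequences.

    ``combined`` is None when the response domain was undefined.
    """
    blocks: dict[str, list[str]] = {}
    current: Optional[str] = None
    for line in text.splitlines():
        if line.strip() in (_BLOCK_THERAPY, _BLOCK_RESPONSE, _BLOCK_EPISODE):
            current = line.strip()
            blocks[current] = []
        elif current is not None:
            blocks[current].append(line)
    if _BLOCK_THERAPY not in blocks or _BLOCK_RESPONSE not in blocks:
        raise SchemaError("rendering must contain therapy and response blocks")
    therapy = _parse_block(blocks[_BLOCK_THERAPY], "therapy")
    resp_lines = [l for l in blocks[_BLOCK_RESPONSE] if l.strip()]
    if resp_lines and resp_lines[0].strip() == _UNDEFINED:
        return therapy, DomainSequence.empty("response"), None
    response = _parse_block(blocks[_BLOCK_RESPONSE], "response")
    combined = (
        _parse_block(blocks[_BLOCK_EPISODE], "combined")
        if _BLOCK_EPISODE in blocks
        else None
    )
    return therapy, response, combined
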