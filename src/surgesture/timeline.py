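"""Annotated case timelines: the event data model with readers and writers.

A :class:`CaseTimeline` is one video's worth of annotation: a time-ordered
list of gesture events across the two analyzed phases (MHT, DGB), the phase
durations, and clinical metadata (Parkland difficulty grade, critical-view-
of-safety score, intraoperative events).

Time coordinates are seconds relative to the start of the event's phase,
with half-open intervals ``[start, end)``: an event may begin exactly when
the previous one on the same hand ends.  Events on different hands may
overlap (bimanual work); events on the same hand — or two unattributed
events — may not.

Two on-disk dialects are supported.  The CSV dialect has header
``video_id,surgeon_id,phase,label,hand,start_s,end_s`` with one event per
row; phase durations and metadata travel in a single ``#meta`` comment line
holding a JSON object, so the CSV round-trips losslessly.  The JSON dialect
is one object per case with an ``events`` array and a ``metadata`` object.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .taxonomy import HANDS, PHASES, Taxonomy, TaxonomyError

_PHASE_ORDER = {p: i for i, p in enumerate(PHASES)}
_HAND_ORDER = {"left": 0, "right": 1, "unattributed": 2}

VALID_INTRAOP_EVENTS = frozenset(
    {
        "cholecystic_vascular_injury",
        "gallbladder_broken",
        "liver_thermal_injury",
        "gastrointestinal_injury",
        "bile_duct_injury",
        "parietal_peritoneum_injury",
        "check_for_cystic_stone",
    }
)


class TimelineError(ValueError):
    """Raised when a timeline file or structure fails validation."""


@dataclass(frozen=True, order=True)
class GestureEvent:
    """One labeled gesture occurrence within a phase.

    Ordering is (phase, start, hand, label) — total and deterministic, so a
    permutation of input rows always parses to the same timeline.
    """

    sort_index: tuple = field(init=False, repr=False, compare=True)
    label: str = field(compare=False)
    hand: str = field(compare=False)
    start_s: float = field(compare=False)
    end_s: float = field(compare=False)
    phase: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise TimelineError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.hand not in HANDS:
            raise TimelineError(f"unknown hand {self.hand!r}; expected one of {HANDS}")
        if not (self.start_s >= 0):
            raise TimelineError(f"event {self.label!r}: start_s must be >= 0, got {self.start_s}")
        if not (self.end_s > self.start_s):
            raise TimelineError(
                f"event {self.label!r}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        object.__setattr__(
            self,
            "sort_index",
            (_PHASE_ORDER[self.phase], self.start_s, _HAND_ORDER[self.hand], self.label),
        )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class CaseMetadata:
    parkland_grade: int = 1
    cvs_score: int = 0
    intraop_events: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= int(self.parkland_grade) <= 5:
            raise TimelineError(f"parkland_grade must be in 1..5, got {self.parkland_grade}")
        if not 0 <= int(self.cvs_score) <= 6:
            raise TimelineError(f"cvs_score must be in 0..6, got {self.cvs_score}")
        unknown = set(self.intraop_events) - VALID_INTRAOP_EVENTS
        if unknown:
            raise TimelineError(f"unknown intraoperative events: {sorted(unknown)}")
        object.__setattr__(self, "intraop_events", frozenset(self.intraop_events))


@dataclass(frozen=True)
class CaseTimeline:
    """One annotated video: ordered events, phase durations, metadata."""

    video_id: str
    surgeon_id: str
    events: tuple[GestureEvent, ...]
    phase_durations: dict[str, float]  # phase -> seconds
    metadata: CaseMetadata = field(default_factory=CaseMetadata)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(sorted(self.events)))
        object.__setattr__(self, "phase_durations", dict(self.phase_durations))
        for phase in self.phase_durations:
            if phase not in PHASES:
                raise TimelineError(f"unknown phase {phase!r} in phase_durations")
        if self.manipulation_time_s <= 0:
            raise TimelineError("total phase duration (manipulation time) must be > 0")
        self._validate_events()

    def _validate_events(self) -> None:
        last_end: dict[tuple[str, str], float] = {}
        for ev in self.events:
            dur = self.phase_durations.get(ev.phase)
            if dur is None:
                raise TimelineError(
                    f"event {ev.label!r} in phase {ev.phase!r} but no duration for that phase"
                )
            if ev.end_s > dur + 1e-9:
                raise TimelineError(
                    f"event {ev.label!r} [{ev.start_s}, {ev.end_s}) exceeds "
                    f"{ev.phase} duration {dur}"
                )
            key = (ev.phase, ev.hand)
            prev = last_end.get(key)
            # half-open intervals: start == previous end is not an overlap
            if prev is not None and ev.start_s < prev - 1e-9:
                raise TimelineError(
                    f"same-hand overlap in {ev.phase}/{ev.hand}: event {ev.label!r} "
                    f"starts at {ev.start_s} before previous ends at {prev}"
                )
            last_end[key] = max(prev or 0.0, ev.end_s)

    @property
    def manipulation_time_s(self) -> float:
        """Combined MHT + DGB duration in seconds."""
        return float(sum(self.phase_durations.values()))

    def events_in_phase(self, phase: str) -> tuple[GestureEvent, ...]:
        return tuple(ev for ev in self.events if ev.phase == phase)

    def validate_labels(self, taxonomy: Taxonomy) -> None:
        """Check every label against the vocabulary and per-hand rules."""
        for i, ev in enumerate(self.events):
            if ev.label not in taxonomy:
                raise TimelineError(f"event {i}: unknown gesture label {ev.label!r}")
            if taxonomy[ev.label].per_hand and ev.hand == "unattributed":
                raise TimelineError(
                    f"event {i}: per-hand gesture {ev.label!r} requires hand left/right"
                )

    def with_events(self, events) -> "CaseTimeline":
        return replace(self, events=tuple(events))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_HEADER = "video_id,surgeon_id,phase,label,hand,start_s,end_s"


def _fmt(x: float) -> str:
    """Canonical decimal rendering so repeated writes are byte-identical."""
    return repr(round(float(x), 6))


def _meta_dict(case: CaseTimeline) -> dict:
    return {
        "video_id": case.video_id,
        "surgeon_id": case.surgeon_id,
        "phase_durations": {p: round(float(d), 6) for p, d in sorted(case.phase_durations.items())},
        "metadata": {
            "parkland_grade": int(case.metadata.parkland_grade),
            "cvs_score": int(case.metadata.cvs_score),
            "intraop_events": sorted(case.metadata.intraop_events),
        },
    }


def write_timeline(case: CaseTimeline, path: str | Path) -> None:
    """Write a case in the CSV dialect (``.json`` extension: JSON dialect).

    Output is canonical: sorted events, fixed field order, fixed float
    rendering — two writes of the same case are byte-identical.
    """
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(_to_json(case), encoding="utf-8")
        return
    buf = io.StringIO()
    buf.write("#meta " + json.dumps(_meta_dict(case), sort_keys=True) + "\n")
    buf.write(_CSV_HEADER + "\n")
    for ev in case.events:
        buf.write(
            f"{case.video_id},{case.surgeon_id},{ev.phase},{ev.label},{ev.hand},"
            f"{_fmt(ev.start_s)},{_fmt(ev.end_s)}\n"
        )
    path.write_text(buf.getvalue(), encoding="utf-8")


def _to_json(case: CaseTimeline) -> str:
    obj = {
        "video_id": case.video_id,
        "surgeon_id": case.surgeon_id,
        "events": [
            {
                "phase": ev.phase,
                "label": ev.label,
                "hand": ev.hand,
                "start_s": round(float(ev.start_s), 6),
                "end_s": round(float(ev.end_s), 6),
            }
            for ev in case.events
        ],
        **_meta_dict(case),
    }
    return json.dumps(obj, indent=1, sort_keys=True) + "\n"


def _case_from_parts(
    video_id: str,
    surgeon_id: str,
    rows: list[tuple[str, str, str, float, float]],
    meta: dict,
    taxonomy: Taxonomy | None,
) -> CaseTimeline:
    events = []
    errors = []
    for i, (phase, label, hand, start, end) in enumerate(rows, start=1):
        try:
            events.append(
                GestureEvent(label=label, hand=hand, start_s=start, end_s=end, phase=phase)
            )
        except TimelineError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise TimelineError("invalid event rows:\n  " + "\n  ".join(errors))
    md = meta.get("metadata", {})
    phase_durations = meta.get("phase_durations")
    if phase_durations is None:
        # fall back to the observed extent of each phase
        phase_durations = {}
        for ev in events:
            phase_durations[ev.phase] = max(phase_durations.get(ev.phase, 0.0), ev.end_s)
        if not phase_durations:
            raise TimelineError("no events and no phase_durations metadata")
    case = CaseTimeline(
        video_id=video_id,
        surgeon_id=surgeon_id,
        events=tuple(events),
        phase_durations={p: float(d) for p, d in phase_durations.items()},
        metadata=CaseMetadata(
            parkland_grade=int(md.get("parkland_grade", 1)),
            cvs_score=int(md.get("cvs_score", 0)),
            intraop_events=frozenset(md.get("intraop_events", ())),
        ),
    )
    if taxonomy is not None:
        try:
            case.validate_labels(taxonomy)
        except TaxonomyError as exc:
            raise TimelineError(str(exc)) from exc
    return case


def read_timeline(path: str | Path, taxonomy: Taxonomy | None = None) -> CaseTimeline:
    """Read one case from either dialect; events are re-sorted and validated."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        obj = json.loads(text)
        rows = [
            (e["phase"], e["label"], e.get("hand", "unattributed"),
             float(e["start_s"]), float(e["end_s"]))
            for e in obj.get("events", [])
        ]
        return _case_from_parts(
            str(obj["video_id"]), str(obj["surgeon_id"]), rows, obj, taxonomy
        )

    meta: dict = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if line.startswith("#meta "):
                meta = json.loads(line[len("#meta "):])
        else:
            break
    if body_start >= len(lines) or lines[body_start].strip() != _CSV_HEADER:
        raise TimelineError(f"{path}: expected header {_CSV_HEADER!r}")
    video_id = surgeon_id = None
    rows = []
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise TimelineError(f"{path} row {lineno}: expected 7 fields, got {len(parts)}")
        vid, sid, phase, label, hand, start, end = (p.strip() for p in parts)
        if video_id is None:
            video_id, surgeon_id = vid, sid
        elif (vid, sid) != (video_id, surgeon_id):
            raise TimelineError(
                f"{path} row {lineno}: mixed video/surgeon ids in one timeline file"
            )
        try:
            rows.append((phase, label, hand, float(start), float(end)))
        except ValueError:
            raise TimelineError(f"{path} row {lineno}: non-numeric start/end") from None
    if video_id is None:
        video_id = meta.get("video_id")
        surgeon_id = meta.get("surgeon_id")
        if video_id is None:
            raise TimelineError(f"{path}: empty timeline needs a #meta line with ids")
    return _case_from_parts(str(video_id), str(surgeon_id), rows, meta, taxonomy)


def read_timeline_dir(directory: str | Path, taxonomy: Taxonomy | None = None) -> list[CaseTimeline]:
    """Read every ``*.csv`` / ``*.json`` timeline in a directory, sorted by name."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.suffix in (".csv", ".json"))
    if not paths:
        raise TimelineError(f"no timeline files found in {directory}")
    return [read_timeline(p, taxonomy) for p in paths]
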