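"""The 63-feature representation of one annotated case.

Under the default 20-category vocabulary the feature vector decomposes as

=====================  ==  =========================================
counts                 20  events per tracked category (MHT+DGB)
durations              20  total seconds per tracked category
intervals              12  gap stats (mean/max/min/SD) x 3 streams
shift frequencies       3  label changes per minute x 3 streams
dissection/exposure     7  D and E counts/durations, ratios, D<->E shift
manipulation time       1  MHT + DGB duration, minutes
=====================  ==  =========================================

Streams are the all-events sequence and the left- and right-hand
subsequences, each time-sorted within a phase; gaps and label shifts are
never counted across the MHT/DGB boundary.  Gaps in the all-events stream
may be negative when the hands overlap; they are clamped to zero.  Shift
frequencies and the D<->E shift are per-minute rates (divided by
manipulation time), so they compare across cases of different operative
length.  Ratios with an empty denominator use a floor of 1 event / 1 s
rather than reporting infinity, keeping feature matrices finite.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import DISSECTION, PHASES, Taxonomy
from .timeline import CaseTimeline, GestureEvent

log = logging.getLogger(__name__)

INTERVAL_STREAMS = ("all", "left", "right")
INTERVAL_STATS = ("mean", "max", "min", "sd")


def feature_names(taxonomy: Taxonomy) -> list[str]:
    """Deterministic feature order for a vocabulary: 63 names by default."""
    cats = taxonomy.tracked_categories()
    names = [f"count.{c}" for c in cats]
    names += [f"dur.{c}" for c in cats]
    names += [f"int.{s}.{st}" for s in INTERVAL_STREAMS for st in INTERVAL_STATS]
    names += [f"shift.{s}" for s in INTERVAL_STREAMS]
    names += ["de.count_D", "de.count_E", "de.dur_D", "de.dur_E",
              "de.count_ratio", "de.dur_ratio", "de.shift"]
    names += ["manip_time"]
    return names


def _stream(events: Sequence[GestureEvent], which: str) -> list[GestureEvent]:
    if which == "all":
        return list(events)
    return [ev for ev in events if ev.hand == which]


def count_and_duration_features(case: CaseTimeline, taxonomy: Taxonomy) -> dict[str, float]:
    """Per tracked category: event count and total duration in seconds."""
    case.validate_labels(taxonomy)
    cats = taxonomy.tracked_categories()
    counts = dict.fromkeys(cats, 0)
    durs = dict.fromkeys(cats, 0.0)
    for ev in case.events:
        cat = taxonomy.category_of(ev.label, ev.hand)
        counts[cat] += 1
        durs[cat] += ev.duration_s
    out = {f"count.{c}": float(counts[c]) for c in cats}
    out.update({f"dur.{c}": durs[c] for c in cats})
    return out


def _phase_gaps(events: Sequence[GestureEvent]) -> list[float]:
    """Inter-event gaps within each phase; negative gaps clamped to 0."""
    gaps: list[float] = []
    for phase in PHASES:
        evs = sorted((ev for ev in events if ev.phase == phase),
                     key=lambda e: (e.start_s, e.end_s))
        for prev, nxt in zip(evs, evs[1:]):
            gaps.append(max(0.0, nxt.start_s - prev.end_s))
    return gaps


def interval_features(case: CaseTimeline) -> dict[str, float]:
    """Gap statistics (mean/max/min/sample SD) for the all/left/right streams.

    A stream with fewer than two events has no gaps; its four statistics are
    reported as 0 with a logged warning so the vector length never varies.
    """
    out: dict[str, float] = {}
    for stream in INTERVAL_STREAMS:
        gaps = _phase_gaps(_stream(case.events, stream))
        if not gaps:
            log.warning("case %s: stream %r has <2 events; interval stats set to 0",
                        case.video_id, stream)
            stats = {"mean": 0.0, "max": 0.0, "min": 0.0, "sd": 0.0}
        else:
            arr = np.asarray(gaps, dtype=float)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            if arr.size == 1:
                log.warning("case %s: stream %r has a single gap; SD set to 0",
                            case.video_id, stream)
            stats = {"mean": float(arr.mean()), "max": float(arr.max()),
                     "min": float(arr.min()), "sd": sd}
        for st in INTERVAL_STATS:
            out[f"int.{stream}.{st}"] = stats[st]
    return out


def _label_changes(events: Sequence[GestureEvent], key) -> int:
    changes = 0
    for phase in PHASES:
        evs = sorted((ev for ev in events if ev.phase == phase),
                     key=lambda e: (e.start_s, e.end_s))
        changes += sum(1 for a, b in zip(evs, evs[1:]) if key(a) != key(b))
    return changes


def shift_frequency(case: CaseTimeline, stream: str = "all") -> float:
    """Label changes per minute along the time-sorted stream (within phases)."""
    if stream not in INTERVAL_STREAMS:
        raise ValueError(f"stream must be one of {INTERVAL_STREAMS}, got {stream!r}")
    manip_min = case.manipulation_time_s / 60.0
    if manip_min <= 0:
        raise ValueError("manipulation time must be positive")
    changes = _label_changes(_stream(case.events, stream), key=lambda e: e.label)
    return changes / manip_min


def de_features(case: CaseTimeline, taxonomy: Taxonomy) -> dict[str, float]:
    """Dissection/exposure aggregates: counts, durations, ratios, D<->E shift."""
    case.validate_labels(taxonomy)
    count_d = count_e = 0
    dur_d = dur_e = 0.0
    for ev in case.events:
        if taxonomy.functional_class(ev.label) == DISSECTION:
            count_d += 1
            dur_d += ev.duration_s
        else:
            count_e += 1
            dur_e += ev.duration_s
    if count_e == 0:
        log.warning("case %s: no exposure events; count ratio uses floor of 1 event",
                    case.video_id)
    if dur_e <= 0:
        log.warning("case %s: zero exposure duration; duration ratio uses floor of 1 s",
                    case.video_id)
    manip_min = case.manipulation_time_s / 60.0
    changes = _label_changes(case.events, key=lambda e: taxonomy.functional_class(e.label))
    return {
        "de.count_D": float(count_d),
        "de.count_E": float(count_e),
        "de.dur_D": dur_d,
        "de.dur_E": dur_e,
        "de.count_ratio": count_d / max(count_e, 1),
        "de.dur_ratio": dur_d / max(dur_e, 1.0),
        "de.shift": changes / manip_min,
    }


def extract_features(case: CaseTimeline, taxonomy: Taxonomy) -> dict[str, float]:
    """The full named feature vector of one case (63 entries by default)."""
    out = count_and_duration_features(case, taxonomy)
    out.update(interval_features(case))
    for stream in INTERVAL_STREAMS:
        out[f"shift.{stream}"] = shift_frequency(case, stream)
    out.update(de_features(case, taxonomy))
    out["manip_time"] = case.manipulation_time_s / 60.0
    names = feature_names(taxonomy)
    assert set(out) == set(names)
    return {name: out[name] for name in names}


def feature_matrix(cases: Iterable[CaseTimeline], taxonomy: Taxonomy) -> pd.DataFrame:
    """Feature table: one row per case, indexed by video id.

    Carries ``surgeon_id`` as a column ahead of the feature columns so the
    grouping needed for surgeon-aware cross-validation travels with the
    matrix.
    """
    rows = []
    index = []
    surgeons = []
    for case in cases:
        rows.append(extract_features(case, taxonomy))
        index.append(case.video_id)
        surgeons.append(case.surgeon_id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="video_id"),
                      columns=feature_names(taxonomy))
    df.insert(0, "surgeon_id", surgeons)
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix produced by :func:`feature_matrix`."""
    return [c for c in df.columns if c != "surgeon_id"]
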