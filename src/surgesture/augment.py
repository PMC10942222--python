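"""Timeline-level data augmentation and class balancing.

Annotated skill cohorts are small and imbalanced (typically far fewer
incompetent than competent cases), so training folds are equalized by
oversampling the minority class with perturbed copies of its timelines.
The perturbation scheme is the event-stream analogue of light text
augmentation: boundary jitter (~synonym-level noise), random event
deletion, and duplication-with-jitter (~insertion).  Gesture labels are
never altered, every output passes full timeline validation, and all
randomness flows from an explicit seed.

Augmentation belongs strictly inside training folds: perturbing a case
that shares its source with a held-out case leaks identity information,
so the cross-validation driver applies :func:`balance_classes` after the
fold split, never before.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .taxonomy import PHASES
from .timeline import CaseTimeline, GestureEvent

_MIN_DURATION_S = 0.05  # survived events keep at least this much time
_TRUNC = 1.5  # jitter truncated at +/- 1.5 sd: one boundary moves < 1.5*sd


class AugmentError(ValueError):
    """Raised for parameter combinations that cannot produce valid output."""


@dataclass(frozen=True)
class AugmentParams:
    jitter_sd_s: float = 1.0
    p_delete: float = 0.05
    p_duplicate: float = 0.05
    target_balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_s < 0:
            raise AugmentError("jitter_sd_s must be >= 0")
        if not (0 <= self.p_delete < 1):
            raise AugmentError("p_delete must lie in [0, 1): deleting everything "
                               "would empty the timeline")
        if not (0 <= self.p_duplicate < 1):
            raise AugmentError("p_duplicate must lie in [0, 1)")


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.clip(rng.normal(0.0, sd), -_TRUNC * sd, _TRUNC * sd))


def augment_timeline(case: CaseTimeline, params: AugmentParams,
                     rng: np.random.Generator | int | None = None,
                     new_video_id: str | None = None) -> CaseTimeline:
    """One perturbed copy of a case; identity when all knobs are zero.

    Boundaries receive truncated-Gaussian jitter; ordering, positivity and
    same-hand non-overlap are re-enforced by clipping against the previous
    event in the stream and the phase duration.  Each event is independently
    deleted with ``p_delete`` (at least one event always survives) and
    duplicated-with-jitter with ``p_duplicate``.  Deterministic given the
    generator state.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else int(rng))

    if params.jitter_sd_s == 0 and params.p_delete == 0 and params.p_duplicate == 0:
        return case if new_video_id is None else replace(case, video_id=new_video_id)

    # deletion (never all events), then duplication candidates
    survivors = [ev for ev in case.events if rng.random() >= params.p_delete]
    if case.events and not survivors:
        survivors = [case.events[int(rng.integers(len(case.events)))]]
    pool: list[GestureEvent] = []
    for ev in survivors:
        pool.append(ev)
        if rng.random() < params.p_duplicate:
            # duplicate placed just after the original; clipping pass resolves fit
            offset = abs(_truncated_normal(rng, max(params.jitter_sd_s, _MIN_DURATION_S)))
            pool.append(replace(ev,
                                start_s=ev.end_s + offset,
                                end_s=ev.end_s + offset + ev.duration_s))

    # jitter + clip, stream by stream (phase x hand)
    out: list[GestureEvent] = []
    for phase in PHASES:
        phase_dur = case.phase_durations.get(phase)
        if phase_dur is None:
            continue
        for hand in ("left", "right", "unattributed"):
            stream = sorted((ev for ev in pool if ev.phase == phase and ev.hand == hand),
                            key=lambda e: (e.start_s, e.end_s))
            prev_end = 0.0
            for ev in stream:
                start = ev.start_s + _truncated_normal(rng, params.jitter_sd_s)
                end = ev.end_s + _truncated_normal(rng, params.jitter_sd_s)
                start = min(max(start, prev_end, 0.0), phase_dur - _MIN_DURATION_S)
                end = min(max(end, start + _MIN_DURATION_S), phase_dur)
                if end - start < _MIN_DURATION_S / 2 or start < prev_end:
                    continue  # duplicate that no longer fits
                out.append(replace(ev, start_s=start, end_s=end))
                prev_end = end
    return replace(case, events=tuple(out),
                   video_id=new_video_id if new_video_id is not None else case.video_id)


def balance_classes(cases: list[CaseTimeline], labels: np.ndarray,
                    params: AugmentParams) -> tuple[list[CaseTimeline], np.ndarray, dict[str, str]]:
    """Oversample the minority class with augmented copies until classes match.

    Returns the extended case list, extended labels, and a provenance map
    from each synthetic video id to its source video id.  Synthetic ids are
    ``<source>#aug<i>``.  Deterministic given ``params.seed``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(cases) != len(labels):
        raise AugmentError("cases and labels must align")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise AugmentError("both classes must be present to balance")
    minority = int(classes[np.argmin(counts)])
    deficit = int(counts.max() - counts.min())
    minority_idx = [i for i, y in enumerate(labels) if y == minority]

    new_cases = list(cases)
    new_labels = list(labels)
    provenance: dict[str, str] = {}
    seeds = np.random.SeedSequence(params.seed).spawn(max(deficit, 1))
    for j in range(deficit):
        src = cases[minority_idx[j % len(minority_idx)]]
        rng = np.random.default_rng(seeds[j])
        new_id = f"{src.video_id}#aug{j}"
        new_cases.append(augment_timeline(src, params, rng, new_video_id=new_id))
        new_labels.append(minority)
        provenance[new_id] = src.video_id
    return new_cases, np.array(new_labels, dtype=int), provenance
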