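import numpy as np
import pytest

from surgesture import CaseTimeline, GestureEvent, default_taxonomy
from surgesture.taxonomy import PHASES


@pytest.fixture(scope="session")
def tax():
    return default_taxonomy()


def make_random_timeline(rng: np.random.Generator, tax, max_events: int = 30,
                         video_id: str = "V", surgeon_id: str = "S") -> CaseTimeline:
    """A small random valid timeline: sequential events per (phase, hand) stream."""
    phase_durations = {p: round(float(rng.uniform(60, 240)), 3) for p in PHASES}
    events = []
    n_target = int(rng.integers(0, max_events + 1))
    names = tax.names
    budget = n_target
    for phase in PHASES:
        for hand in ("left", "right", "unattributed"):
            t = float(rng.uniform(0, 5))
            while budget > 0 and t < phase_durations[phase] - 2:
                label = str(names[int(rng.integers(len(names)))])
                if tax[label].per_hand and hand == "unattributed":
                    continue
                if not tax[label].per_hand and hand != "unattributed":
                    # single gestures live on the unattributed stream here
                    budget -= 1
                    continue
                dur = float(rng.uniform(0.5, 15))
                end = min(t + dur, phase_durations[phase])
                if end - t < 0.2:
                    break
                events.append(GestureEvent(label=label, hand=hand,
                                           start_s=round(t, 3), end_s=round(end, 3),
                                           phase=phase))
                budget -= 1
                t = end + float(rng.uniform(0.05, 10))
    return CaseTimeline(video_id=video_id, surgeon_id=surgeon_id,
                        events=tuple(events), phase_durations=phase_durations)


@pytest.fixture()
def random_timeline(tax):
    def factory(seed: int = 0, max_events: int = 30):
        return make_random_timeline(np.random.default_rng(seed), tax, max_events)
    return factory
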