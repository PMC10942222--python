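"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops and textbook formulas, sharing no code with
the package's feature/statistic implementations.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_features(case, taxonomy) -> dict[str, float]:
    """Recompute the full feature vector of one case by direct bookkeeping."""
    out: dict[str, float] = {}

    def cat(ev):
        g = taxonomy[ev.label]
        if g.per_hand:
            return f"{ev.label}.{'L' if ev.hand == 'left' else 'R'}"
        return ev.label

    for c in taxonomy.tracked_categories():
        evs = [e for e in case.events if cat(e) == c]
        out[f"count.{c}"] = float(len(evs))
        out[f"dur.{c}"] = float(sum(e.end_s - e.start_s for e in evs))

    def stream_events(which):
        if which == "all":
            return list(case.events)
        return [e for e in case.events if e.hand == which]

    for which in ("all", "left", "right"):
        gaps = []
        for phase in ("MHT", "DGB"):
            evs = sorted([e for e in stream_events(which) if e.phase == phase],
                         key=lambda e: (e.start_s, e.end_s))
            for i in range(len(evs) - 1):
                gaps.append(max(0.0, evs[i + 1].start_s - evs[i].end_s))
        if gaps:
            mean = sum(gaps) / len(gaps)
            var = (sum((g - mean) ** 2 for g in gaps) / (len(gaps) - 1)
                   if len(gaps) > 1 else 0.0)
            vals = {"mean": mean, "max": max(gaps), "min": min(gaps),
                    "sd": math.sqrt(var)}
        else:
            vals = {"mean": 0.0, "max": 0.0, "min": 0.0, "sd": 0.0}
        for st, v in vals.items():
            out[f"int.{which}.{st}"] = v

    manip_min = sum(case.phase_durations.values()) / 60.0
    for which in ("all", "left", "right"):
        changes = 0
        for phase in ("MHT", "DGB"):
            evs = sorted([e for e in stream_events(which) if e.phase == phase],
                         key=lambda e: (e.start_s, e.end_s))
            for i in range(len(evs) - 1):
                if evs[i + 1].label != evs[i].label:
                    changes += 1
        out[f"shift.{which}"] = changes / manip_min

    d_events = [e for e in case.events
                if taxonomy[e.label].functional_class == "dissection"]
    e_events = [e for e in case.events
                if taxonomy[e.label].functional_class == "exposure"]
    cd, ce = len(d_events), len(e_events)
    dd = sum(e.end_s - e.start_s for e in d_events)
    de = sum(e.end_s - e.start_s for e in e_events)
    changes = 0
    for phase in ("MHT", "DGB"):
        evs = sorted([e for e in case.events if e.phase == phase],
                     key=lambda e: (e.start_s, e.end_s))
        for i in range(len(evs) - 1):
            if (taxonomy[evs[i + 1].label].functional_class
                    != taxonomy[evs[i].label].functional_class):
                changes += 1
    out["de.count_D"] = float(cd)
    out["de.count_E"] = float(ce)
    out["de.dur_D"] = dd
    out["de.dur_E"] = de
    out["de.count_ratio"] = cd / max(ce, 1)
    out["de.dur_ratio"] = dd / max(de, 1.0)
    out["de.shift"] = changes / manip_min
    out["manip_time"] = manip_min
    return out


def oracle_auc(scores, labels) -> float:
    """Pairwise concordance count: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_chi2(a, b, c, d) -> float:
    """Pearson statistic by the direct O-E loop on a 2x2 table."""
    obs = [[a, b], [c, d]]
    n = a + b + c + d
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            exp = rows[i] * cols[j] / n
            stat += (obs[i][j] - exp) ** 2 / exp
    return stat


def oracle_icc21(matrix) -> float:
    """ICC(2,1) by the explicit two-way ANOVA decomposition (loops only)."""
    m = np.asarray(matrix, dtype=float)
    k, n = m.shape
    grand = m.sum() / (k * n)
    ms_rows = 0.0  # targets (columns of the raters x videos layout)
    for j in range(n):
        ms_rows += (m[:, j].mean() - grand) ** 2
    ms_rows = k * ms_rows / (n - 1)
    ms_cols = 0.0
    for i in range(k):
        ms_cols += (m[i, :].mean() - grand) ** 2
    ms_cols = n * ms_cols / (k - 1)
    sse = 0.0
    for i in range(k):
        for j in range(n):
            resid = m[i, j] - m[i, :].mean() - m[:, j].mean() + grand
            sse += resid ** 2
    mse = sse / ((k - 1) * (n - 1))
    return (ms_rows - mse) / (ms_rows + (k - 1) * mse + k * (ms_cols - mse) / n)


def oracle_spearman_no_ties(x, y) -> float:
    """Classical 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    x = list(x)
    y = list(y)
    n = len(x)
    rx = [sorted(x).index(v) + 1 for v in x]
    ry = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n * (n ** 2 - 1))
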