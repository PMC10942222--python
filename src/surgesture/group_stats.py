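"""Between-group statistics: chi-square on outcomes, per-feature tests, Spearman.

The outcome comparisons (e.g. cholecystic vascular injury by competence
group) use the Pearson chi-square test of independence on a 2x2 table
without continuity correction.  Feature-by-feature group contrasts pair a
rank test (Kruskal–Wallis, which for two groups is the tie-corrected
Mann–Whitney) with Student's t-test.  Spearman correlation relates
gesture features to mGOALS scores.  No multiple-testing adjustment is
applied by default across the 63 feature tests; a Benjamini–Hochberg
option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns


class StatsError(ValueError):
    """Raised for degenerate inputs (zero marginals, constant vectors)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows = skill groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("competent", "incompetent")
    col_labels: tuple[str, str] = ("no", "yes")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise StatsError(f"cell counts must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise StatsError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def pearson_chi2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 table: (statistic, dof=1, p).

    Warns when any expected count falls below 5 (the usual validity caveat)
    and rejects tables with a zero marginal, where expected counts vanish.
    """
    obs = table.as_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise StatsError("zero marginal: chi-square test undefined")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"expected count below 5 (min {expected.min():.2f}); "
            "chi-square approximation may be poor"
        )
    return float(stat), int(dof), float(p)


def proportion_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage as printed in outcome tables, e.g. 8/26 -> 30.8."""
    if denominator <= 0:
        raise StatsError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def group_feature_tests(features: pd.DataFrame, labels: np.ndarray,
                        adjust: str | None = None) -> pd.DataFrame:
    """Per-feature two-group contrasts: Kruskal–Wallis rank test + t-test.

    ``labels`` is a 0/1 array over the rows of ``features``.  Each feature
    row reports both tests' statistics and p-values and the direction of
    the group-1 minus group-0 mean difference; constant features are
    skipped with a note.  ``adjust='bh'`` appends Benjamini–Hochberg
    q-values for the rank test (off by default).
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise StatsError("labels must be binary 0/1")
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        raise StatsError("both groups must be non-empty")
    cols = feature_columns(features)
    rows = []
    for col in cols:
        x = features.loc[:, col].to_numpy(dtype=float)
        g0, g1 = x[labels == 0], x[labels == 1]
        if np.all(x == x[0]):
            rows.append({"feature": col, "note": "constant feature; tests skipped",
                         "kw_stat": np.nan, "kw_p": np.nan,
                         "t_stat": np.nan, "t_p": np.nan, "direction": 0})
            continue
        kw_stat, kw_p = stats.kruskal(g0, g1)
        t_stat, t_p = stats.ttest_ind(g0, g1)
        rows.append({
            "feature": col, "note": "",
            "kw_stat": float(kw_stat), "kw_p": float(kw_p),
            "t_stat": float(t_stat), "t_p": float(t_p),
            "direction": int(np.sign(g1.mean() - g0.mean())),
        })
    out = pd.DataFrame(rows).set_index("feature")
    if adjust == "bh":
        mask = out["kw_p"].notna()
        q = np.full(len(out), np.nan)
        q[mask.to_numpy()] = stats.false_discovery_control(
            out.loc[mask, "kw_p"].to_numpy(), method="bh")
        out["kw_q_bh"] = q
    elif adjust is not None:
        raise StatsError(f"unknown adjustment {adjust!r}; use 'bh' or None")
    return out


def spearman(x, y) -> float:
    """Spearman rank correlation with midrank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise StatsError("spearman needs two equal-length vectors of >=3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("spearman undefined for a constant vector")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
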