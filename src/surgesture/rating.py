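"""mGOALS skill ratings: aggregation, rater agreement, quantile grouping.

The modified Global Operative Assessment of Laparoscopic Skills (mGOALS)
scores four items — depth perception, bimanual dexterity, efficiency,
tissue handling — each 1..5, for a case total of 4..20.  (The original
GOALS "autonomy" item is dropped for independently operating surgeons.)

Two or more raters score each video.  Rater consistency is verified with
the intraclass correlation coefficient ICC(2,1) — two-way random effects,
absolute agreement, single measure — against a qualification threshold of
0.75, and with Kendall's coefficient of concordance W (midrank ties, tie
correction).

Surgeons are grouped by the empirical quartiles of their mean case score:
bottom level below the first quartile, top level above the third, medium
between; the binary split is competent (top + medium) versus incompetent
(bottom).  Scores landing exactly on a cut are medium.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

MGOALS_ITEMS = ("depth_perception", "bimanual_dexterity", "efficiency", "tissue_handling")
ICC_QUALIFICATION_THRESHOLD = 0.75


class RatingError(ValueError):
    """Raised for malformed ratings or degenerate agreement inputs."""


@dataclass(frozen=True)
class MGoalsRating:
    video_id: str
    rater_id: str
    items: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.items) != set(MGOALS_ITEMS):
            raise RatingError(
                f"rating for {self.video_id} must score exactly the items "
                f"{MGOALS_ITEMS}, got {sorted(self.items)}"
            )
        for item, score in self.items.items():
            if not (isinstance(score, (int, np.integer)) and 1 <= score <= 5):
                raise RatingError(
                    f"rating for {self.video_id}, item {item!r}: score must be "
                    f"an integer in [1, 5], got {score!r}"
                )
        object.__setattr__(self, "items", dict(self.items))

    @property
    def total(self) -> int:
        return int(sum(self.items.values()))


def case_score(ratings: list[MGoalsRating]) -> tuple[float, dict[str, float]]:
    """Mean across raters of item sums, plus per-item rater means."""
    if not ratings:
        raise RatingError("at least one rating is required")
    vids = {r.video_id for r in ratings}
    if len(vids) > 1:
        raise RatingError(f"ratings span multiple videos: {sorted(vids)}")
    total = float(np.mean([r.total for r in ratings]))
    per_item = {item: float(np.mean([r.items[item] for r in ratings]))
                for item in MGOALS_ITEMS}
    return total, per_item


def ratings_table(ratings: list[MGoalsRating]) -> pd.DataFrame:
    """Long-form table (video_id, rater_id, one column per item, total)."""
    rows = [{"video_id": r.video_id, "rater_id": r.rater_id, **r.items, "total": r.total}
            for r in ratings]
    return pd.DataFrame(rows)


def case_scores(ratings: list[MGoalsRating]) -> pd.DataFrame:
    """Per-video mean total and per-item means, indexed by video id."""
    tab = ratings_table(ratings)
    agg = tab.groupby("video_id")[list(MGOALS_ITEMS) + ["total"]].mean()
    return agg.rename(columns={"total": "score"})


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

def icc_absolute_agreement(scores: np.ndarray) -> tuple[float, bool]:
    """ICC(2,1) from the two-way ANOVA mean squares of a raters x videos matrix.

    Rows are raters, columns are videos (targets).  Returns the coefficient
    and whether it clears the 0.75 qualification threshold.  A matrix with
    no between-video variance has an undefined ICC.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise RatingError("ICC needs a complete matrix with >=2 raters and >=2 videos")
    if np.isnan(scores).any():
        raise RatingError("ICC requires a complete matrix (no missing cells)")
    k, n = scores.shape  # k raters, n targets
    grand = scores.mean()
    target_means = scores.mean(axis=0)
    rater_means = scores.mean(axis=1)
    ss_rows = k * ((target_means - grand) ** 2).sum()      # between targets
    ss_cols = n * ((rater_means - grand) ** 2).sum()       # between raters
    ss_total = ((scores - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-12 and denom <= 1e-12:
        raise RatingError("degenerate ICC: no variance across videos")
    icc = float((msr - mse) / denom)
    return icc, icc > ICC_QUALIFICATION_THRESHOLD


def kendalls_w(scores: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for a raters x items matrix.

    Midranks for ties with the standard tie correction
    ``T_j = sum(t^3 - t) / 12`` per rater.  W is 1 under identical rankings
    and 0 when rank sums are all equal.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise RatingError("Kendall's W needs >=2 raters")
    k, n = scores.shape
    if n < 2:
        raise RatingError("Kendall's W needs >=2 rated items")
    ranks = np.vstack([rankdata(row) for row in scores])
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    tie_corr = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_corr += float((counts ** 3 - counts).sum()) / 12.0
    denom = k ** 2 * (n ** 3 - n) / 12.0 - k * tie_corr
    if denom <= 0:
        # every rater ranked every item identically tied: no information
        raise RatingError("degenerate Kendall's W: all ranks tied within every rater")
    return float(s / denom)


# ---------------------------------------------------------------------------
# Quantile grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkillGrouping:
    """Quartile cuts plus per-surgeon three-level and binary labels."""

    q1_cut: float
    q3_cut: float
    scores: dict[str, float]
    group: dict[str, str] = field(init=False)    # surgeon -> top|medium|bottom
    binary: dict[str, str] = field(init=False)   # surgeon -> competent|incompetent

    def __post_init__(self) -> None:
        if self.q1_cut > self.q3_cut:
            raise RatingError("q1_cut must not exceed q3_cut")
        group = {}
        binary = {}
        for sid, score in self.scores.items():
            if score < self.q1_cut:
                g = "bottom"
            elif score > self.q3_cut:
                g = "top"
            else:
                g = "medium"
            group[sid] = g
            binary[sid] = "incompetent" if g == "bottom" else "competent"
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "binary", binary)

    def binary_labels(self, surgeon_ids) -> np.ndarray:
        """0/1 array over an id sequence; 1 marks incompetent (the positive
        class the classifier is asked to detect)."""
        return np.array([1 if self.binary[s] == "incompetent" else 0
                         for s in surgeon_ids], dtype=int)


def quantile_grouping(surgeon_scores: dict[str, float],
                      q_low: float = 0.25, q_high: float = 0.75) -> SkillGrouping:
    """Three-level grouping at the empirical q_low/q_high quantiles.

    Quantiles use the linear-interpolation estimator.  Boundary scores fall
    in the medium group; a constant score vector yields a single (medium)
    group with a warning.
    """
    if len(surgeon_scores) < 4:
        raise RatingError("quantile grouping needs >=4 surgeons")
    if not (0 < q_low <= q_high < 1):
        raise RatingError("need 0 < q_low <= q_high < 1")
    vals = np.array(list(surgeon_scores.values()), dtype=float)
    q1, q3 = np.quantile(vals, [q_low, q_high], method="linear")
    if vals.min() == vals.max():
        warnings.warn("all scores identical: grouping is degenerate (everyone medium)")
    return SkillGrouping(q1_cut=float(q1), q3_cut=float(q3), scores=dict(surgeon_scores))


def surgeon_scores(scores_per_video: pd.DataFrame, surgeon_of: dict[str, str]) -> dict[str, float]:
    """Surgeon-level score: the mean of that surgeon's case scores."""
    by_surgeon: dict[str, list[float]] = {}
    for vid, row in scores_per_video.iterrows():
        by_surgeon.setdefault(surgeon_of[vid], []).append(float(row["score"]))
    return {sid: float(np.mean(v)) for sid, v in by_surgeon.items()}


def item_binarize(per_item_scores: pd.Series, q: float = 0.25) -> pd.Series:
    """Per-video binary target for one mGOALS item: 1 below the q-quantile.

    Mirrors the overall bottom-quartile construction at the item level;
    invariant to monotone rescaling of the scores.  A cut below which no
    video falls yields an all-zero (degenerate) target with a warning.
    """
    if len(per_item_scores) < 4:
        raise RatingError("item binarization needs >=4 videos")
    vals = per_item_scores.astype(float)
    cut = float(np.quantile(vals.to_numpy(), q, method="linear"))
    labels = (vals < cut).astype(int)
    if labels.sum() == 0:
        warnings.warn(f"item target degenerate: no video below the {q:.0%} quantile")
    return labels


def read_ratings_csv(path) -> list[MGoalsRating]:
    """Ratings CSV: ``video_id,rater_id,dp,bd,eff,th`` (one row per rating)."""
    df = pd.read_csv(path, dtype={"video_id": str, "rater_id": str})
    short = {"dp": "depth_perception", "bd": "bimanual_dexterity",
             "eff": "efficiency", "th": "tissue_handling"}
    missing = {"video_id", "rater_id", *short} - set(df.columns)
    if missing:
        raise RatingError(f"ratings file missing columns: {sorted(missing)}")
    return [
        MGoalsRating(
            video_id=row["video_id"], rater_id=row["rater_id"],
            items={long: int(row[s]) for s, long in short.items()},
        )
        for _, row in df.iterrows()
    ]


def write_ratings_csv(ratings: list[MGoalsRating], path) -> None:
    rows = [{"video_id": r.video_id, "rater_id": r.rater_id,
             "dp": r.items["depth_perception"], "bd": r.items["bimanual_dexterity"],
             "eff": r.items["efficiency"], "th": r.items["tissue_handling"]}
            for r in ratings]
    pd.DataFrame(rows).to_csv(path, index=False)
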