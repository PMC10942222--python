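"""Synthetic surgeon cohorts with the skill-dependent structure of real ones.

Real gesture-annotated cholecystectomy cohorts are not publicly released,
so every pipeline stage is exercised against a generator whose group
contrasts are directly configured effect parameters:

* incompetent surgeons substitute inefficient gesture variants more often
  (``inefficient_rate_ratio``),
* operate longer (``duration_scale_ratio`` on phase durations),
* switch gestures more frequently (``shift_rate_ratio`` on the label-change
  probability between consecutive events), and
* spend relatively less time dissecting versus exposing: the expected
  dissection/exposure duration ratio of the competent group exceeds the
  incompetent group's by ``de_ratio_fold``.
* Cholecystic vascular injury is Bernoulli with a per-group probability.

Each video is a two-phase (MHT, DGB) alternating semi-Markov stream:
exposure and dissection blocks with exponential dwell times, filled with
log-normally-sized events whose labels persist or shift between
consecutive draws.  The block-dwell means are set so the expected D/E
duration ratio equals the configured per-group value, which makes the
generator self-calibrating for parameter-recovery checks.

Two simulated raters score each video: item score = latent skill per item
plus Gaussian noise, rounded and clipped to 1..5.  Latent skill is drawn
per surgeon by group and wobbles slightly per video.

The generator draws its feature-driving processes independently given the
surgeon's skill group; real inter-feature correlation structure beyond
what the shared group induces is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rating import MGOALS_ITEMS, MGoalsRating, write_ratings_csv
from .taxonomy import DISSECTION, EXPOSURE, Taxonomy, default_taxonomy
from .timeline import CaseMetadata, CaseTimeline, GestureEvent, write_timeline


class CohortConfigError(ValueError):
    """Raised before any generation when a cohort config is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, group split, and the effect block.

    Defaults mirror the study conditions this generator emulates: 75 videos
    by 33 surgeons, a 26/75 incompetent fraction, a 2-fold inefficient-
    gesture rate, 1.5-fold operative duration, 2-fold gesture shift rate,
    a 1.6-fold D/E duration-ratio advantage for the competent group, and
    vascular-injury probabilities of 6.1% (competent) vs 30.8%
    (incompetent).
    """

    seed: int
    n_videos: int = 75
    n_surgeons: int = 33
    incompetent_fraction: float = 26 / 75
    inefficient_rate_ratio: float = 2.0
    duration_scale_ratio: float = 1.5
    shift_rate_ratio: float = 2.0
    de_ratio_fold: float = 1.6
    injury_prob_competent: float = 0.061
    injury_prob_incompetent: float = 0.308
    rating_noise_sd: float = 0.35

    # baseline (competent-group) mechanics
    mht_mean_s: float = 330.0
    dgb_mean_s: float = 220.0
    phase_lognorm_sigma: float = 0.25
    exposure_dwell_mean_s: float = 25.0
    base_de_dwell_ratio: float = 1.25   # incompetent-group E[dur D]/E[dur E]
    event_mean_s: float = 4.5
    event_lognorm_sigma: float = 0.45
    gap_mean_s: float = 1.2
    base_shift_prob: float = 0.35
    base_inefficient_prob: float = 0.12

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CohortConfigError("seed is mandatory")
        if self.n_videos < 1 or self.n_surgeons < 1 or self.n_surgeons > self.n_videos:
            raise CohortConfigError("need 1 <= n_surgeons <= n_videos")
        if not (0 < self.incompetent_fraction < 1):
            raise CohortConfigError("incompetent_fraction must lie in (0, 1)")
        for name in ("inefficient_rate_ratio", "duration_scale_ratio",
                     "shift_rate_ratio", "de_ratio_fold"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(f"{name} must be > 0")
        for name in ("injury_prob_competent", "injury_prob_incompetent"):
            if not (0 <= getattr(self, name) <= 1):
                raise CohortConfigError(f"{name} must lie in [0, 1]")
        if self.rating_noise_sd < 0:
            raise CohortConfigError("rating_noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise CohortConfigError(f"unknown cohort config fields: {sorted(unknown)}")
        return cls(**cfg)


@dataclass(frozen=True)
class _GroupParams:
    """Generator parameters resolved for one skill group."""

    phase_scale: float
    de_dwell_ratio: float
    shift_prob: float
    inefficient_prob: float
    injury_prob: float
    skill_mean: float
    skill_sd: float


def _group_params(cfg: CohortConfig, group: str) -> _GroupParams:
    if group == "competent":
        return _GroupParams(
            phase_scale=1.0,
            de_dwell_ratio=cfg.base_de_dwell_ratio * cfg.de_ratio_fold,
            shift_prob=cfg.base_shift_prob,
            inefficient_prob=cfg.base_inefficient_prob,
            injury_prob=cfg.injury_prob_competent,
            skill_mean=17.4, skill_sd=1.3,
        )
    return _GroupParams(
        phase_scale=cfg.duration_scale_ratio,
        de_dwell_ratio=cfg.base_de_dwell_ratio,
        shift_prob=min(0.9, cfg.base_shift_prob * cfg.shift_rate_ratio),
        inefficient_prob=min(0.9, cfg.base_inefficient_prob * cfg.inefficient_rate_ratio),
        injury_prob=cfg.injury_prob_incompetent,
        skill_mean=13.6, skill_sd=1.2,
    )


# class vocabularies with draw weights; inefficient variants substitute
# their base gesture and inherit its functional class
_CLASS_WEIGHTS = {
    DISSECTION: (("hook", 0.45), ("blunt_dissection", 0.20), ("spread", 0.15),
                 ("coagulate", 0.10), ("cut", 0.05), ("clip", 0.05)),
    EXPOSURE: (("grasp", 0.40), ("push", 0.25), ("pull", 0.15), ("retract", 0.10),
               ("suction", 0.05), ("irrigate", 0.05)),
}
_INEFFICIENT_VARIANT = {"hook": "inefficient_hook", "grasp": "inefficient_grasp"}
# per-hand gestures lean toward the hand that typically performs them
_LEFT_HAND_PROB = {EXPOSURE: 0.65, DISSECTION: 0.35}


_CLASS_CUMW = {
    k: (tuple(n for n, _ in rows),
        np.cumsum([w for _, w in rows]) / sum(w for _, w in rows))
    for k, rows in _CLASS_WEIGHTS.items()
}


def _draw_label(rng: np.random.Generator, klass: str, p_ineff: float,
                tax: Taxonomy) -> tuple[str, str]:
    names, cumw = _CLASS_CUMW[klass]
    label = names[int(np.searchsorted(cumw, rng.random()))]
    if label in _INEFFICIENT_VARIANT and rng.random() < p_ineff:
        label = _INEFFICIENT_VARIANT[label]
    if tax[label].per_hand:
        hand = "left" if rng.random() < _LEFT_HAND_PROB[klass] else "right"
    else:
        hand = "unattributed"
    return label, hand


def _simulate_phase(rng: np.random.Generator, phase: str, phase_dur: float,
                    gp: _GroupParams, cfg: CohortConfig,
                    tax: Taxonomy) -> list[GestureEvent]:
    mu_e = cfg.exposure_dwell_mean_s
    mu_d = mu_e * gp.de_dwell_ratio
    events: list[GestureEvent] = []
    t = 0.0
    klass = EXPOSURE  # establish the field first
    label = hand = None
    while t < phase_dur - 1.0:
        dwell = max(6.0, rng.exponential(mu_d if klass == DISSECTION else mu_e))
        block_end = min(t + dwell, phase_dur)
        first_in_block = True
        while t < block_end - 0.5:
            if first_in_block or label is None or rng.random() < gp.shift_prob:
                label, hand = _draw_label(rng, klass, gp.inefficient_prob, tax)
            first_in_block = False
            dur = cfg.event_mean_s * rng.lognormal(0.0, cfg.event_lognorm_sigma)
            end = min(t + dur, block_end)
            if end - t < 0.3:
                break
            events.append(GestureEvent(label=label, hand=hand,
                                       start_s=round(t, 3), end_s=round(end, 3),
                                       phase=phase))
            # 10 ms separation floor keeps 3-decimal rounding from ever
            # inverting the order of adjacent events in one stream
            t = end + 0.01 + rng.exponential(cfg.gap_mean_s)
        t = max(t, block_end)
        klass = DISSECTION if klass == EXPOSURE else EXPOSURE
        label = None
    return events


def generate_cohort(cfg: CohortConfig, taxonomy: Taxonomy | None = None
                    ) -> tuple[list[CaseTimeline], list[MGoalsRating], pd.DataFrame]:
    """Draw one cohort: timelines, two-rater mGOALS scores, outcome table.

    Videos are dealt round-robin over surgeons (every surgeon contributes
    at least one).  The outcomes table has one row per video with the true
    group and the vascular-injury indicator.  Deterministic given the
    config (which embeds the seed).
    """
    tax = taxonomy or default_taxonomy()
    root = np.random.SeedSequence(cfg.seed)
    rng_assign = np.random.default_rng(root.spawn(1)[0])

    n_incomp = int(round(cfg.incompetent_fraction * cfg.n_surgeons))
    n_incomp = min(max(n_incomp, 1), cfg.n_surgeons - 1)
    groups = np.array(["incompetent"] * n_incomp
                      + ["competent"] * (cfg.n_surgeons - n_incomp))
    rng_assign.shuffle(groups)
    skill = {
        f"S{idx:03d}": float(np.clip(
            rng_assign.normal(_group_params(cfg, g).skill_mean,
                              _group_params(cfg, g).skill_sd),
            9.0 if g == "incompetent" else 15.6,
            15.4 if g == "incompetent" else 20.0))
        for idx, g in enumerate(groups)
    }
    surgeon_ids = list(skill)

    cases: list[CaseTimeline] = []
    ratings: list[MGoalsRating] = []
    outcome_rows = []
    video_seeds = root.spawn(cfg.n_videos)
    for v in range(cfg.n_videos):
        rng = np.random.default_rng(video_seeds[v])
        sid = surgeon_ids[v % cfg.n_surgeons]
        group = groups[v % cfg.n_surgeons]
        gp = _group_params(cfg, group)
        vid = f"V{v:04d}"

        phase_durations = {
            "MHT": round(cfg.mht_mean_s * gp.phase_scale
                         * rng.lognormal(0.0, cfg.phase_lognorm_sigma), 3),
            "DGB": round(cfg.dgb_mean_s * gp.phase_scale
                         * rng.lognormal(0.0, cfg.phase_lognorm_sigma), 3),
        }
        events = []
        for phase, dur in phase_durations.items():
            events.extend(_simulate_phase(rng, phase, dur, gp, cfg, tax))

        injured = bool(rng.random() < gp.injury_prob)
        intraop = set()
        if injured:
            intraop.add("cholecystic_vascular_injury")
        if rng.random() < 0.90:
            intraop.add("liver_thermal_injury")
        if rng.random() < 0.067:
            intraop.add("gallbladder_broken")
        metadata = CaseMetadata(
            parkland_grade=1 if rng.random() < 0.853 else 2,
            cvs_score=int(rng.integers(0, 5)),
            intraop_events=frozenset(intraop),
        )
        cases.append(CaseTimeline(video_id=vid, surgeon_id=sid, events=tuple(events),
                                  phase_durations=phase_durations, metadata=metadata))

        video_skill = float(np.clip(skill[sid] + rng.normal(0.0, 0.3), 4.0, 20.0))
        item_latent = video_skill / 4.0
        for rater in ("R1", "R2"):
            items = {
                item: int(np.clip(round(item_latent + rng.normal(0.0, cfg.rating_noise_sd)),
                                  1, 5))
                for item in MGOALS_ITEMS
            }
            ratings.append(MGoalsRating(video_id=vid, rater_id=rater, items=items))

        outcome_rows.append({"video_id": vid, "surgeon_id": sid, "true_group": group,
                             "cholecystic_vascular_injury": int(injured)})

    outcomes = pd.DataFrame(outcome_rows).set_index("video_id")
    return cases, ratings, outcomes


def null_config(seed: int, **overrides) -> CohortConfig:
    """A no-effect cohort: all group ratios 1, equal injury probabilities.

    Skill ratings still differ between groups, so downstream grouping works,
    but timelines carry no group signal — classifiers should score at
    chance.
    """
    base = dict(inefficient_rate_ratio=1.0, duration_scale_ratio=1.0,
                shift_rate_ratio=1.0, de_ratio_fold=1.0,
                injury_prob_competent=0.15, injury_prob_incompetent=0.15)
    base.update(overrides)
    return CohortConfig(seed=seed, **base)


def write_cohort(cases: list[CaseTimeline], ratings: list[MGoalsRating],
                 outcomes: pd.DataFrame, out_dir) -> None:
    """Write timelines/<video>.csv, ratings.csv, outcomes.csv under out_dir."""
    out = Path(out_dir)
    (out / "timelines").mkdir(parents=True, exist_ok=True)
    for case in cases:
        write_timeline(case, out / "timelines" / f"{case.video_id}.csv")
    write_ratings_csv(ratings, out / "ratings.csv")
    outcomes.to_csv(out / "outcomes.csv")


# ---------------------------------------------------------------------------
# Worked micro-cohort (checked-in files)
# ---------------------------------------------------------------------------

def worked_fixture() -> tuple[list[CaseTimeline], list[MGoalsRating], pd.DataFrame]:
    """The deterministic 12-video micro-cohort shipped with the package.

    Twelve small hand-authored timelines covering every parser and feature
    branch: per-hand gestures on both hands, overlapping bimanual events,
    back-to-back events, single-event streams, an all-dissection case, and
    an empty-events case.
    """
    from importlib.resources import files

    from .rating import read_ratings_csv
    from .timeline import read_timeline

    root = files("surgesture").joinpath("data/worked_fixture")
    tax = default_taxonomy()
    cases = [read_timeline(p, tax)
             for p in sorted(root.iterdir()) if p.name.startswith("V")]
    ratings = read_ratings_csv(root.joinpath("ratings.csv"))
    outcomes = pd.read_csv(root.joinpath("outcomes.csv")).set_index("video_id")
    return cases, ratings, outcomes
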