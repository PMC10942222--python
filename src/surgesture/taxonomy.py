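"""Surgesture vocabulary: gesture names, functional classes, hand tracking.

An annotated laparoscopic cholecystectomy timeline labels every elementary
functional gesture ("Surgesture") a surgeon performs.  Each gesture belongs
to exactly one functional class — *dissection* (tissue-dividing actions such
as hooking or blunt dissection) or *exposure* (field-establishing actions
such as grasping or pushing) — and carries an efficiency flag marking the
inefficient variants ("inefficient hook", "inefficient grasp").  Gestures
performed distinguishably by either hand are tracked per hand, doubling
their category count in the feature space.

The default vocabulary has 14 gestures, 6 of them per-hand, giving
2 x 6 + 8 = 20 tracked categories.  Only a subset of gesture names is fixed
by the annotation scheme this package models (hook, inefficient hook, grasp,
inefficient grasp, push, blunt dissection); the remaining names are
declared placeholders and every aspect of the vocabulary is overridable
through a YAML/JSON config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

DISSECTION = "dissection"
EXPOSURE = "exposure"
EFFECTIVE = "effective"
INEFFICIENT = "inefficient"

PHASES = ("MHT", "DGB")  # mobilizing hepatocystic triangle; gallbladder bed dissection
HANDS = ("left", "right", "unattributed")


class TaxonomyError(ValueError):
    """Raised when a taxonomy configuration is malformed."""


@dataclass(frozen=True)
class Gesture:
    name: str
    functional_class: str  # "dissection" | "exposure"
    efficiency: str = EFFECTIVE  # "effective" | "inefficient"
    per_hand: bool = False

    def __post_init__(self) -> None:
        if self.functional_class not in (DISSECTION, EXPOSURE):
            raise TaxonomyError(
                f"gesture {self.name!r}: functional_class must be "
                f"'{DISSECTION}' or '{EXPOSURE}', got {self.functional_class!r}"
            )
        if self.efficiency not in (EFFECTIVE, INEFFICIENT):
            raise TaxonomyError(
                f"gesture {self.name!r}: efficiency must be "
                f"'{EFFECTIVE}' or '{INEFFICIENT}', got {self.efficiency!r}"
            )


@dataclass(frozen=True)
class Taxonomy:
    """The gesture vocabulary used for validation and feature naming."""

    gestures: tuple[Gesture, ...]
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        names = [g.name for g in self.gestures]
        if not names:
            raise TaxonomyError("taxonomy must contain at least one gesture")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TaxonomyError(f"duplicate gesture names: {sorted(dupes)}")
        if not any(g.functional_class == DISSECTION for g in self.gestures):
            raise TaxonomyError("taxonomy has no dissection gestures")
        if not any(g.functional_class == EXPOSURE for g in self.gestures):
            raise TaxonomyError("taxonomy has no exposure gestures")
        object.__setattr__(self, "_by_name", {g.name: g for g in self.gestures})

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Gesture:
        try:
            return self._by_name[name]
        except KeyError:
            raise TaxonomyError(f"unknown gesture label {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.gestures)

    def tracked_categories(self) -> tuple[str, ...]:
        """Category names, per-hand gestures expanded to `<name>.L` / `<name>.R`.

        These are the units over which count and duration features are
        computed; the default vocabulary yields 20 of them.
        """
        cats: list[str] = []
        for g in self.gestures:
            if g.per_hand:
                cats.extend((f"{g.name}.L", f"{g.name}.R"))
            else:
                cats.append(g.name)
        return tuple(cats)

    def category_of(self, label: str, hand: str) -> str:
        g = self[label]
        if g.per_hand:
            if hand == "left":
                return f"{label}.L"
            if hand == "right":
                return f"{label}.R"
            raise TaxonomyError(
                f"per-hand gesture {label!r} requires hand 'left' or 'right', got {hand!r}"
            )
        return label

    def functional_class(self, label: str) -> str:
        return self[label].functional_class


# Default vocabulary.  The six names marked by the annotation scheme are
# fixed; the others are placeholders completing 14 gestures / 20 categories.
_DEFAULT_GESTURES: Sequence[tuple[str, str, str, bool]] = (
    # (name, functional_class, efficiency, per_hand)
    ("grasp", EXPOSURE, EFFECTIVE, True),
    ("inefficient_grasp", EXPOSURE, INEFFICIENT, True),
    ("push", EXPOSURE, EFFECTIVE, True),
    ("pull", EXPOSURE, EFFECTIVE, True),
    ("spread", DISSECTION, EFFECTIVE, True),
    ("retract", EXPOSURE, EFFECTIVE, True),
    ("hook", DISSECTION, EFFECTIVE, False),
    ("inefficient_hook", DISSECTION, INEFFICIENT, False),
    ("blunt_dissection", DISSECTION, EFFECTIVE, False),
    ("cut", DISSECTION, EFFECTIVE, False),
    ("clip", DISSECTION, EFFECTIVE, False),
    ("coagulate", DISSECTION, EFFECTIVE, False),
    ("suction", EXPOSURE, EFFECTIVE, False),
    ("irrigate", EXPOSURE, EFFECTIVE, False),
)


def default_taxonomy() -> Taxonomy:
    """The built-in 14-gesture vocabulary (20 tracked categories)."""
    return Taxonomy(tuple(Gesture(*row) for row in _DEFAULT_GESTURES))


def load_taxonomy(config_path: str | Path | None = None) -> Taxonomy:
    """Load a gesture vocabulary from a YAML/JSON config, or the default.

    The config holds a ``gestures:`` list of mappings with keys ``name``,
    ``functional_class``, and optional ``efficiency`` (default effective)
    and ``per_hand`` (default false).
    """
    if config_path is None:
        return default_taxonomy()
    path = Path(config_path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise TaxonomyError(f"cannot parse taxonomy config {path}: {exc}") from exc
    if not isinstance(cfg, dict) or "gestures" not in cfg:
        raise TaxonomyError(f"taxonomy config {path} must contain a 'gestures' list")
    gestures = []
    for i, entry in enumerate(cfg["gestures"]):
        if not isinstance(entry, dict) or "name" not in entry or "functional_class" not in entry:
            raise TaxonomyError(
                f"taxonomy config entry {i}: needs 'name' and 'functional_class'"
            )
        unknown = set(entry) - {"name", "functional_class", "efficiency", "per_hand"}
        if unknown:
            raise TaxonomyError(f"taxonomy config entry {i}: unknown fields {sorted(unknown)}")
        gestures.append(
            Gesture(
                name=str(entry["name"]),
                functional_class=str(entry["functional_class"]),
                efficiency=str(entry.get("efficiency", EFFECTIVE)),
                per_hand=bool(entry.get("per_hand", False)),
            )
        )
    return Taxonomy(tuple(gestures))
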