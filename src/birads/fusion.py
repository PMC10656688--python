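"""Frame-proportion fusion of per-frame lexicon labels into a BI-RADS call.

Per-frame labels are aggregated into per-category frame proportions;
each category then commits to one level via a proportion threshold
(suspicious levels win ties), the chosen levels are scored by a weight
table, and the total score is mapped through rank thresholds to a
BI-RADS category (2-5) and a benign/malignant call.  The weights and
thresholds are not fixed by any external source: the defaults are
chosen so the canonical archetypes land correctly (simple cyst -> 2,
all-benign solid -> 3, all-suspicious -> 5) and every number is
user-editable YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

from .features import FrameFeatures

__all__ = [
    "FeatureProfile",
    "ScoreTable",
    "Assessment",
    "NoLesionError",
    "aggregate_profile",
    "select_levels",
    "score_and_classify",
    "classify_video",
]

CATEGORIES = ("shape", "orientation", "margin", "echo", "posterior",
              "calcification")

#: ordered BI-RADS output categories (1 and 6 are never emitted)
BIRADS_ORDER = ("2", "3", "4a", "4b", "4c", "5")

_DEFAULT_WEIGHTS = {
    "shape": {"regular": 0, "irregular": 2},
    "orientation": {"parallel": 0, "not_parallel": 2},
    "margin": {"circumscribed": 0, "not_circumscribed": 2},
    "echo": {"anechoic": -2, "homogeneous": 0, "heterogeneous": 1},
    "posterior": {"none": 0, "enhancement": 0, "shadowing": 2},
    "calcification": {"none": 0, "coarse": 0, "punctate": 2},
}

_DEFAULT_PROPORTIONS = {
    "shape": 0.5, "orientation": 0.5, "margin": 0.5,
    "echo": 0.5, "posterior": 0.5, "calcification": 0.2,
}

#: (upper score bound inclusive, category); scanned in order
_DEFAULT_RANKS = [(-1, "2"), (0, "3"), (2, "4a"), (4, "4b"), (6, "4c")]


class NoLesionError(ValueError):
    """No lesion was detected in any frame of the video."""


@dataclass
class FeatureProfile:
    """Per-category frame-proportion distributions over lesion frames."""

    proportions: dict[str, dict[str, float]]
    n_lesion_frames: int

    def __post_init__(self) -> None:
        if self.n_lesion_frames < 1:
            raise ValueError("need at least one lesion frame")
        for cat, dist in self.proportions.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{cat} proportions sum to {total}, not 1")


@dataclass
class ScoreTable:
    weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_WEIGHTS.items()})
    proportion_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    rank_thresholds: list[tuple[float, str]] = field(
        default_factory=lambda: list(_DEFAULT_RANKS))
    top_category: str = "5"
    malignancy_cut: str = "4b"
    simple_cyst_override: bool = True

    def validate(self) -> None:
        bounds = [b for b, _ in self.rank_thresholds]
        cats = [c for _, c in self.rank_thresholds] + [self.top_category]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("rank threshold bounds must strictly increase")
        order = [BIRADS_ORDER.index(c) for c in cats]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("rank threshold categories must strictly increase")
        if self.malignancy_cut not in BIRADS_ORDER:
            raise ValueError(f"unknown malignancy cut {self.malignancy_cut!r}")

    def category_for(self, score: float) -> str:
        for bound, cat in self.rank_thresholds:
            if score <= bound:
                return cat
        return self.top_category

    def is_malignant(self, category: str) -> bool:
        return BIRADS_ORDER.index(category) >= BIRADS_ORDER.index(
            self.malignancy_cut)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights,
            "proportion_thresholds": self.proportion_thresholds,
            "rank_thresholds": [[float(b), str(c)]
                                for b, c in self.rank_thresholds],
            "top_category": self.top_category,
            "malignancy_cut": self.malignancy_cut,
            "simple_cyst_override": self.simple_cyst_override,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreTable":
        kwargs = dict(d)
        if "rank_thresholds" in kwargs:
            kwargs["rank_thresholds"] = [
                (float(b), str(c)) for b, c in kwargs["rank_thresholds"]]
        table = cls(**kwargs)
        table.validate()
        return table


@dataclass
class Assessment:
    category: str
    malignant: bool
    total_score: float
    chosen_levels: dict[str, str]
    profile: Optional[FeatureProfile] = None
    cyst_override: bool = False
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "birads": self.category,
            "malignant": self.malignant,
            "total_score": self.total_score,
            "chosen_levels": self.chosen_levels,
            "cyst_override": self.cyst_override,
            "provenance": self.provenance,
        }
        if self.profile is not None:
            d["proportions"] = self.profile.proportions
            d["n_lesion_frames"] = self.profile.n_lesion_frames
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Assessment":
        profile = None
        if "proportions" in d:
            profile = FeatureProfile(proportions=d["proportions"],
                                     n_lesion_frames=d["n_lesion_frames"])
        return cls(category=d["birads"], malignant=d["malignant"],
                   total_score=d["total_score"],
                   chosen_levels=d["chosen_levels"], profile=profile,
                   cyst_override=d.get("cyst_override", False),
                   provenance=d.get("provenance", {}))


def config_hash(*configs) -> str:
    """Stable short hash of one or more config mappings."""
    blob = json.dumps([getattr(c, "to_dict", lambda: c.__dict__)()
                       if not isinstance(c, dict) else c for c in configs],
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def aggregate_profile(frame_features: list[FrameFeatures]) -> FeatureProfile:
    """Empirical per-category level frequencies over lesion frames."""
    if not frame_features:
        raise NoLesionError("zero lesion frames")
    n = len(frame_features)
    proportions: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        counts: dict[str, int] = {}
        for ff in frame_features:
            level = getattr(ff, cat)
            counts[level] = counts.get(level, 0) + 1
        proportions[cat] = {lvl: c / n for lvl, c in counts.items()}
    return FeatureProfile(proportions=proportions, n_lesion_frames=n)


def _pick_level(cat: str, dist: dict[str, float], table: ScoreTable) -> str:
    weights = table.weights[cat]
    threshold = table.proportion_thresholds[cat]
    # levels ordered by descending weight: the most suspicious level that
    # clears the proportion threshold wins
    by_weight = sorted(weights, key=lambda l: -weights[l])
    baseline = min(weights.values())
    for level in by_weight:
        if weights[level] <= baseline:
            break  # benign baseline level(s) handled by fallback
        if dist.get(level, 0.0) >= threshold:
            return level
    if len(weights) == 2:  # binary category: below threshold -> benign level
        return by_weight[-1]
    # three-level fallback: modal level, ties broken toward the higher weight
    return max(dist, key=lambda l: (dist[l], weights.get(l, 0)))


def select_levels(profile: FeatureProfile, table: ScoreTable) -> dict[str, str]:
    """Commit each category to one level using the proportion thresholds."""
    table.validate()
    return {cat: _pick_level(cat, profile.proportions[cat], table)
            for cat in CATEGORIES}


def score_and_classify(chosen: dict[str, str], table: ScoreTable,
                       profile: Optional[FeatureProfile] = None) -> Assessment:
    """Map chosen levels through the weight/rank table to an Assessment."""
    table.validate()
    total = sum(table.weights[cat][chosen[cat]] for cat in CATEGORIES)
    override = (table.simple_cyst_override
                and chosen["echo"] == "anechoic"
                and chosen["margin"] == "circumscribed"
                and chosen["shape"] == "regular"
                and chosen["orientation"] == "parallel"
                and chosen["calcification"] == "none")
    if override:
        category = "2"
    else:
        category = table.category_for(total)
    malignant = table.is_malignant(category) and not override
    return Assessment(category=category, malignant=malignant,
                      total_score=total, chosen_levels=dict(chosen),
                      profile=profile, cyst_override=override)


def classify_video(frames, seg_config=None, feat_config=None,
                   table: Optional[ScoreTable] = None) -> Assessment:
    """Full pipeline: segment, extract, aggregate, select, score."""
    from .features import FeatureConfig, extract_all
    from .segmentation import SegConfig, segment_video

    seg_config = seg_config or SegConfig()
    feat_config = feat_config or FeatureConfig()
    table = table or ScoreTable()
    masks = segment_video(frames, seg_config)
    per_frame = [extract_all(frame, lm.mask, feat_config)
                 for frame, lm in zip(frames, masks) if lm is not None]
    if not per_frame:
        raise NoLesionError("no lesion detected in any frame")
    profile = aggregate_profile(per_frame)
    chosen = select_levels(profile, table)
    assessment = score_and_classify(chosen, table, profile=profile)
    assessment.provenance["config_hash"] = config_hash(
        seg_config.__dict__, feat_config.__dict__, table.to_dict())
    return assessment
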