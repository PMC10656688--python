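"""Synthetic breast-ultrasound sweep phantoms.

A sweep video is modelled as a linear-transducer pass through an
ellipsoidal lesion: the visible cross-section appears, grows to its
maximum at the middle of the clip, shrinks and disappears again, over a
multiplicative-speckle background.  Every rendered video carries exact
per-frame ground-truth masks and the six lexicon labels, so the
segmentation, feature-extraction and fusion stages can be exercised
without clinical data.

Conventions: 0-based (row, col) indexing; row 0 is the shallow (skin)
side, depth increases with the row index.  Geometry (masks) is a
deterministic function of the spec excluding ``seed`` and
``speckle_shape``; speckle is applied after geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "sweep_radius",
    "render_frame",
    "generate_video",
    "benign_spec",
    "malignant_spec",
    "cyst_spec",
    "level_spec",
    "FEATURE_LEVELS",
]

#: the 15 lexicon levels, keyed by category.
FEATURE_LEVELS = {
    "shape": ("regular", "irregular"),
    "orientation": ("parallel", "not_parallel"),
    "margin": ("circumscribed", "not_circumscribed"),
    "echo": ("anechoic", "homogeneous", "heterogeneous"),
    "posterior": ("none", "enhancement", "shadowing"),
    "calcification": ("none", "coarse", "punctate"),
}

#: smallest radius (px) still considered renderable
MIN_RENDER_RADIUS = 2.0

#: intensity offset of each half in the heterogeneous interior pattern
HETERO_SPLIT = 0.15


@dataclass
class PhantomSpec:
    """Full description of one synthetic sweep video."""

    image_height: int = 128
    image_width: int = 128
    n_frames: int = 24
    lesion_center: tuple[int, int] = (52, 64)
    max_radii: tuple[float, float] = (14.0, 26.0)  # (vertical, horizontal)
    shape_label: str = "regular"
    spiculation: tuple[int, float] = (8, 6.0)  # (count, amplitude px), irregular only
    orientation_label: str = "parallel"
    margin_label: str = "circumscribed"
    edge_blur_sigma: float = 5.0  # used when not_circumscribed
    interior_level: float = 0.25
    interior_pattern: str = "homogeneous"
    posterior_label: str = "none"
    posterior_gain: float = 1.0
    calcification_label: str = "none"
    calc_foci: Sequence[tuple[int, int, float, float]] = field(default_factory=list)
    background_level: float = 0.60
    speckle_shape: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_height, self.image_width
        cr, cc = self.lesion_center
        rv, rh = self.max_radii
        if rv <= 0 or rh <= 0:
            raise ValueError("max_radii must be positive")
        if not (cr - rv >= 10 and cr + rv <= h - 10
                and cc - rh >= 10 and cc + rh <= w - 10):
            raise ValueError("lesion must fit inside the image with a >=10 px margin")
        parallel = rh >= rv
        if (self.orientation_label == "parallel") != parallel:
            raise ValueError(
                "orientation_label must be consistent with max_radii aspect")
        if self.interior_pattern == "anechoic" and self.interior_level > 0.05:
            raise ValueError("anechoic interior requires interior_level <= 0.05")
        gain, lab = self.posterior_gain, self.posterior_label
        ok = ((gain > 1 and lab == "enhancement")
              or (gain < 1 and lab == "shadowing")
              or (gain == 1 and lab == "none"))
        if not ok:
            raise ValueError("posterior_gain inconsistent with posterior_label")
        for cat, levels in FEATURE_LEVELS.items():
            val = getattr(self, _LABEL_ATTR[cat])
            if val not in levels:
                raise ValueError(f"unknown {cat} level {val!r}")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")

    @property
    def labels(self) -> dict[str, str]:
        return {cat: getattr(self, _LABEL_ATTR[cat]) for cat in FEATURE_LEVELS}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesion_center"] = list(self.lesion_center)
        d["max_radii"] = list(self.max_radii)
        d["spiculation"] = list(self.spiculation)
        d["calc_foci"] = [list(f) for f in self.calc_foci]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("lesion_center", "max_radii", "spiculation"):
            if key in d:
                d[key] = tuple(d[key])
        if "calc_foci" in d:
            d["calc_foci"] = [tuple(f) for f in d["calc_foci"]]
        return cls(**d)


_LABEL_ATTR = {
    "shape": "shape_label",
    "orientation": "orientation_label",
    "margin": "margin_label",
    "echo": "_echo_label",
    "posterior": "posterior_label",
    "calcification": "calcification_label",
}


# echo label is derived from interior_pattern; expose it like the others
def _echo_label(self: PhantomSpec) -> str:
    return self.interior_pattern


PhantomSpec._echo_label = property(_echo_label)  # type: ignore[attr-defined]


@dataclass
class GroundTruth:
    """Per-frame truth for one rendered sweep video."""

    masks: list[np.ndarray]
    lesion_present: list[bool]
    labels: dict[str, str]
    areas: list[int]

    @property
    def n_lesion_frames(self) -> int:
        return int(sum(self.lesion_present))


def sweep_radius(spec: PhantomSpec, frame_index: int) -> tuple[float, float]:
    """Lesion cross-section radii at ``frame_index``.

    The sweep samples an ellipsoid at constant speed: radii scale by
    ``sqrt(max(0, 1 - ((t - t_mid) / t_half)^2))`` with
    ``t_mid = (n_frames - 1) / 2`` and ``t_half = 0.4 * n_frames``, so
    the lesion is absent at both ends of the clip and maximal in the
    middle.
    """
    n = spec.n_frames
    if not 0 <= frame_index < n:
        raise IndexError(f"frame_index {frame_index} outside [0, {n})")
    t_mid = (n - 1) / 2.0
    t_half = 0.4 * n
    scale = math.sqrt(max(0.0, 1.0 - ((frame_index - t_mid) / t_half) ** 2))
    return spec.max_radii[0] * scale, spec.max_radii[1] * scale


def _lesion_support(spec: PhantomSpec, rv: float, rh: float) -> np.ndarray:
    """Binary support of the (possibly spiculated) lesion cross-section."""
    rr, cc = np.mgrid[0:spec.image_height, 0:spec.image_width]
    dr = (rr - spec.lesion_center[0]) / rv
    dc = (cc - spec.lesion_center[1]) / rh
    rho = np.hypot(dr, dc)
    if spec.shape_label == "irregular":
        count, amp = spec.spiculation
        theta = np.arctan2(dr, dc)
        r_geo = math.sqrt(rv * rh)
        boundary = 1.0 + (amp / r_geo) * np.cos(count * theta)
    else:
        boundary = 1.0
    return rho <= boundary


def render_frame(
    spec: PhantomSpec, frame_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame plus its ground-truth mask.

    The noiseless scene is composed first (background, lesion interior
    pattern, optional margin blur, posterior band, calcific foci), then
    multiplied by unit-mean gamma speckle and clipped to [0, 1].  The
    mask is the unblurred lesion support.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    rv, rh = sweep_radius(spec, frame_index)
    present = min(rv, rh) >= MIN_RENDER_RADIUS

    ideal = np.full((h, w), spec.background_level, dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    if present:
        mask = _lesion_support(spec, rv, rh)
        interior = np.full((h, w), spec.interior_level)
        if spec.interior_pattern == "heterogeneous":
            left = np.mgrid[0:h, 0:w][1] < spec.lesion_center[1]
            interior = np.where(left,
                                spec.interior_level - HETERO_SPLIT,
                                spec.interior_level + HETERO_SPLIT)
        ideal[mask] = interior[mask]
        if spec.margin_label == "not_circumscribed":
            ideal = gaussian_filter(ideal, spec.edge_blur_sigma, mode="nearest")
        if spec.posterior_gain != 1.0:
            rows = np.nonzero(mask.any(axis=1))[0]
            cols = np.nonzero(mask.any(axis=0))[0]
            band_top = rows[-1] + 1
            band_bot = min(h, band_top + int(round(rv)))
            ideal[band_top:band_bot, cols[0]:cols[-1] + 1] *= spec.posterior_gain
        sweep_scale = rv / spec.max_radii[0]
        for fr, fc, frad, fint in spec.calc_foci:
            # focus position scales with the sweep so foci stay inside
            pr = spec.lesion_center[0] + (fr - spec.lesion_center[0]) * sweep_scale
            pc = spec.lesion_center[1] + (fc - spec.lesion_center[1]) * sweep_scale
            frr, fcc = np.mgrid[0:h, 0:w]
            focus = (frr - pr) ** 2 + (fcc - pc) ** 2 <= frad ** 2
            focus &= mask
            ideal[focus] = fint

    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=(h, w))
    frame = np.clip(ideal * speckle, 0.0, 1.0)
    return frame, mask


def generate_video(spec: PhantomSpec):
    """Render a full sweep video.

    Returns ``(FrameSequence, GroundTruth)``.  Frames are rendered from
    independent child streams of ``default_rng(spec.seed)`` so a given
    (spec, seed) pair is bit-reproducible.
    """
    from .video_io import FrameSequence

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    streams = rng.spawn(spec.n_frames)
    frames, masks, present, areas = [], [], [], []
    for t in range(spec.n_frames):
        frame, mask = render_frame(spec, t, streams[t])
        frames.append(frame)
        masks.append(mask)
        present.append(bool(mask.any()))
        areas.append(int(mask.sum()))
    seq = FrameSequence(frames=frames, source_id=f"phantom-seed{spec.seed}")
    gt = GroundTruth(masks=masks, lesion_present=present,
                     labels=spec.labels, areas=areas)
    return seq, gt


# ---------------------------------------------------------------------------
# archetype specs

def benign_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Canonical benign solid lesion: every category at its benign level."""
    return PhantomSpec(seed=seed, **overrides)


def malignant_spec(seed: int = 0) -> PhantomSpec:
    """Canonical suspicious lesion: every category at its worst level."""
    return PhantomSpec(
        lesion_center=(48, 64),
        max_radii=(26.0, 14.0),
        shape_label="irregular",
        spiculation=(8, 6.0),
        orientation_label="not_parallel",
        margin_label="not_circumscribed",
        edge_blur_sigma=5.0,
        interior_level=0.30,
        interior_pattern="heterogeneous",
        posterior_label="shadowing",
        posterior_gain=0.75,
        calcification_label="punctate",
        calc_foci=[(48, 58, 1.0, 0.95), (44, 66, 1.0, 0.95), (52, 70, 1.0, 0.95)],
        seed=seed,
    )


def cyst_spec(seed: int = 0) -> PhantomSpec:
    """Simple anechoic cyst with posterior enhancement."""
    return PhantomSpec(
        interior_level=0.02,
        interior_pattern="anechoic",
        posterior_label="enhancement",
        posterior_gain=1.5,
        seed=seed,
    )


def level_spec(category: str, level: str, seed: int = 0) -> PhantomSpec:
    """A default spec exercising exactly one lexicon level.

    Starts from the benign archetype and switches the requested
    category to ``level``; used by the label-recovery battery.
    """
    if category not in FEATURE_LEVELS:
        raise ValueError(f"unknown category {category!r}")
    if level not in FEATURE_LEVELS[category]:
        raise ValueError(f"unknown level {level!r} for category {category!r}")
    spec = benign_spec(seed=seed)
    if category == "shape":
        spec.shape_label = level
    elif category == "orientation":
        spec.orientation_label = level
        if level == "not_parallel":
            spec.max_radii = (26.0, 14.0)
            spec.lesion_center = (48, 64)
    elif category == "margin":
        spec.margin_label = level
    elif category == "echo":
        spec.interior_pattern = level
        if level == "anechoic":
            spec.interior_level = 0.02
        elif level == "heterogeneous":
            spec.interior_level = 0.30
    elif category == "posterior":
        spec.posterior_label = level
        spec.posterior_gain = {"none": 1.0, "enhancement": 1.5, "shadowing": 0.75}[level]
    elif category == "calcification":
        spec.calcification_label = level
        if level == "coarse":
            spec.calc_foci = [(50, 64, 4.0, 0.95)]
        elif level == "punctate":
            spec.calc_foci = [(50, 58, 1.0, 0.95), (48, 66, 1.0, 0.95),
                              (56, 70, 1.0, 0.95)]
    spec.validate()
    return spec
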