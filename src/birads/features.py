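"""Per-frame extraction of the six BI-RADS lexicon categories.

Each extractor maps (frame, mask) to exactly one level of its category
using classical morphological measurements; all thresholds live in
:class:`FeatureConfig` so the decision rules are fully reproducible.

Level taxonomy (15 levels over 6 categories):
  shape          regular | irregular
  orientation    parallel | not_parallel
  margin         circumscribed | not_circumscribed
  echo           anechoic | homogeneous | heterogeneous
  posterior      none | enhancement | shadowing
  calcification  none | coarse | punctate
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure, morphology

__all__ = [
    "FrameFeatures",
    "FeatureConfig",
    "extract_shape",
    "extract_orientation",
    "extract_margin",
    "extract_echo",
    "extract_posterior",
    "extract_calcification",
    "extract_all",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameFeatures:
    shape: str
    orientation: str
    margin: str
    echo: str
    posterior: str
    calcification: str

    def as_dict(self) -> dict[str, str]:
        return asdict(self)


@dataclass
class FeatureConfig:
    circularity_min: float = 0.70
    solidity_min: float = 0.90
    smoothness_max: float = 1.15
    fourier_harmonics: int = 10
    edge_gradient_min: float = 0.03  # intensity/px, on the speckle-suppressed frame
    anechoic_max: float = 0.08
    cv_homog_max: float = 0.35
    posterior_delta: float = 0.15
    calc_z: float = 4.0  # focus threshold in interior SDs
    calc_abs_min: float = 0.10  # absolute intensity margin over interior median
    calc_min_px: int = 2
    calc_coarse_px: int = 12
    calc_extra_erosion: int = 2  # keeps bright boundary leakage out of foci
    interior_erosion: int = 3
    smoothing_sigma: float = 2.0  # speckle suppression before echo/margin stats

    def validate(self) -> None:
        vals = {k: v for k, v in asdict(self).items()}
        for k, v in vals.items():
            if v <= 0:
                raise ValueError(f"{k} must be positive")
        if self.circularity_min > 1:
            raise ValueError("circularity_min must be <= 1")


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    return m


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _main_contour(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found")
    return max(contours, key=len)


def _perimeter(contour: np.ndarray) -> float:
    d = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _fourier_smooth(contour: np.ndarray, harmonics: int) -> np.ndarray:
    """Low-pass the closed contour, keeping ``harmonics`` Fourier terms."""
    z = contour[:, 1] + 1j * contour[:, 0]
    # resample uniformly by arc length so the FFT sees even spacing
    d = np.abs(np.diff(z, append=z[:1]))
    s = np.concatenate([[0.0], np.cumsum(d)])[:-1]
    total = s[-1] + d[-1]
    n = 256
    grid = np.linspace(0, total, n, endpoint=False)
    zu = np.interp(grid, s, z.real) + 1j * np.interp(grid, s, z.imag)
    spec = np.fft.fft(zu)
    keep = np.zeros(n, dtype=bool)
    keep[: harmonics + 1] = True
    keep[-harmonics:] = True
    smooth = np.fft.ifft(np.where(keep, spec, 0))
    return np.column_stack([smooth.imag, smooth.real])


def extract_shape(mask, config: FeatureConfig) -> tuple[str, dict]:
    """regular iff the lesion is both round-ish and convex-ish.

    circularity = 4*pi*A / P^2, solidity = A / convex-hull area.
    """
    m = _as_bool(mask)
    props = measure.regionprops(m.astype(int))[0]
    # Crofton perimeter: the classic chain-code estimate overestimates a
    # digitized circle by ~5%, biasing circularity low
    perimeter = measure.perimeter_crofton(m, directions=4)
    circularity = 4 * math.pi * props.area / perimeter ** 2 if perimeter > 0 else 1.0
    solidity = props.solidity
    level = ("regular"
             if circularity >= config.circularity_min
             and solidity >= config.solidity_min
             else "irregular")
    return level, {"circularity": float(circularity), "solidity": float(solidity)}


def extract_orientation(mask, config: FeatureConfig) -> tuple[str, dict]:
    """parallel iff the bounding box is at least as wide as it is tall."""
    m = _as_bool(mask)
    r0, c0, r1, c1 = _bbox(m)
    width, height = c1 - c0, r1 - r0
    level = "parallel" if width >= height else "not_parallel"
    return level, {"width": width, "height": height}


def extract_margin(frame, mask, config: FeatureConfig) -> tuple[str, dict]:
    """circumscribed iff the boundary is smooth AND the edge is sharp.

    smoothness is the ratio of the contour perimeter to the perimeter
    of its low-order Fourier reconstruction; edge sharpness is the mean
    gradient magnitude (after light speckle suppression) in a ~5 px
    band straddling the boundary.
    """
    m = _as_bool(mask)
    r0, c0, r1, c1 = _bbox(m)
    if r0 == 0 or c0 == 0 or r1 == m.shape[0] or c1 == m.shape[1]:
        raise ValueError("mask touches the frame border; gradient band undefined")
    contour = _main_contour(m)
    smoothness = _perimeter(contour) / _perimeter(
        _fourier_smooth(contour, config.fourier_harmonics))
    smooth_frame = gaussian_filter(np.asarray(frame, dtype=float),
                                   config.smoothing_sigma)
    gr, gc = np.gradient(smooth_frame)
    grad = np.hypot(gr, gc)
    band = morphology.dilation(m, morphology.disk(2)) \
        & ~morphology.erosion(m, morphology.disk(3))
    mean_grad = float(grad[band].mean())
    level = ("circumscribed"
             if smoothness <= config.smoothness_max
             and mean_grad >= config.edge_gradient_min
             else "not_circumscribed")
    return level, {"smoothness": float(smoothness),
                   "mean_edge_gradient": mean_grad}


def _interior(mask: np.ndarray, radius: int) -> np.ndarray:
    interior = morphology.erosion(mask, morphology.disk(radius))
    if not interior.any():
        raise ValueError("interior empty after erosion")
    return interior


def extract_echo(frame, mask, config: FeatureConfig) -> tuple[str, dict]:
    """anechoic / homogeneous / heterogeneous from interior statistics.

    Statistics are taken on the eroded interior of a speckle-suppressed
    copy of the frame, so the coefficient of variation reflects tissue
    structure rather than speckle grain.
    """
    m = _as_bool(mask)
    interior = _interior(m, config.interior_erosion)
    smooth = gaussian_filter(np.asarray(frame, dtype=float),
                             config.smoothing_sigma)
    vals = smooth[interior]
    mean = float(vals.mean())
    cv = float(vals.std() / mean) if mean > 0 else float("inf")
    if mean <= config.anechoic_max:
        level = "anechoic"
    elif cv <= config.cv_homog_max:
        level = "homogeneous"
    else:
        level = "heterogeneous"
    return level, {"interior_mean": mean, "cv": cv}


def extract_posterior(frame, mask, config: FeatureConfig) -> tuple[str, dict]:
    """Compare the band directly beneath the lesion with its flanks.

    band_ratio = mean(band) / mean(flanks); enhancement when the band
    is brighter by ``posterior_delta``, shadowing when darker.
    """
    m = _as_bool(mask)
    frame = np.asarray(frame, dtype=float)
    r0, c0, r1, c1 = _bbox(m)
    band_h = max(1, (r1 - r0) // 2)
    if r1 + band_h > frame.shape[0]:
        raise ValueError("posterior band extends past the image bottom")
    band = frame[r1:r1 + band_h, c0:c1]
    half_w = max(1, (c1 - c0) // 2)
    left = frame[r1:r1 + band_h, max(0, c0 - half_w):c0]
    right = frame[r1:r1 + band_h, c1:min(frame.shape[1], c1 + half_w)]
    flank_vals = np.concatenate([left.ravel(), right.ravel()])
    if flank_vals.size == 0:
        raise ValueError("no flank pixels available for the posterior band")
    ratio = float(band.mean() / flank_vals.mean())
    if ratio >= 1 + config.posterior_delta:
        level = "enhancement"
    elif ratio <= 1 - config.posterior_delta:
        level = "shadowing"
    else:
        level = "none"
    return level, {"band_ratio": ratio}


def _mad_sigma(vals: np.ndarray) -> float:
    """SD estimate from the median absolute deviation (normal scale)."""
    return 1.4826 * float(np.median(np.abs(vals - np.median(vals))))


def extract_calcification(frame, mask, config: FeatureConfig) -> tuple[str, dict]:
    """Detect echogenic foci inside the lesion.

    Candidates are interior pixels that stand out by ``calc_z``
    interior SDs, either in raw intensity or in a 7-px white-top-hat
    response (the top-hat catches punctate foci, the raw rule larger
    deposits the top-hat suppresses).  Components smaller than
    ``calc_min_px`` are discarded; any component of at least
    ``calc_coarse_px`` pixels makes the call coarse, any remaining
    component punctate.
    """
    m = _as_bool(mask)
    frame = np.asarray(frame, dtype=float)
    try:
        interior = _interior(m, config.interior_erosion + config.calc_extra_erosion)
    except ValueError:
        interior = _interior(m, config.interior_erosion)
    tophat = morphology.white_tophat(frame, morphology.disk(3))
    vals = frame[interior]
    th_vals = tophat[interior]
    # robust centre/scale: bright foci would inflate the plain mean/SD;
    # the absolute floor stops speckle grain in near-anechoic interiors
    # (where the MAD is tiny) from masquerading as foci
    raw_cut = np.median(vals) + max(config.calc_z * _mad_sigma(vals),
                                    config.calc_abs_min)
    th_cut = np.median(th_vals) + max(config.calc_z * _mad_sigma(th_vals),
                                      config.calc_abs_min)
    candidates = interior & ((frame > raw_cut) | (tophat > th_cut))
    # speckle dips fragment a genuine focus; a 1-px closing reassembles it
    candidates = morphology.closing(candidates, morphology.disk(1)) & interior
    labels = measure.label(candidates, connectivity=2)
    sizes = [int(s) for s in np.bincount(labels.ravel())[1:]
             if s >= config.calc_min_px]
    if any(s >= config.calc_coarse_px for s in sizes):
        level = "coarse"
    elif sizes:
        level = "punctate"
    else:
        level = "none"
    return level, {"foci_sizes": sorted(sizes, reverse=True)}


def extract_all(frame, mask, config: FeatureConfig | None = None) -> FrameFeatures:
    """Run all six extractors on one frame + mask."""
    config = config or FeatureConfig()
    config.validate()
    shape, _ = extract_shape(mask, config)
    orientation, _ = extract_orientation(mask, config)
    margin, _ = extract_margin(frame, mask, config)
    echo, _ = extract_echo(frame, mask, config)
    try:
        posterior, _ = extract_posterior(frame, mask, config)
    except ValueError:
        logger.warning("posterior band unavailable; falling back to 'none'")
        posterior = "none"
    calcification, _ = extract_calcification(frame, mask, config)
    return FrameFeatures(shape=shape, orientation=orientation, margin=margin,
                         echo=echo, posterior=posterior,
                         calcification=calcification)
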