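"""Lesion frame selection and segmentation, plus pure network operations.

The default runtime engine is classical: Gaussian smoothing, dark-object
thresholding (lesions are hypoechoic relative to the surrounding
tissue), morphological clean-up and largest-component selection.  The
module also exposes the attention weighting, the detection losses and
the overlap metrics as standalone, unit-testable functions; the engine
interface (frames in, masks out) lets a learned segmenter be plugged in
without touching the rest of the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter
from skimage import measure, morphology
from skimage import segmentation as skseg
from skimage.filters import threshold_otsu

__all__ = [
    "SegConfig",
    "LesionMask",
    "equalize",
    "segment_frame",
    "segment_video",
    "simam_weights",
    "bce_loss",
    "focal_loss",
    "ciou_loss",
    "overlap_metrics",
    "detection_counts",
]

logger = logging.getLogger(__name__)

_EPS = 1e-7


@dataclass
class SegConfig:
    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu_dark"  # or "fixed"
    fixed_threshold: float = 0.5
    invert: bool = False  # fixed-threshold polarity for hyperechoic lesions
    open_radius: int = 2
    close_radius: int = 3
    min_area: int = 64
    min_contrast: float = 0.08
    simam_lambda: float = 1e-4
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25

    def validate(self) -> None:
        if self.open_radius < 0 or self.close_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.simam_lambda <= 0:
            raise ValueError("simam_lambda must be positive")
        if self.threshold_method not in ("otsu_dark", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


@dataclass
class LesionMask:
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)
    area: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LesionMask":
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        if rows.size == 0:
            raise ValueError("empty mask")
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        return cls(mask=mask.astype(bool), bbox=bbox, area=int(mask.sum()))


def equalize(frame: np.ndarray) -> np.ndarray:
    """Histogram equalization on [0, 1] intensities (rank preserving)."""
    flat = np.asarray(frame, dtype=float).ravel()
    _, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if counts.size == 1:  # constant frame: keep it constant, not 1.0
        return np.asarray(frame, dtype=float).copy()
    cdf = np.cumsum(counts) / flat.size  # right-continuous empirical CDF
    return cdf[inverse].reshape(frame.shape)


def _largest_component(binary: np.ndarray) -> Optional[np.ndarray]:
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def _grow_hypoechoic(comp: np.ndarray, smooth: np.ndarray,
                     min_contrast: float) -> np.ndarray:
    """Hysteresis completion of a partially captured lesion.

    Otsu can exclude the lighter part of a heterogeneous interior; grow
    the component into connected pixels that are still darker than the
    background by ``min_contrast``.
    """
    bg_mean = smooth[~comp].mean()
    low = (smooth < bg_mean - min_contrast) | comp
    grown = morphology.reconstruction(comp, low, method="dilation").astype(bool)
    return comp if _touches_border(grown) else grown


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any()
                or mask[:, 0].any() or mask[:, -1].any())


def _trim_posterior_tail(comp: np.ndarray, smooth: np.ndarray,
                         min_contrast: float) -> np.ndarray:
    """Detach an acoustic-shadow tail merged into the lesion component.

    A posterior shadow is darker than background but lighter than the
    lesion, and hangs strictly below it.  Re-threshold within the
    component; when the bright sub-region is genuinely lighter, drop
    its pixels that lie below the dark core in their own column.
    Lateral or surrounding bright pixels (blur halo, heterogeneous
    halves) are untouched.
    """
    vals = smooth[comp]
    if vals.size < 2 or np.ptp(vals) == 0:
        return comp
    t2 = threshold_otsu(vals)
    dark = comp & (smooth < t2)
    bright = comp & ~dark
    if not dark.any() or not bright.any():
        return comp
    if smooth[bright].mean() - smooth[dark].mean() < min_contrast:
        return comp
    core = _largest_component(dark)
    rows = np.arange(comp.shape[0])[:, None]
    has_core = core.any(axis=0)
    # bottom-most core row per column (columns without core keep everything)
    core_bottom = np.where(has_core,
                           (core * rows).max(axis=0), comp.shape[0])
    tail = bright & (rows > core_bottom[None, :])
    if not tail.any():
        return comp
    trimmed = comp & ~tail
    biggest = _largest_component(trimmed)
    return biggest if biggest is not None else comp


def segment_frame(frame: np.ndarray, config: SegConfig) -> Optional[LesionMask]:
    """Segment the dominant hypoechoic lesion in one frame.

    Returns ``None`` when no candidate passes both the ``min_area`` and
    ``min_contrast`` gates (a lesion-free frame, not an error).
    """
    config.validate()
    smooth = gaussian_filter(frame.astype(float), config.smoothing_sigma)
    if config.threshold_method == "otsu_dark":
        thresh = threshold_otsu(smooth)
        binary = smooth < thresh
    else:
        binary = (smooth > config.fixed_threshold) if config.invert \
            else (smooth < config.fixed_threshold)
    if config.open_radius > 0:
        binary = morphology.opening(
            binary, morphology.disk(config.open_radius))
    if config.close_radius > 0:
        binary = morphology.closing(
            binary, morphology.disk(config.close_radius))
    # a properly acquired lesion is centred in view; candidates touching
    # the frame border are background speckle or truncated anatomy
    binary = skseg.clear_border(binary)
    comp = _largest_component(binary)
    if comp is None or comp.sum() < config.min_area:
        return None
    # bright internal structures (calcific foci) punch holes in a
    # dark-object threshold; the lesion support has none
    comp = ndi.binary_fill_holes(comp)
    if not config.invert:
        comp = _grow_hypoechoic(comp, smooth, config.min_contrast)
        comp = _trim_posterior_tail(comp, smooth, config.min_contrast)
        # regularize the grown/trimmed boundary; growth follows speckle
        # grain and would otherwise fake an irregular contour
        comp = morphology.closing(comp, morphology.disk(config.close_radius))
        if config.open_radius > 0:
            comp = morphology.opening(comp, morphology.disk(config.open_radius))
        comp = _largest_component(comp)
        if comp is None:
            return None
    if comp.sum() < config.min_area:
        return None
    contrast = float(smooth[~comp].mean() - smooth[comp].mean())
    if config.invert:
        contrast = -contrast
    if contrast < config.min_contrast:
        return None
    return LesionMask.from_mask(comp)


def segment_video(frames, config: SegConfig) -> list[Optional[LesionMask]]:
    """Per-frame segmentation with a temporal consistency pass.

    Isolated single-frame detections flanked by absences are dropped —
    a real lesion swept at constant speed persists across neighbouring
    frames.
    """
    results = [segment_frame(f, config) for f in frames]
    cleaned = list(results)
    for i, res in enumerate(results):
        if res is None:
            continue
        prev_absent = i == 0 or results[i - 1] is None
        next_absent = i == len(results) - 1 or results[i + 1] is None
        if prev_absent and next_absent:
            cleaned[i] = None
    return cleaned


def simam_weights(stack: np.ndarray, lam: float = 1e-4) -> np.ndarray:
    """Parameter-free attention: energy-derived weights times the input.

    Per channel, each unit t gets energy
    ``e_t = 4 (s^2 + lam) / ((t - mu)^2 + 2 s^2 + 2 lam)`` with mu the
    channel mean and s^2 the channel variance (sum of squared
    deviations over n-1, n = pixels per channel).  The output is
    ``sigmoid(1 / e_t)`` Hadamard-multiplied into the input, so salient
    (far-from-mean) units are enhanced.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    x = np.asarray(stack, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected a (channels, rows, cols) stack")
    n = x.shape[1] * x.shape[2] - 1
    mu = x.mean(axis=(1, 2), keepdims=True)
    d2 = (x - mu) ** 2
    var = d2.sum(axis=(1, 2), keepdims=True) / max(n, 1)
    inv_energy = d2 / (4.0 * (var + lam)) + 0.5
    weights = 1.0 / (1.0 + np.exp(-inv_energy))
    out = weights * x
    return out[0] if squeeze else out


def _clamp_prob(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        logger.debug("probability clamped to [%g, %g]", _EPS, 1 - _EPS)
    return np.clip(p, _EPS, 1 - _EPS)


def bce_loss(p, y):
    """Binary cross-entropy, elementwise."""
    p = _clamp_prob(p)
    y = np.asarray(y, dtype=float)
    out = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(out) if out.ndim == 0 else out


def focal_loss(p, y, gamma: float = 2.0, alpha: float = 0.25):
    """Focal loss; reduces to ``alpha * bce`` at gamma=0, alpha_t = alpha."""
    p = _clamp_prob(p)
    y = np.asarray(y, dtype=float)
    p_t = np.where(y == 1, p, 1 - p)
    a_t = np.where(y == 1, alpha, 1 - alpha)
    out = -a_t * (1 - p_t) ** gamma * np.log(p_t)
    return float(out) if out.ndim == 0 else out


def _box_iou(a, b) -> float:
    r0 = max(a[0], b[0]); c0 = max(a[1], b[1])
    r1 = min(a[2], b[2]); c1 = min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def ciou_loss(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Complete-IoU loss between two half-open (r0, c0, r1, c1) boxes.

    ``1 - IoU + rho^2/c^2 + alpha*v`` where rho is the centre distance,
    c the enclosing-box diagonal and v the aspect-ratio penalty
    ``(4/pi^2) (atan(w_a/h_a) - atan(w_b/h_b))^2``.
    """
    for box in (box_a, box_b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(f"degenerate box {box}")
    iou = _box_iou(box_a, box_b)
    ca = ((box_a[0] + box_a[2]) / 2, (box_a[1] + box_a[3]) / 2)
    cb = ((box_b[0] + box_b[2]) / 2, (box_b[1] + box_b[3]) / 2)
    rho2 = (ca[0] - cb[0]) ** 2 + (ca[1] - cb[1]) ** 2
    er0 = min(box_a[0], box_b[0]); ec0 = min(box_a[1], box_b[1])
    er1 = max(box_a[2], box_b[2]); ec1 = max(box_a[3], box_b[3])
    c2 = (er1 - er0) ** 2 + (ec1 - ec0) ** 2
    wa, ha = box_a[3] - box_a[1], box_a[2] - box_a[0]
    wb, hb = box_b[3] - box_b[1], box_b[2] - box_b[0]
    v = (4 / math.pi ** 2) * (math.atan(wa / ha) - math.atan(wb / hb)) ** 2
    alpha = v / (1 - iou + v) if v > 0 else 0.0
    return 1.0 - iou + rho2 / c2 + alpha * v


def overlap_metrics(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """(Dice, IoU) of two same-shape binary masks.

    Both-empty is defined as perfect agreement, (1, 1).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    inter = np.logical_and(a, b).sum()
    sa, sb = a.sum(), b.sum()
    if sa == 0 and sb == 0:
        return 1.0, 1.0
    dice = 2 * inter / (sa + sb)
    iou = inter / (sa + sb - inter)
    return float(dice), float(iou)


def detection_counts(predictions, truths, iou_cut: float = 0.5):
    """Frame-level detection (precision, recall, specificity).

    ``predictions`` and ``truths`` are parallel lists of masks or
    ``None``.  A predicted frame is a TP when the true mask is present
    and IoU >= ``iou_cut``; truly lesion-free frames predicted absent
    are TNs (the negative class is lesion-free frames).
    """
    if not 0 < iou_cut < 1:
        raise ValueError("iou_cut must be in (0, 1)")
    tp = fp = fn = tn = 0
    for pred, truth in zip(predictions, truths, strict=True):
        pred_mask = getattr(pred, "mask", pred)
        truth_present = truth is not None and np.asarray(truth).any()
        pred_present = pred_mask is not None and np.asarray(pred_mask).any()
        if truth_present and pred_present:
            _, iou = overlap_metrics(pred_mask, truth)
            if iou >= iou_cut:
                tp += 1
            else:
                fn += 1  # detected something, but not the lesion
        elif truth_present:
            fn += 1
        elif pred_present:
            fp += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return precision, recall, specificity
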