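"""Reading and writing sweep videos, masks, reports and rating tables.

The neutral on-disk carrier for a video is a directory of zero-padded
8-bit PNG frames (``frame_0000.png`` ...), read in lexicographic order.
AVI/MP4 containers are accepted when an imageio video plugin (ffmpeg)
is available in the environment; frame directories never need one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v2 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence",
    "RatingRecord",
    "ORDINAL_ENCODING",
    "read_video",
    "write_frames",
    "read_ratings",
    "write_report",
    "read_report",
]

#: BI-RADS category -> ordinal rank used by the ROC machinery
ORDINAL_ENCODING = {"2": 1, "3": 2, "4a": 3, "4b": 4, "4c": 5, "5": 6}

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered grayscale frames of one sweep video."""

    frames: list[np.ndarray]
    source_id: str = ""
    fps: Optional[float] = None
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameSequence requires at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {shape}")
            if f.min() < 0 or f.max() > 1:
                raise ValueError(f"frame {i} intensities outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass
class RatingRecord:
    """One lesion's truth plus the BI-RADS ratings of several raters."""

    lesion_id: str
    truth: Optional[str] = None  # "benign" / "malignant"
    ratings: dict[str, str] = field(default_factory=dict)  # rater -> category
    features: dict[str, str] = field(default_factory=dict)

    def ordinal(self, rater: str) -> int:
        return ORDINAL_ENCODING[self.ratings[rater]]


def _to_gray01(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return np.clip(arr / scale, 0.0, 1.0)


def read_video(path: str | Path, fps: Optional[float] = None) -> FrameSequence:
    """Read a video from a frame directory or an AVI/MP4 container.

    Directory frames are taken in lexicographic filename order, so
    names must be zero-padded.  Frames are converted to grayscale via
    luma weights and rescaled to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() == ".png" and not p.name.startswith("mask"))
        if not files:
            raise ValueError(f"no PNG frames found in {path}")
        frames = [_to_gray01(iio.imread(p)) for p in files]
    else:
        try:
            reader = iio.get_reader(str(path))
        except Exception as exc:  # pragma: no cover - plugin availability
            raise ValueError(
                f"cannot open video container {path}; install an imageio "
                f"video plugin or pass a PNG frame directory ({exc})") from exc
        frames = [_to_gray01(im) for im in reader]
        reader.close()
        if not frames:
            raise ValueError(f"zero frames in {path}")
    return FrameSequence(frames=frames, source_id=str(path), fps=fps)


def write_frames(seq: FrameSequence, out_dir: str | Path,
                 prefix: str = "frame") -> list[Path]:
    """Write the sequence as 8-bit PNGs; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(seq):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (np.clip(frame, 0, 1) * 255).round().astype(np.uint8))
        paths.append(p)
    return paths


_RATER_COLUMNS = ("rating_auto", "rating_expA", "rating_expB",
                  "rating_junA", "rating_junB")


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Parse a CSV rating table into :class:`RatingRecord` objects.

    Required columns: ``lesion_id``; optional: ``truth`` and any of the
    rater columns, whose values must be BI-RADS tokens 2/3/4a/4b/4c/5.
    """
    df = pd.read_csv(path, dtype=str)
    if "lesion_id" not in df.columns:
        raise ValueError("ratings CSV must have a lesion_id column")
    rater_cols = [c for c in df.columns if c in _RATER_COLUMNS]
    feature_cols = [c for c in df.columns
                    if c not in rater_cols and c not in ("lesion_id", "truth")]
    records = []
    for idx, row in df.iterrows():
        truth = row.get("truth")
        if isinstance(truth, str):
            truth = truth.strip()
            if truth not in ("benign", "malignant"):
                raise ValueError(f"row {idx}: unknown truth token {truth!r}")
        else:
            truth = None
        ratings = {}
        for col in rater_cols:
            val = row[col]
            if not isinstance(val, str) or not val.strip():
                continue
            val = val.strip()
            if val not in ORDINAL_ENCODING:
                raise ValueError(
                    f"row {idx}: unknown BI-RADS token {val!r} in {col}")
            ratings[col.removeprefix("rating_")] = val
        features = {c: row[c] for c in feature_cols
                    if isinstance(row[c], str) and row[c].strip()}
        records.append(RatingRecord(lesion_id=str(row["lesion_id"]),
                                    truth=truth, ratings=ratings,
                                    features=features))
    return records


def write_report(assessment, path: str | Path) -> Path:
    """Serialize an :class:`~birads.fusion.Assessment` to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(assessment.to_dict(), fh, indent=2, sort_keys=True)
    return path


def read_report(path: str | Path):
    """Round-trip a report written by :func:`write_report`."""
    from .fusion import Assessment

    with open(path) as fh:
        return Assessment.from_dict(json.load(fh))
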