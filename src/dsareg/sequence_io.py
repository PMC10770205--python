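"""I/O and projection for DSA frame sequences.

A digital subtraction angiography acquisition is an ordered stack of 2D
frames in which contrast-filled vessels appear *dark* on a bright background.
This module reads sequences from multi-frame DICOM (XA) or directories of
PNG/TIFF frames, min-max normalizes intensities to [0, 1] per sequence, and
collapses a sequence into its minimum intensity projection (minIP) — the
per-pixel minimum over frames, which shows every vessel that opacified at any
time and is the working image for registration.

Manual point annotations travel as CSV (``image_id,label,x,y``) or JSON;
labels shared between a pre and a post image define point correspondences.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .transform_models import CorrespondenceSet, CorrespondenceSource


class View(str, Enum):
    AP = "ap"
    LATERAL = "lateral"


class Phase(str, Enum):
    PRE_EVT = "pre"
    POST_EVT = "post"


class SequenceFormat(str, Enum):
    DICOM = "dicom"
    IMAGE_STACK = "image_stack"


@dataclass
class DSASequence:
    """Ordered stack of same-shape 2D frames with view/phase metadata."""

    frames: np.ndarray  # (T, H, W) float in [0, 1]
    view: View = View.AP
    phase: Phase = Phase.PRE_EVT
    pixel_spacing_mm: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) stack")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame values must lie in [0, 1]")
        if self.pixel_spacing_mm is not None:
            if min(self.pixel_spacing_mm) <= 0:
                raise ValueError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MinIPImage:
    """Per-pixel minimum over a sequence's frames."""

    pixels: np.ndarray  # (H, W) float in [0, 1]
    view: View = View.AP
    phase: Phase = Phase.PRE_EVT
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("minIP must be a 2D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_intensities(frames: np.ndarray) -> np.ndarray:
    """Min-max normalize a frame stack to [0, 1] over the whole sequence.

    A constant sequence has an undefined rescale and maps to all zeros.
    """
    frames = np.asarray(frames, dtype=float)
    lo, hi = frames.min(), frames.max()
    if hi - lo < 1e-12:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


_FRAME_EXTS = (".png", ".tif", ".tiff")


def load_sequence(
    path: str | Path,
    format: SequenceFormat | str | None = None,
    view: View = View.AP,
    phase: Phase = Phase.PRE_EVT,
    source_id: str | None = None,
) -> DSASequence:
    """Read a DSA sequence from multi-frame DICOM or a directory of frames.

    Frames are ordered by DICOM frame index or lexical filename order, and
    intensities are min-max normalized per sequence.  Only pixel data and
    pixel spacing are consumed from DICOM; all other tags are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if format is None:
        format = SequenceFormat.DICOM if path.is_file() else SequenceFormat.IMAGE_STACK
    format = SequenceFormat(format)

    spacing = None
    if format is SequenceFormat.DICOM:
        frames, spacing = _read_dicom_frames(path)
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS)
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        raw = [np.asarray(iio.imread(f), dtype=float) for f in files]
        shapes = {a.shape for a in raw}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        if raw[0].ndim != 2:
            raise ValueError("frames must be single-channel 2D images")
        frames = np.stack(raw)

    return DSASequence(
        frames=normalize_intensities(frames),
        view=view,
        phase=phase,
        pixel_spacing_mm=spacing,
        source_id=source_id if source_id is not None else path.stem,
    )


def _read_dicom_frames(path: Path):
    import pydicom

    if path.is_file():
        ds = pydicom.dcmread(path)
        frames = np.asarray(ds.pixel_array, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        elif frames.ndim != 3:
            raise ValueError(f"unsupported DICOM pixel array shape {frames.shape}")
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
        if not files:
            raise ValueError(f"no .dcm files in {path}")
        ds = None
        raw = []
        for f in files:
            ds = pydicom.dcmread(f)
            raw.append(np.asarray(ds.pixel_array, dtype=float))
        shapes = {a.shape for a in raw}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
        frames = np.stack(raw)
    spacing = None
    for tag in ("PixelSpacing", "ImagerPixelSpacing"):
        val = getattr(ds, tag, None)
        if val is not None:
            spacing = (float(val[0]), float(val[1]))
            break
    return frames, spacing


def save_sequence(seq: DSASequence, out_dir: str | Path, bit_depth: int = 16) -> list[Path]:
    """Write a sequence as zero-padded 16-bit (or 8-bit) PNG frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        scale, dtype = 65535, np.uint16
    elif bit_depth == 8:
        scale, dtype = 255, np.uint8
    else:
        raise ValueError("bit_depth must be 8 or 16")
    paths = []
    for i, frame in enumerate(seq.frames):
        p = out_dir / f"frame_{i:04d}.png"
        iio.imwrite(p, np.round(np.clip(frame, 0, 1) * scale).astype(dtype))
        paths.append(p)
    return paths


def compute_minip(seq: DSASequence, frame_range: tuple[int, int] | None = None) -> MinIPImage:
    """Minimum intensity projection over ``frame_range`` (half-open, 0-based).

    The default uses all frames, so every opacified vessel contributes; a
    sub-range restricts the projection to a chosen contrast phase.
    """
    if frame_range is None:
        lo, hi = 0, seq.n_frames
    else:
        lo, hi = frame_range
    if not (0 <= lo < hi <= seq.n_frames):
        raise ValueError(f"empty or out-of-range frame_range {frame_range} for T={seq.n_frames}")
    return MinIPImage(
        pixels=seq.frames[lo:hi].min(axis=0),
        view=seq.view,
        phase=seq.phase,
        source_id=seq.source_id,
    )


def save_minip(img: MinIPImage, path: str | Path) -> Path:
    """Write a minIP as 16-bit PNG or float TIFF, chosen by file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, np.round(np.clip(img.pixels, 0, 1) * 65535).astype(np.uint16))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels.astype(np.float32))
    else:
        raise ValueError(f"unsupported minIP extension {path.suffix}")
    return path


def load_minip(path: str | Path, **meta) -> MinIPImage:
    path = Path(path)
    arr = np.asarray(iio.imread(path), dtype=float)
    if path.suffix.lower() == ".png":
        arr = arr / 65535.0
    return MinIPImage(pixels=arr, **meta)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Labelled points per image; shared labels across images define pairs."""

    points: pd.DataFrame  # columns image_id, label, x, y

    COLUMNS = ("image_id", "label", "x", "y")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.points, columns=list(self.COLUMNS))
        df = df.astype({"image_id": str, "label": str, "x": float, "y": float})
        dup = df.duplicated(subset=["image_id", "label"])
        if dup.any():
            bad = df.loc[dup, ["image_id", "label"]].iloc[0]
            raise ValueError(f"duplicate label {bad.label!r} for image {bad.image_id!r}")
        self.points = df.reset_index(drop=True)

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.points["image_id"].unique())

    def for_image(self, image_id: str) -> pd.DataFrame:
        return self.points[self.points["image_id"] == str(image_id)]

    def validate_bounds(self, image_id: str, shape: tuple[int, int]) -> None:
        h, w = shape
        pts = self.for_image(image_id)
        bad = pts[(pts.x < 0) | (pts.x > w - 1) | (pts.y < 0) | (pts.y > h - 1)]
        if not bad.empty:
            r = bad.iloc[0]
            raise ValueError(
                f"annotation {r.label!r} at ({r.x}, {r.y}) outside {w}x{h} image {image_id!r}"
            )


def load_annotations(path: str | Path) -> AnnotationSet:
    """Read annotations from CSV (``image_id,label,x,y``) or equivalent JSON."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such annotation file: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(records, columns=list(AnnotationSet.COLUMNS))
    else:
        df = pd.read_csv(path)
        missing = set(AnnotationSet.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    return AnnotationSet(points=df[list(AnnotationSet.COLUMNS)])


def save_annotations(ann: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(ann.points.to_dict(orient="records"), indent=1))
    else:
        ann.points.to_csv(path, index=False)
    return path


def pair_correspondences(ann: AnnotationSet, pre_id: str, post_id: str) -> CorrespondenceSet:
    """Pair pre/post annotations by shared label (moving = pre, fixed = post).

    Labels present on only one side are dropped; order is deterministic
    (sorted by label).  An empty intersection yields an empty set.
    """
    pre = ann.for_image(pre_id).set_index("label")
    post = ann.for_image(post_id).set_index("label")
    shared = sorted(set(pre.index) & set(post.index))
    moving = pre.loc[shared, ["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)
    fixed = post.loc[shared, ["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)
    return CorrespondenceSet(moving, fixed, labels=list(shared),
                             source=CorrespondenceSource.MANUAL)
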