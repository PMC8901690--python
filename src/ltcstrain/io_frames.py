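"""Echocardiogram cine I/O.

Reads multi-frame ultrasound DICOM files and ordered PNG/TIFF image stacks
into a :class:`FrameSequence` — an ordered stack of grayscale frames with
the acquisition frame interval (seconds per frame) and optional pixel
spacing.  Frame indexing is 0-based, ranges are half-open, and pixel
coordinates are (x=column, y=row) with y increasing downward.  Intensities
are rescaled to [0, 1] by dividing by the dtype maximum (not the observed
maximum), preserving inter-frame brightness relations needed for CNR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["FrameSequence", "read_dicom_sequence", "read_image_stack", "select_beat"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """Ordered grayscale frames with acquisition metadata.

    frames
        Array of shape (n_frames, N, M) with intensities in [0, 1].
    frame_interval
        Seconds per frame (reciprocal of the frame rate).
    pixel_spacing
        mm per pixel, isotropic, if known.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_spacing: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, N, M) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frames.min() < -1e-9 or self.frames.max() > 1.0 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Per-frame acquisition time with the first frame at 0 s."""
        return np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3].astype(float) @ _LUMA
    return arr.astype(float)


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def read_dicom_sequence(path: str | Path) -> FrameSequence:
    """Read a multi-frame ultrasound DICOM cine.

    Color frames are converted to grayscale by luma weighting.  The frame
    interval is taken from the per-frame ``FrameTime`` (ms) attribute, or
    the reciprocal of ``CineRate``/``RecommendedDisplayFrameRate`` when
    only a cine rate is recorded.  Missing frame-time metadata or a
    single-frame file raises.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    pix = ds.pixel_array
    raw = np.asarray(pix)
    if raw.ndim == 2 or (raw.ndim == 3 and raw.shape[-1] in (3, 4) and "NumberOfFrames" not in ds):
        raise ValueError(f"{path}: single-frame DICOM; a cine sequence is required")
    frames = _to_grayscale(raw)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError(f"{path}: single-frame DICOM; a cine sequence is required")

    if getattr(ds, "FrameTime", None):
        interval = float(ds.FrameTime) / 1000.0
    elif getattr(ds, "FrameTimeVector", None):
        interval = float(np.mean(np.asarray(ds.FrameTimeVector, dtype=float)[1:])) / 1000.0
    elif getattr(ds, "CineRate", None):
        interval = 1.0 / float(ds.CineRate)
    elif getattr(ds, "RecommendedDisplayFrameRate", None):
        interval = 1.0 / float(ds.RecommendedDisplayFrameRate)
    else:
        raise ValueError(
            f"{path}: no frame-time metadata (FrameTime, FrameTimeVector, CineRate "
            "and RecommendedDisplayFrameRate all absent)"
        )

    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    frames = np.clip(frames / _dtype_max(raw), 0.0, 1.0)
    return FrameSequence(frames=frames, frame_interval=interval,
                         pixel_spacing=spacing, source_id=str(path))


def read_image_stack(paths: Sequence[str | Path], frame_interval: float) -> FrameSequence:
    """Read an ordered stack of single-frame images (PNG/TIFF) as a cine.

    All images must share dimensions; intensities are rescaled to [0, 1] by
    the dtype maximum and color images reduced by luma weighting.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 images")
    frames = []
    shape = None
    for p in paths:
        raw = iio.imread(str(p))
        img = _to_grayscale(raw) / _dtype_max(raw)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"{p}: dimensions {img.shape} do not match first image {shape}")
        frames.append(np.clip(img, 0.0, 1.0))
    return FrameSequence(frames=np.stack(frames), frame_interval=frame_interval,
                         source_id=str(paths[0]))


def select_beat(seq: FrameSequence, start: int, end: int) -> FrameSequence:
    """Sub-sequence covering one beat, half-open [start, end).

    The first retained frame becomes the reference (zero-strain) frame.
    """
    if not (0 <= start < end <= seq.n_frames):
        raise ValueError(f"invalid beat range [{start}, {end}) for {seq.n_frames} frames")
    if end - start < 2:
        raise ValueError("a beat needs at least 2 frames")
    return replace(seq, frames=seq.frames[start:end])
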