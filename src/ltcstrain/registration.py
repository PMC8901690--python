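"""Landmark tracking, frame co-registration and the circular LV ROI.

The direct strain estimator needs the left ventricle presented with its
long axis vertical and its geometric center fixed, so that between-frame
deformation reduces to a near-pure rescaling.  Three user-supplied seed
points — apex, septal annulus and lateral annulus — are tracked through
the cine by windowed phase correlation; each frame is then rigidly aligned
(translation plus rotation of the annulus-center-to-apex axis onto the
vertical) and cropped to a circular region of interest that covers the LV
while excluding the right-ventricular free wall and left atrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_frames import FrameSequence
from .ltc_core import spectral_correlate

logger = logging.getLogger(__name__)

__all__ = [
    "Landmarks",
    "LandmarkTrack",
    "RegistrationTransform",
    "RegisteredSequence",
    "track_landmarks",
    "compute_frame_transform",
    "register_frames",
    "apply_circular_roi",
]


@dataclass
class Landmarks:
    """Apex and the two mitral-annulus corner points, (x, y) pixels."""

    apex: tuple[float, float]
    annulus_septal: tuple[float, float]
    annulus_lateral: tuple[float, float]

    def __post_init__(self) -> None:
        pts = self.as_array()
        d01 = np.linalg.norm(pts[0] - pts[1])
        d02 = np.linalg.norm(pts[0] - pts[2])
        d12 = np.linalg.norm(pts[1] - pts[2])
        if min(d01, d02, d12) == 0:
            raise ValueError("landmarks must be pairwise distinct")
        e1, e2 = pts[1] - pts[0], pts[2] - pts[0]
        area = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area <= 1.0:
            raise ValueError(f"landmarks are (near-)collinear: triangle area {area:.3f} px^2")

    def as_array(self) -> np.ndarray:
        return np.array([self.apex, self.annulus_septal, self.annulus_lateral], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Landmarks":
        return cls(apex=tuple(arr[0]), annulus_septal=tuple(arr[1]),
                   annulus_lateral=tuple(arr[2]))


@dataclass
class LandmarkTrack:
    """Per-frame landmark positions, shape (n_frames, 3, 2)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (3, 2):
            raise ValueError("positions must have shape (n_frames, 3, 2)")
        for k in range(self.positions.shape[0]):
            Landmarks.from_array(self.positions[k])  # validates

    def __len__(self) -> int:
        return self.positions.shape[0]

    def landmarks(self, k: int) -> Landmarks:
        return Landmarks.from_array(self.positions[k])


@dataclass
class RegistrationTransform:
    """Rigid alignment parameters for one frame.

    ``center`` is the geometric center of the three landmarks and ``angle``
    the signed angle (degrees, positive clockwise in image coordinates) of
    the annulus-center-to-apex line measured from the upward vertical; the
    correction rotates by ``-angle``.
    """

    center: tuple[float, float]
    angle: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.angle <= 180.0):
            raise ValueError("angle must lie in (-180, 180]")


@dataclass
class RegisteredSequence:
    """Aligned, ROI-masked square sub-images of uniform odd side length."""

    frames: np.ndarray  # (n_frames, side, side)
    frame_interval: float
    roi_radius: float
    transforms: list[RegistrationTransform]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# --------------------------------------------------------------------------

def _extract_window(frame: np.ndarray, center_xy: np.ndarray, window: int) -> np.ndarray | None:
    """Odd-sided window at the rounded position, its center clamped so the
    patch fits inside the frame; None if the frame is smaller than the
    window.  Both frames of a pair use the same clamped center, so the
    relative shift estimate is unaffected."""
    half = window // 2
    ny, nx = frame.shape
    if ny < window or nx < window:
        return None
    cx = int(np.clip(round(center_xy[0]), half, nx - half - 1))
    cy = int(np.clip(round(center_xy[1]), half, ny - half - 1))
    return frame[cy - half:cy + half + 1, cx - half:cx + half + 1]


def track_landmarks(
    seq: FrameSequence,
    initial: Landmarks,
    window: int = 96,
    peak_ratio_threshold: float = 1.2,
    max_step: float = 10.0,
) -> LandmarkTrack:
    """Track the three seed landmarks through the cine.

    For each consecutive pair, the displacement of each landmark is the
    subpixel peak of the phase-filtered spectral cross-correlation of
    window-sized patches centered on the current estimate; positions
    accumulate over frames.  A correlation peak ratio below the threshold,
    or a step exceeding ``max_step`` pixels (faster than cardiac tissue
    moves between frames; such peaks are clutter lock-ons), zeroes the
    displacement for that step with a logged warning; a landmark drifting
    outside the image raises with the frame index.
    """
    if window < 16:
        raise ValueError("tracking window must be >= 16 px")
    window = window | 1  # odd side so the patch center is a pixel
    pos = initial.as_array()
    n, m = seq.frame_shape
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] >= m) or np.any(pos[:, 1] < 0) or np.any(pos[:, 1] >= n):
        raise ValueError("initial landmarks must lie inside frame 0")
    track = [pos.copy()]
    held: set[int] = set()  # landmarks already warned about, to avoid log floods

    def _hold(j: int, k: int, reason: str) -> None:
        log = logger.warning if j not in held else logger.debug
        log("landmark %d at frame %d: %s; holding", j, k, reason)
        held.add(j)

    for k in range(seq.n_frames - 1):
        new = track[-1].copy()
        for j in range(3):
            pa = _extract_window(seq.frames[k], new[j], window)
            pb = _extract_window(seq.frames[k + 1], new[j], window)
            if pa is None or pb is None:
                raise ValueError(f"landmark {j} left the image bounds at frame {k}")
            try:
                cp = spectral_correlate(pa, pb)
            except ValueError:
                _hold(j, k, "degenerate correlation")
                continue
            if cp.peak_ratio < peak_ratio_threshold:
                _hold(j, k, f"peak ratio {cp.peak_ratio:.2f} below {peak_ratio_threshold:.2f}")
                continue
            if np.hypot(*cp.peak_shift) > max_step:
                _hold(j, k, f"step {np.hypot(*cp.peak_shift):.1f} px exceeds {max_step:.1f} px")
                continue
            new[j] += cp.peak_shift
        if np.any(new[:, 0] < 0) or np.any(new[:, 0] >= m) or np.any(new[:, 1] < 0) or np.any(new[:, 1] >= n):
            raise ValueError(f"a landmark drifted outside the image at frame {k + 1}")
        track.append(new)
    return LandmarkTrack(positions=np.stack(track))


def compute_frame_transform(lm: Landmarks) -> RegistrationTransform:
    """Geometric center and long-axis orientation angle of one frame.

    The center is the arithmetic mean of the three landmarks; the angle is
    the signed angle between the annulus-midpoint-to-apex vector and the
    upward vertical, positive clockwise in image coordinates.
    """
    pts = lm.as_array()
    center = pts.mean(axis=0)
    mid_annulus = 0.5 * (pts[1] + pts[2])
    v = pts[0] - mid_annulus  # annulus center -> apex
    angle = np.degrees(np.arctan2(v[0], -v[1]))
    if angle <= -180.0:
        angle += 360.0
    return RegistrationTransform(center=tuple(center), angle=float(angle))


def register_frames(
    seq: FrameSequence,
    track: LandmarkTrack,
    roi_factor: float = 1.3,
    taper_fraction: float = 0.25,
) -> RegisteredSequence:
    """Align each frame on its landmark center with a vertical long axis.

    Each frame is resampled (inverse mapping, bicubic) so the geometric
    center of its landmarks lands on the sub-image center and the
    annulus-to-apex axis is vertical, then cropped to a common odd-sided
    square and masked by the circular ROI (radius ``roi_factor`` times the
    frame-0 maximum landmark distance, raised-cosine edge taper over the
    outer quarter of the radius; a generous margin and a wide taper keep
    the moving wall ends away from the sharp aperture edge).  Content
    that would fall past the image border is zero-padded with a warning.
    """
    if len(track) != seq.n_frames:
        raise ValueError("track length must equal the frame count")
    transforms = [compute_frame_transform(track.landmarks(k)) for k in range(seq.n_frames)]
    t0 = transforms[0]
    pts0 = track.positions[0]
    radius = roi_factor * float(np.max(np.linalg.norm(pts0 - np.asarray(t0.center), axis=1)))
    side = 2 * int(np.ceil(radius)) + 1
    c_out = (side - 1) / 2.0

    n, m = seq.frame_shape
    out = np.empty((seq.n_frames, side, side))
    warned = False
    for k, tr in enumerate(transforms):
        th = np.radians(tr.angle)
        # output coords -> input coords: rotate by +angle about the landmark
        # center after moving the sub-image center onto it
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])  # (x, y)
        cin = np.asarray(tr.center)
        # p_in = R @ (p_out - c_out) + cin ; in (row, col): swap components
        Rrc = np.array([[R[1, 1], R[1, 0]], [R[0, 1], R[0, 0]]])
        offset = cin[::-1] - Rrc @ np.array([c_out, c_out])
        reg = ndimage.affine_transform(seq.frames[k], Rrc, offset=offset,
                                       output_shape=(side, side), order=3, mode="constant")
        corners = cin[None, :] + (np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]]) * c_out) @ R.T
        if (not warned) and (corners.min() < 0 or np.any(corners.max(axis=0) >= (m, n))):
            logger.warning("frame %d: ROI extends past the image after alignment; zero-padded", k)
            warned = True
        out[k] = apply_circular_roi(reg, (c_out, c_out), radius, taper_fraction * radius)
    return RegisteredSequence(frames=out, frame_interval=seq.frame_interval,
                              roi_radius=radius, transforms=transforms)


def apply_circular_roi(
    frame: np.ndarray,
    center: tuple[float, float],
    radius: float,
    taper: float = 0.0,
) -> np.ndarray:
    """Mask pixels outside a closed disk, with a raised-cosine edge taper.

    Pixels beyond ``radius`` are zeroed; within the taper band
    ``[radius - taper, radius]`` the mask falls smoothly from 1 to 0; the
    interior is unchanged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 <= taper < radius):
        raise ValueError("taper must satisfy 0 <= taper < radius")
    ny, nx = frame.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - center[0], yy - center[1])
    mask = np.ones_like(frame, dtype=float)
    mask[r > radius] = 0.0
    if taper > 0:
        band = (r > radius - taper) & (r <= radius)
        mask[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - (radius - taper)) / taper))
    return frame * mask
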