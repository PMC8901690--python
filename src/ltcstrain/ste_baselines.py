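"""Block-matching speckle-tracking baselines (DCC and FTC).

Two conventional speckle-tracking estimators serve as benchmarks for the
direct method:

* **DCC** — direct cross-correlation: zero-mean normalized *spatial*
  correlation of interrogation windows (zero-padded, full search).
* **FTC** — Fourier-transform correlation: the inverse FT of the conjugate
  spectral product of the two windows (circular).

Displacement fields from either kernel advect an initial myocardial
boundary polyline with fourth-order Runge-Kutta; GLS follows from the
change in boundary arc length relative to the reference frame.  No image
co-registration is performed for these baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftshift, ifft2
from scipy.signal.windows import tukey
from scipy.interpolate import RegularGridInterpolator

from .ltc_core import subpixel_peak
from .strain_series import StrainSeries, drift_correct

logger = logging.getLogger(__name__)

__all__ = [
    "VectorField",
    "BoundaryTrack",
    "displacement_field",
    "propagate_boundary",
    "arc_length_gls",
]


@dataclass
class VectorField:
    """Displacement field on a regular window-center grid (px/frame)."""

    grid_x: np.ndarray  # (nx,)
    grid_y: np.ndarray  # (ny,)
    u: np.ndarray  # (ny, nx) horizontal displacement
    v: np.ndarray  # (ny, nx) vertical displacement

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement field contains non-finite values")

    def interpolator(self) -> "RegularGridInterpolator":
        uv = np.stack([self.u, self.v], axis=-1)
        return RegularGridInterpolator(
            (self.grid_y, self.grid_x), uv, bounds_error=False, fill_value=None
        )


@dataclass
class BoundaryTrack:
    """Per-frame boundary polylines (apex-to-annulus open curve)."""

    points: np.ndarray  # (n_frames, n_points, 2) as (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[-1] != 2:
            raise ValueError("points must have shape (n_frames, n_points, 2)")
        if np.any(self.arc_length <= 0):
            raise ValueError("degenerate (zero-length) boundary")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=1), axis=2)
        return seg.sum(axis=1)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]


# --------------------------------------------------------------------------
# window correlation kernels
# --------------------------------------------------------------------------

def window_correlation(
    a: np.ndarray,
    b: np.ndarray,
    kernel: str = "dcc",
    zero_pad: bool | None = None,
    normalize: bool | None = None,
    zero_mean: bool = True,
) -> np.ndarray:
    """Correlation plane of two equal windows under a named kernel.

    ``dcc`` defaults to zero-mean normalized, zero-padded spatial
    correlation; ``ftc`` to the conjugate spectral product (circular) of
    raised-cosine-apodized windows — the apodization suppresses the
    wrap-around leakage the circular kernel is otherwise prone to.  The
    keyword overrides expose matched conventions so the two kernels can be
    compared estimating the same quantity.  The plane is returned
    peak-centered (zero shift at the center pixel).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("windows must share a shape")
    if kernel not in ("dcc", "ftc"):
        raise ValueError(f"unknown kernel {kernel!r}")
    if zero_pad is None:
        zero_pad = kernel == "dcc"
    if normalize is None:
        normalize = kernel == "dcc"
    if zero_mean:
        a = a - a.mean()
        b = b - b.mean()
    if kernel == "ftc" and not zero_pad:
        w = np.outer(tukey(a.shape[0], 0.3), tukey(a.shape[1], 0.3))
        a = a * w
        b = b * w
    w = a.shape[0]
    if zero_pad:
        size = 2 * w
        fa = fft2(a, s=(size, size))
        fb = fft2(b, s=(size, size))
        plane = np.real(ifft2(np.conj(fa) * fb))
        # compensate the triangular overlap weighting of the linear
        # correlation, which otherwise biases the peak toward zero lag
        ones = fft2(np.ones_like(a), s=(size, size))
        overlap = np.real(ifft2(np.conj(ones) * ones))
        plane = plane / np.maximum(overlap, w)
        crop = slice(size // 2 - w // 2, size // 2 + w // 2 + 1)
        plane = fftshift(plane)[crop, crop]
    else:
        plane = fftshift(np.real(ifft2(np.conj(fft2(a)) * fft2(b))))
    if normalize:
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        plane = plane / denom if denom > 0 else plane * 0.0
    return plane


def _window_starts(extent: int, window: int, step: int) -> np.ndarray:
    starts = np.arange(0, extent - window + 1, step)
    return starts


def displacement_field(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 32,
    overlap: float = 0.75,
    kernel: str = "dcc",
) -> VectorField:
    """Window-wise displacement of ``frame_b`` relative to ``frame_a``.

    The frames are tiled with ``window``-sized interrogation windows at the
    given overlap fraction; each window pair is correlated with the named
    kernel and the subpixel peak gives the local (u, v) displacement in
    px/frame.  Windows whose correlation is degenerate get zero
    displacement.
    """
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    n, m = frame_a.shape
    if window > min(n, m):
        raise ValueError(f"window {window} larger than frame {frame_a.shape}")
    step = max(int(round(window * (1.0 - overlap))), 1)
    ys = _window_starts(n, window, step)
    xs = _window_starts(m, window, step)
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros((len(ys), len(xs)))
    for j, y0 in enumerate(ys):
        for i, x0 in enumerate(xs):
            wa = frame_a[y0:y0 + window, x0:x0 + window]
            wb = frame_b[y0:y0 + window, x0:x0 + window]
            plane = window_correlation(wa, wb, kernel=kernel)
            # quarter rule: shifts beyond window/4 are unreliable
            c = plane.shape[0] // 2
            q = window // 4
            sub = plane[c - q:c + q + 1, c - q:c + q + 1]
            try:
                dx, dy = subpixel_peak(sub)
            except ValueError:
                dx = dy = 0.0
            u[j, i] = dx
            v[j, i] = dy
    centers = (window - 1) / 2.0
    return VectorField(grid_x=xs + centers, grid_y=ys + centers, u=u, v=v)


# --------------------------------------------------------------------------
# boundary propagation and arc-length strain
# --------------------------------------------------------------------------

def propagate_boundary(
    initial: np.ndarray,
    fields: list[VectorField],
    frame_interval: float,
) -> BoundaryTrack:
    """Advect a boundary polyline through per-pair displacement fields.

    Each point advances by one frame per field using RK4 in pseudo-time
    (one unit per pair), sampling the fields bilinearly in space and
    linearly in time for the substeps.  Points leaving the field domain
    are clamped to the domain edge with a logged warning.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 2 or initial.shape[1] != 2:
        raise ValueError("initial boundary must be (n_points, 2)")
    interps = [f.interpolator() for f in fields]
    x_lo = min(f.grid_x[0] for f in fields)
    x_hi = max(f.grid_x[-1] for f in fields)
    y_lo = min(f.grid_y[0] for f in fields)
    y_hi = max(f.grid_y[-1] for f in fields)
    clamped = False

    def velocity(t: float, pts: np.ndarray) -> np.ndarray:
        # fields anchored at pair midpoints k + 0.5, linear in time between
        s = t - 0.5
        k0 = int(np.clip(np.floor(s), 0, len(fields) - 1))
        k1 = min(k0 + 1, len(fields) - 1)
        w = float(np.clip(s - k0, 0.0, 1.0))
        q = pts[:, ::-1]  # (y, x)
        uv = (1 - w) * interps[k0](q) + w * interps[k1](q)
        return uv

    track = [initial.copy()]
    for k in range(len(fields)):
        p = track[-1].copy()
        t = float(k)
        h = 1.0
        k1 = velocity(t, p)
        k2 = velocity(t + h / 2, p + h / 2 * k1)
        k3 = velocity(t + h / 2, p + h / 2 * k2)
        k4 = velocity(t + h, p + h * k3)
        p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out = (p[:, 0] < x_lo) | (p[:, 0] > x_hi) | (p[:, 1] < y_lo) | (p[:, 1] > y_hi)
        if out.any():
            if not clamped:
                logger.warning("boundary points left the field domain; clamped to edge")
                clamped = True
            p[:, 0] = np.clip(p[:, 0], x_lo, x_hi)
            p[:, 1] = np.clip(p[:, 1], y_lo, y_hi)
        track.append(p)
    return BoundaryTrack(points=np.stack(track))


def arc_length_gls(
    track: BoundaryTrack,
    frame_interval: float,
    meta: str = "ste",
    apply_drift_correction: bool = True,
) -> StrainSeries:
    """GLS from the change in boundary arc length.

    ``GLS(t) = (L(t) - L(0)) / L(0) * 100%`` with L the cumulative polyline
    length; drift correction (linear ramp to zero at the last frame) is
    applied by default so the beat ends undeformed.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    L = track.arc_length
    gls = (L - L[0]) / L[0] * 100.0
    series = StrainSeries(times=np.arange(track.n_frames) * frame_interval,
                          gls=gls, meta=meta)
    return drift_correct(series) if apply_drift_correction else series
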