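"""Synthetic speckle sequences and LV phantoms with exact ground truth.

Two generators feed the test battery:

* :func:`affine_sequence` warps a speckle texture by prescribed per-pair
  affine deformations (stretch factors a11/a22, translation), the cleanest
  possible oracle for the spectral scale estimators.
* :func:`lv_phantom` draws a U-shaped speckled myocardial band around a
  dark blood pool, drives it through a beat-like shortening waveform, and
  adds cavity noise calibrated to a target contrast-to-noise ratio (CNR),
  emulating the image-quality spread of clinical echocardiograms.

Both return the generated :class:`~ltcstrain.io_frames.FrameSequence`
together with a :class:`PhantomTruth` carrying per-frame GLS, per-pair
GLSr, landmark positions, midwall boundary and region masks.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_frames import FrameSequence

__all__ = [
    "AffineTruth",
    "PhantomGeometry",
    "PhantomTruth",
    "SpeckleBlobs",
    "sample_speckle_blobs",
    "render_speckle",
    "make_speckle_field",
    "affine_sequence",
    "lv_phantom",
    "compute_cnr",
]


@dataclass
class AffineTruth:
    """Per-frame-pair planar affine deformation ground truth.

    Each array has one entry per consecutive frame pair.  ``F`` is the
    deformation gradient ``[[a11, a12], [a21, a22]]`` and ``(t1, t2)`` the
    translation, applied about the image center.  The derived per-pair
    longitudinal strain is ``a22 - 1``.
    """

    a11: np.ndarray
    a22: np.ndarray
    a12: np.ndarray = None  # type: ignore[assignment]
    a21: np.ndarray = None  # type: ignore[assignment]
    t1: np.ndarray = None  # type: ignore[assignment]
    t2: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.a11 = np.atleast_1d(np.asarray(self.a11, dtype=float))
        self.a22 = np.atleast_1d(np.asarray(self.a22, dtype=float))
        n = len(self.a11)
        for name in ("a12", "a21", "t1", "t2"):
            v = getattr(self, name)
            v = np.zeros(n) if v is None else np.atleast_1d(np.asarray(v, dtype=float))
            setattr(self, name, v)
        det = self.a11 * self.a22 - self.a12 * self.a21
        if np.any(det <= 0):
            raise ValueError("deformation gradient must have positive determinant")

    def __len__(self) -> int:
        return len(self.a11)

    def F(self, k: int) -> np.ndarray:
        return np.array([[self.a11[k], self.a12[k]], [self.a21[k], self.a22[k]]])

    def displacement_gradient(self, k: int) -> np.ndarray:
        """grad(u) = I - F for pair k."""
        return np.eye(2) - self.F(k)

    @property
    def pair_strain(self) -> np.ndarray:
        """Per-pair longitudinal strain a22 - 1 (dimensionless)."""
        return self.a22 - 1.0


@dataclass
class PhantomGeometry:
    """LV phantom geometry in pixels (y increases downward, apex on top)."""

    size: tuple[int, int] = (193, 193)
    apex_y: float = 28.0
    annulus_y: float = 158.0
    cavity_half_width: float = 34.0
    wall_thickness: float = 20.0


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom sequence."""

    gls_truth: np.ndarray  # per-frame GLS (%)
    glsr_truth: np.ndarray  # per-pair strain rate (1/s)
    boundary: np.ndarray | None = None  # (n_frames, n_points, 2) midwall polylines
    ventricle_masks: np.ndarray | None = None  # (n_frames, N, M) bool
    myocardium_masks: np.ndarray | None = None
    landmarks: np.ndarray | None = None  # (n_frames, 3, 2): apex, septal, lateral
    cnr_target: float | None = None
    pair_strain: np.ndarray | None = None  # per-pair strain (dimensionless)
    affine: AffineTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.gls_truth = np.asarray(self.gls_truth, dtype=float)
        if abs(self.gls_truth[0]) > 1e-12:
            raise ValueError("gls_truth must start at 0 (reference frame)")
        if self.ventricle_masks is not None and self.myocardium_masks is not None:
            if np.any(self.ventricle_masks & self.myocardium_masks):
                raise ValueError("ventricle and myocardium masks must be disjoint")


# --------------------------------------------------------------------------
# speckle texture
# --------------------------------------------------------------------------

@dataclass
class SpeckleBlobs:
    """Continuous-position Gaussian scatterer set.

    Frames are rendered by evaluating the Gaussian sum analytically at the
    (affinely transformed) blob positions, never by resampling a reference
    grid: grid resampling leaves an interpolation-error ghost of the
    undeformed content that real acquisitions do not have, and that ghost
    anchors correlation estimators at zero deformation.
    """

    centers: np.ndarray  # (n, 2) as (x, y), continuous
    amps: np.ndarray
    sigma: float  # isotropic blob std (px)
    shape: tuple[int, int]


def sample_speckle_blobs(
    shape: tuple[int, int],
    density: float = 0.08,
    diameter: float = 3.0,
    seed: int = 0,
) -> SpeckleBlobs:
    """Draw a deterministic scatterer set: ``round(density*N*M)`` blobs of
    FWHM ``diameter`` px at uniform continuous positions."""
    if density <= 0:
        raise ValueError("density must be positive")
    if diameter < 1:
        raise ValueError("diameter must be >= 1 px")
    n, m = shape
    count = int(round(density * n * m))
    rng = np.random.default_rng(seed)
    xs = rng.uniform(0, m - 1, count)
    ys = rng.uniform(0, n - 1, count)
    amps = rng.uniform(0.5, 1.0, count)
    return SpeckleBlobs(centers=np.column_stack([xs, ys]), amps=amps,
                        sigma=diameter / 2.355, shape=(n, m))


def render_speckle(
    blobs: SpeckleBlobs,
    F: np.ndarray | None = None,
    T: np.ndarray | None = None,
    about: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the blob field, optionally deformed by ``x' = F.(x-c)+T+c``.

    Blob centers move with the material map and the blob covariance
    transforms as ``F sigma^2 F^T`` (peak amplitudes are preserved, as for
    an intensity pattern).  Returns the raw, unnormalized sum.
    """
    n, m = blobs.shape
    if F is None:
        F = np.eye(2)
    if T is None:
        T = np.zeros(2)
    c = about if about is not None else np.array([(m - 1) / 2.0, (n - 1) / 2.0])
    centers = (blobs.centers - c) @ F.T + T + c
    cov = F @ (blobs.sigma**2 * np.eye(2)) @ F.T
    cov_inv = np.linalg.inv(cov)
    # blob support radius ~4 sigma of the largest principal axis
    rad = int(np.ceil(4.0 * np.sqrt(np.linalg.eigvalsh(cov)[-1])))
    grid = np.zeros((n, m))
    for (cx, cy), a in zip(centers, blobs.amps):
        x0 = int(np.floor(cx)) - rad
        x1 = int(np.floor(cx)) + rad + 2
        y0 = int(np.floor(cy)) - rad
        y1 = int(np.floor(cy)) + rad + 2
        if x1 <= 0 or y1 <= 0 or x0 >= m or y0 >= n:
            continue
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, m), min(y1, n)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        q = (cov_inv[0, 0] * xs[None, :] ** 2
             + 2.0 * cov_inv[0, 1] * ys[:, None] * xs[None, :]
             + cov_inv[1, 1] * ys[:, None] ** 2)
        grid[y0:y1, x0:x1] += a * np.exp(-0.5 * q)
    return grid


def make_speckle_field(
    shape: tuple[int, int],
    density: float = 0.08,
    diameter: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Random Gaussian-blob speckle texture normalized to [0, 1].

    ``density`` is blobs per pixel^2 (the count is ``round(density*N*M)``,
    drawn deterministically) and ``diameter`` the blob full width at half
    maximum in pixels.  Identical seed and parameters give bit-identical
    output.
    """
    grid = render_speckle(sample_speckle_blobs(shape, density, diameter, seed))
    lo, hi = grid.min(), grid.max()
    if hi > lo:
        grid = (grid - lo) / (hi - lo)
    return grid


# --------------------------------------------------------------------------
# affine-truth sequences
# --------------------------------------------------------------------------

def _warp_affine_about_center(
    image: np.ndarray, F: np.ndarray, T: np.ndarray, order: int = 3
) -> np.ndarray:
    """Warp ``image`` so material points move by x' = F.(x-c) + T + c.

    Implemented as the inverse map sampled at output pixels (single
    interpolation).  F and T are in (x, y) convention.
    """
    n, m = image.shape
    c = np.array([(m - 1) / 2.0, (n - 1) / 2.0])  # (x, y)
    Finv = np.linalg.inv(F)
    # output pixel x_out samples input at Finv.(x_out - c - T) + c
    # affine_transform works in (row, col) = (y, x): swap axes
    P = np.array([[Finv[1, 1], Finv[1, 0]], [Finv[0, 1], Finv[0, 0]]])
    shift_xy = -Finv @ (c + T) + c
    offset = shift_xy[::-1]
    return ndimage.affine_transform(image, P, offset=offset, order=order, mode="constant")


def affine_sequence(
    field: np.ndarray | SpeckleBlobs,
    truth: AffineTruth,
    n_frames: int,
    frame_interval: float = 0.02,
) -> tuple[FrameSequence, PhantomTruth]:
    """Deform a speckle texture by prescribed per-pair affine transforms.

    Frame ``k+1`` applies pair ``k``'s transform on top of the accumulated
    deformation about the image center.  Given a :class:`SpeckleBlobs`
    scatterer set, every frame is rendered analytically at the composed
    transform (exact, no interpolation); given a plain grid, frames are
    rendered by a single bicubic warp of the reference.  Ground-truth
    compound GLS per frame is ``prod(a22) - 1``.
    """
    if len(truth) != n_frames - 1:
        raise ValueError("need one truth entry per frame pair")
    if isinstance(field, SpeckleBlobs):
        blobs = field
        n, m = blobs.shape
        raw0 = render_speckle(blobs)
        lo, hi = raw0.min(), raw0.max()
        span = (hi - lo) if hi > lo else 1.0
        field_img = (raw0 - lo) / span
    else:
        blobs = None
        field_img = np.asarray(field, dtype=float)
        n, m = field_img.shape
    frames = [field_img]
    Fc = np.eye(2)
    Tc = np.zeros(2)
    scale_prod = [1.0]
    for k in range(n_frames - 1):
        Fk = truth.F(k)
        Tk = np.array([truth.t1[k], truth.t2[k]])
        Fc = Fk @ Fc
        Tc = Fk @ Tc + Tk
        if max(abs(Fc[0, 0]), abs(Fc[1, 1])) > 1.6 or np.max(np.abs(Tc)) > min(n, m) / 4:
            raise ValueError(
                f"cumulative deformation at pair {k} pushes content outside the frame"
            )
        if blobs is not None:
            raw = render_speckle(blobs, F=Fc, T=Tc)
            frames.append(np.clip((raw - lo) / span, 0.0, 1.0))
        else:
            frames.append(np.clip(_warp_affine_about_center(field_img, Fc, Tc), 0.0, 1.0))
        scale_prod.append(scale_prod[-1] * truth.a22[k])
    gls = (np.asarray(scale_prod) - 1.0) * 100.0
    pair_eps = truth.pair_strain
    ptruth = PhantomTruth(
        gls_truth=gls,
        glsr_truth=pair_eps / frame_interval,
        pair_strain=pair_eps,
        affine=truth,
    )
    seq = FrameSequence(
        frames=np.stack(frames), frame_interval=frame_interval, source_id="affine-phantom"
    )
    return seq, ptruth


# --------------------------------------------------------------------------
# LV phantom
# --------------------------------------------------------------------------

def _midwall_polyline(geom: PhantomGeometry, n_points: int = 257) -> np.ndarray:
    """Open apex-to-annulus midwall curve: two straight walls joined by a
    semicircular apex cap, sampled uniformly in arc length, (x, y) pairs
    ordered septal-annulus -> apex -> lateral-annulus."""
    cx = (geom.size[1] - 1) / 2.0
    rx = geom.cavity_half_width
    cap_cy = geom.apex_y + rx
    wall_len = geom.annulus_y - cap_cy
    if wall_len <= 0:
        raise ValueError("annulus must sit below the apex cap")
    cap_len = np.pi * rx
    total = 2 * wall_len + cap_len
    s = np.linspace(0.0, total, n_points)
    pts = np.empty((n_points, 2))
    for i, si in enumerate(s):
        if si < wall_len:  # left wall, going up
            pts[i] = (cx - rx, geom.annulus_y - si)
        elif si < wall_len + cap_len:  # apex cap
            th = np.pi + (si - wall_len) / rx  # from pi (left) to 2*pi (right)
            pts[i] = (cx + rx * np.cos(th), cap_cy + rx * np.sin(th))
        else:  # right wall, going down
            pts[i] = (cx + rx, cap_cy + (si - wall_len - cap_len))
    return pts


def _phantom_masks(geom: PhantomGeometry, midwall: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Myocardium (within half thickness of the midwall) and ventricle
    interior masks for the reference geometry."""
    n, m = geom.size
    yy, xx = np.mgrid[0:n, 0:m]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(midwall)
    d, _ = tree.query(pts, workers=-1)
    d = d.reshape(n, m)
    half = geom.wall_thickness / 2.0
    myo = d <= half
    cx = (m - 1) / 2.0
    rx = geom.cavity_half_width
    cap_cy = geom.apex_y + rx
    inner = rx - half
    in_shaft = (np.abs(xx - cx) < inner) & (yy >= cap_cy) & (yy < geom.annulus_y)
    in_cap = ((xx - cx) ** 2 + (yy - cap_cy) ** 2 < inner**2) & (yy < cap_cy)
    ventricle = (in_shaft | in_cap) & ~myo
    return myo, ventricle


def _beat_waveform(peak_strain: float, n_frames: int, frame_interval: float) -> np.ndarray:
    """GLS(t) = -|peak| * sin^2(pi*t/T) in %, zero at both ends."""
    t = np.arange(n_frames) * frame_interval
    T = (n_frames - 1) * frame_interval
    return -abs(peak_strain) * np.sin(np.pi * t / T) ** 2


def lv_phantom(
    geometry: PhantomGeometry | None = None,
    peak_strain: float = -15.0,
    n_frames: int = 20,
    frame_interval: float = 0.02,
    cnr: float = 8.0,
    seed: int = 0,
    speckle_density: float = 0.15,
    speckle_diameter: float = 3.0,
    noise_scale: float = 3.0,
) -> tuple[FrameSequence, PhantomTruth]:
    """Speckled LV phantom undergoing a beat of longitudinal shortening.

    A U-shaped myocardial band (two walls meeting at an apex cap) is drawn
    around a dark cavity and contracted by an isotropic scale about the
    annulus midpoint following ``GLS(t) = -|peak| * sin^2(pi t/T)``, so the
    midwall arc length shortens by exactly the prescribed strain.  Additive
    Gaussian noise inside the cavity is calibrated by bisection so that
    :func:`compute_cnr` on the emitted frames hits the requested target
    within +-0.5 dB.  Landmarks (apex, septal and lateral annulus), the
    midwall boundary, masks, per-frame GLS and per-pair GLSr are returned
    as ground truth.

    ``peak_strain`` must lie in (-30, 0) % and ``n_frames`` be >= 16.
    """
    if not (-30.0 < peak_strain < 0.0):
        raise ValueError("peak_strain must be in (-30, 0) percent")
    if n_frames < 16:
        raise ValueError("need at least 16 frames per beat")
    geom = geometry or PhantomGeometry()
    n, m = geom.size
    rng = np.random.default_rng(seed)

    midwall0 = _midwall_polyline(geom)

    # continuous scatterer set: frames are rendered analytically at each
    # deformation, so consecutive frames share no resampling artifacts
    blobs = sample_speckle_blobs(geom.size, density=speckle_density,
                                 diameter=speckle_diameter, seed=seed)
    cavity_base = 0.25
    gls = _beat_waveform(peak_strain, n_frames, frame_interval)
    scales = 1.0 + gls / 100.0
    cx = (m - 1) / 2.0
    anchor = np.array([cx, geom.annulus_y])  # annulus midpoint (x, y)

    apex0 = np.array([cx, geom.apex_y])
    sept0 = midwall0[0].copy()
    lat0 = midwall0[-1].copy()

    raw0 = render_speckle(blobs)
    lo, hi = raw0.min(), raw0.max()
    span = (hi - lo) if hi > lo else 1.0
    yy, xx = np.mgrid[0:n, 0:m]
    grid_pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    clean = np.empty((n_frames, n, m))
    ven_masks = np.empty((n_frames, n, m), dtype=bool)
    myo_masks = np.empty((n_frames, n, m), dtype=bool)
    boundary = np.empty((n_frames, midwall0.shape[0], 2))
    landmarks = np.empty((n_frames, 3, 2))
    half0 = geom.wall_thickness / 2.0
    for k, s in enumerate(scales):
        F = np.array([[s, 0.0], [0.0, s]])
        if k == 0:
            raw = raw0
        else:
            raw = render_speckle(blobs, F=F, about=anchor)
        spk = np.clip((raw - lo) / span, 0.0, 1.0)
        midwall_k = anchor + s * (midwall0 - anchor)
        tree = cKDTree(midwall_k)
        d0 = tree.query(grid_pts, workers=-1)[0].reshape(n, m) / s  # ref-coord distance
        soft = np.clip((half0 + 1.0 - d0) / 2.0, 0.0, 1.0)
        tissue = 0.62 + 0.38 * spk
        clean[k] = cavity_base + (tissue - cavity_base) * soft
        myo = d0 <= half0
        pts0 = anchor + (grid_pts - anchor) / s
        x0 = pts0[:, 0].reshape(n, m)
        y0 = pts0[:, 1].reshape(n, m)
        cap_cy = geom.apex_y + geom.cavity_half_width
        inner = geom.cavity_half_width - half0
        in_shaft = (np.abs(x0 - cx) < inner) & (y0 >= cap_cy) & (y0 < geom.annulus_y)
        in_cap = ((x0 - cx) ** 2 + (y0 - cap_cy) ** 2 < inner**2) & (y0 < cap_cy)
        myo_masks[k] = myo
        ven_masks[k] = (in_shaft | in_cap) & ~myo
        boundary[k] = midwall_k
        for j, p0 in enumerate((apex0, sept0, lat0)):
            landmarks[k, j] = anchor + s * (p0 - anchor)
        del F

    # calibrate cavity noise to the CNR target using eroded frame-0 masks
    # and the actual frame-0 clutter realization
    ven_cnr = ndimage.binary_erosion(ven_masks[0], iterations=2)
    myo_cnr = ndimage.binary_erosion(myo_masks[0], iterations=2)
    clutter = [_clutter_field((n, m), noise_scale, rng) for _ in range(n_frames)]
    sigma = _solve_noise_sigma(clean[0], ven_cnr, myo_cnr, cavity_base, cnr,
                               clutter[0])

    # clutter occupies the blood pool and a halo around the walls: acoustic
    # noise concentrates near the imaged structures, and a noise-free outer
    # wall edge would hand the block-matching baselines an unrealistically
    # clean anchor
    frames = np.empty_like(clean)
    for k in range(n_frames):
        halo = ndimage.binary_dilation(myo_masks[k], iterations=18)
        noise_region = (halo | ven_masks[k]) & ~myo_masks[k]
        frames[k] = np.clip(clean[k] + sigma * clutter[k] * noise_region, 0.0, 1.0)

    achieved = compute_cnr(frames[0], ven_cnr, myo_cnr)
    if abs(achieved - cnr) > 0.5:
        raise ValueError(
            f"CNR target {cnr} dB unreachable (achieved {achieved:.2f} dB)"
        )

    glsr = np.diff(gls) / 100.0 / frame_interval
    truth = PhantomTruth(
        gls_truth=gls,
        glsr_truth=glsr,
        boundary=boundary,
        ventricle_masks=ven_masks,
        myocardium_masks=myo_masks,
        landmarks=landmarks,
        cnr_target=cnr,
        pair_strain=np.diff(gls) / 100.0,
    )
    seq = FrameSequence(frames=frames, frame_interval=frame_interval,
                        source_id=f"lv-phantom-seed{seed}-cnr{cnr}")
    return seq, truth


def _clutter_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian clutter.

    Cavity 'noise' in B-mode images is reverberation haze and blood-pool
    clutter, coherent over several pixels rather than pixel-white;
    ``scale`` is the Gaussian correlation length (px)."""
    f = rng.standard_normal(shape)
    if scale > 0:
        f = ndimage.gaussian_filter(f, scale)
        f /= f.std()
    return f


def _solve_noise_sigma(
    clean_frame: np.ndarray,
    ven_mask: np.ndarray,
    myo_mask: np.ndarray,
    cavity_base: float,
    target: float,
    probe: np.ndarray,
) -> float:
    """Bisection on the cavity-noise std so the measured CNR of the noised
    frame matches the target, using the frame's own clutter realization."""

    def measured(sig: float) -> float:
        f = np.clip(clean_frame + sig * probe * ven_mask, 0.0, 1.0)
        return compute_cnr(f, ven_mask, myo_mask)

    hi_cnr = measured(1e-6)
    if hi_cnr < target - 0.5:
        raise ValueError(
            f"CNR target {target} dB unreachable: noiseless phantom measures {hi_cnr:.2f} dB"
        )
    lo, hi = 1e-6, 1.5
    if measured(hi) > target:
        raise ValueError(f"CNR target {target} dB unreachable (too low)")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if measured(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_cnr(frame: np.ndarray, ventricle_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio between the LV cavity and the myocardium.

    ``CNR = |mu_V - mu_T| / sqrt(sigma_V^2 + sigma_T^2)`` from the pixel
    intensities inside each mask.  Reported on the conventional dB-labeled
    scale used for echocardiographic image quality (the raw ratio).
    """
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not ventricle_mask.any() or not tissue_mask.any():
        raise ValueError("masks must be non-empty")
    if np.any(ventricle_mask & tissue_mask):
        raise ValueError("masks must be disjoint")
    v = frame[ventricle_mask]
    t = frame[tissue_mask]
    var = v.var() + t.var()
    if var == 0:
        raise ValueError("both regions are constant; CNR undefined")
    return float(abs(v.mean() - t.mean()) / np.sqrt(var))
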