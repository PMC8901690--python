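"""Logarithm-transform correlation (LTC) kernel.

The left ventricle shortens along its long axis between consecutive
echocardiogram frames, which to first order is an anisotropic rescaling of
the speckle pattern plus a rigid translation.  The Fourier-transform
magnitude of a frame is invariant to translation, and a spatial rescaling by
``a`` maps the magnitude spectrum multiplicatively (wavenumbers scale by
``1/a``).  Resampling the magnitude onto uniform *logarithmic* wavenumber
axes turns that multiplicative rescaling into an additive shift, which a
phase correlation recovers with subpixel precision.  The vertical log-axis
shift ``dy'`` converts directly into the per-pair longitudinal strain
``eps = exp(dy') - 1`` and, divided by the frame interval, into the global
longitudinal strain rate (GLSr, 1/s).

The module provides the spectral primitives (FT magnitude, log resampling
into four spectral quadrants, dynamic phase-filtered ensemble correlation,
subpixel peak fitting) and the per-pair GLSr driver used on registered
sequences.  The driver evaluates the log-domain correlation profile by
symmetric scale-hypothesis rescaling rather than resampling both spectra
onto one shared log grid; see :func:`pairwise_strain` for why.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, fftshift, ifft2, ifftshift
from scipy import ndimage
from scipy.signal.windows import tukey

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralImage",
    "LogSpectralImage",
    "CorrelationPlane",
    "StrainRateSeries",
    "ft_magnitude",
    "log_resample",
    "estimate_envelope_diameter",
    "dynamic_phase_filter",
    "spectral_correlate",
    "ensemble_correlate",
    "subpixel_peak",
    "peak_ratio",
    "shift_to_strain_rate",
    "pairwise_strain",
    "pairwise_glsr",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SpectralImage:
    """DC-centered 2D Fourier transform with wavenumber axes.

    ``values[j, i]`` corresponds to wavenumber ``(u_axis[i], v_axis[j])`` in
    cycles per sub-image.
    """

    values: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class LogSpectralImage:
    """One spectral quadrant resampled onto uniform log-wavenumber axes.

    The grid holds real FT-magnitude samples at wavenumbers
    ``u_k = exp(k * log_step)``, ``k = 0 .. n-1`` on both axes, oriented so
    wavenumber increases rightward and downward.  DC is excluded.
    """

    values: np.ndarray
    log_step: float
    quadrant_id: int

    def __post_init__(self) -> None:
        if self.log_step <= 0:
            raise ValueError("log_step must be positive")
        if self.quadrant_id not in (1, 2, 3, 4):
            raise ValueError("quadrant_id must be 1-4")


@dataclass
class CorrelationPlane:
    """Real correlation surface with its subpixel peak.

    ``peak_shift`` is the (dx, dy) location of the correlation peak relative
    to the plane center, in samples; ``peak_ratio`` is the height ratio of
    the primary to the secondary peak (a quality figure, >= 1).
    """

    values: np.ndarray
    peak_shift: tuple[float, float]
    peak_ratio: float


@dataclass
class StrainRateSeries:
    """Per-frame-pair global longitudinal strain rate.

    times
        Midpoint time of each frame pair (s).
    glsr
        Strain rate per pair (1/s, fractional strain per second); NaN flags
        a failed pair.
    log_shifts
        The (dx', dy') log-axis shifts per pair (natural-log units).
    quality
        Correlation peak ratio per pair.
    """

    times: np.ndarray
    glsr: np.ndarray
    log_shifts: np.ndarray = field(default=None)  # type: ignore[assignment]
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glsr = np.asarray(self.glsr, dtype=float)
        if self.times.shape != self.glsr.shape:
            raise ValueError("times and glsr must have the same length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.glsr)


# --------------------------------------------------------------------------
# spectral primitives
# --------------------------------------------------------------------------

def _apodize(frame: np.ndarray, margin: float = 0.1) -> np.ndarray:
    """Raised-cosine (Tukey) apodization tapering a ``margin`` fraction on
    each edge.  Suppresses the cross-shaped spectral leakage of the crop
    boundary, which would otherwise bias the magnitude correlation."""
    n = frame.shape[0]
    w = tukey(n, alpha=2.0 * margin)
    return frame * np.outer(w, w)


def ft_magnitude(frame: np.ndarray, window: bool = True, pad: int = 2) -> SpectralImage:
    """DC-centered 2D Fourier transform of a square odd-sided sub-image.

    Parameters
    ----------
    frame
        Square, odd-sided 2D array (so DC lands on a pixel after shifting).
    window
        Apply raised-cosine apodization before transforming.
    pad
        Zero-padding factor of the transform.  The continuous windowed
        spectrum has structure at the one-DFT-bin scale, which plain
        sampling cannot carry through the later bilinear log resampling;
        the default 2x oversampling resolves it.  Axes stay in cycles per
        original sub-image.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != frame.shape[1]:
        raise ValueError(f"input must be square 2D, got shape {frame.shape}")
    if pad < 1:
        raise ValueError("pad must be >= 1")
    if window:
        frame = _apodize(frame)
    n = frame.shape[0]
    big = pad * n + (1 - (pad * n) % 2)  # odd, so DC lands on a pixel
    spec = fftshift(fft2(ifftshift(frame), s=(big, big)))
    axis = (np.arange(big) - big // 2) / float(pad)
    return SpectralImage(values=spec, u_axis=axis, v_axis=axis)


def log_resample(
    spec: SpectralImage,
    n_samples: int | None = None,
    preprocess=None,
    u_min: float = 6.0,
    u_max: float | None = None,
    sampling_scale: float = 1.5,
) -> tuple[LogSpectralImage, ...]:
    """Resample the FT magnitude of each spectral quadrant onto log axes.

    For each quadrant about DC (DC row/column excluded) the magnitude is
    bilinearly interpolated onto wavenumbers ``u_k = u_min*exp(k*log_step)``
    with ``log_step = ln(u_max/u_min)/(n_samples-1)``, and reoriented so
    wavenumber increases rightward/downward.  Quadrants are numbered
    1: (+u,+v), 2: (-u,+v), 3: (-u,-v), 4: (+u,-v) with v increasing
    downward.  ``preprocess`` optionally maps the magnitude grid (e.g. log
    compression) before interpolation.

    The wavenumber band matters: below a few cycles per sub-image the log
    grid oversamples the spectrum so heavily that grid-anchored structure
    (identical in any two frames) dominates the correlation, and close to
    Nyquist the magnitude fine structure aliases; the default band
    [6, Nyquist/2] cycles avoids both.  ``n_samples`` defaults to
    ``sampling_scale * ln(u_max/u_min) * sqrt(u_min*u_max) / du``, i.e.
    about two-thirds of a spectral sample per log step at the geometric
    band center.
    """
    mag = spec.magnitude
    if preprocess is not None:
        mag = preprocess(mag)
    n = mag.shape[0]
    if n % 2 == 0:
        raise ValueError("spectrum must be odd-sided (DC on a pixel)")
    k = n // 2  # quadrant side in spectral samples
    # sample spacing in wavenumber units (pad-aware via the stored axes)
    du = float(spec.u_axis[1] - spec.u_axis[0])
    nyquist = k * du
    if u_max is None:
        u_max = nyquist / 2.0
    if not (0 < u_min < u_max <= nyquist):
        raise ValueError(
            f"band [{u_min}, {u_max}] invalid or exceeds the Nyquist extent {nyquist}"
        )
    if n_samples is None:
        n_samples = max(
            int(sampling_scale * np.log(u_max / u_min) * np.sqrt(u_min * u_max) / du), 32
        )
    if n_samples < 32:
        raise ValueError("n_samples must be >= 32")
    if n_samples > 2 * k:
        raise ValueError(
            f"n_samples={n_samples} exceeds the available Nyquist extent (quadrant side {k})"
        )
    log_step = np.log(u_max / u_min) / (n_samples - 1)
    wn = u_min * np.exp(log_step * np.arange(n_samples))
    # quadrant sub-arrays oriented with wavenumber increasing right/down
    c = k  # DC index
    quads = {
        1: mag[c + 1:, c + 1:],
        2: mag[c + 1:, c - 1::-1],
        3: mag[c - 1::-1, c - 1::-1],
        4: mag[c - 1::-1, c + 1:],
    }
    # wavenumber w sits at quadrant array index w/du - 1
    idx = wn / du - 1.0
    jj, ii = np.meshgrid(idx, idx, indexing="ij")
    out = []
    for qid in (1, 2, 3, 4):
        vals = ndimage.map_coordinates(quads[qid], [jj, ii], order=1, mode="nearest")
        out.append(LogSpectralImage(values=vals, log_step=float(log_step), quadrant_id=qid))
    return tuple(out)


def estimate_envelope_diameter(img: np.ndarray) -> float:
    """Estimate the spectral-envelope effective diameter (in FFT samples)
    from the autocorrelation peak width of ``img``.

    The mean full width at half maximum of the central autocorrelation peak
    gives the characteristic speckle/texture size ``sigma_b``; the matched
    Gaussian magnitude spectrum then has e^-2 diameter ``2*n/(pi*sigma_b)``
    samples, which parameterizes the dynamic phase-filter envelope.
    """
    img = np.asarray(img, dtype=float)
    a = img - img.mean()
    power = np.abs(fft2(a)) ** 2
    r = fftshift(np.real(ifft2(power)))
    n = img.shape[0]
    c0 = n // 2
    peak = r[c0, c0]
    if peak <= 0:
        raise ValueError("degenerate (constant) image; no autocorrelation peak")

    def _fwhm(profile: np.ndarray) -> float:
        half = peak / 2.0
        # walk right from the center until the profile drops below half
        for i in range(1, len(profile)):
            if profile[i] < half:
                p0, p1 = profile[i - 1], profile[i]
                frac = (p0 - half) / (p0 - p1) if p0 != p1 else 0.0
                return 2.0 * (i - 1 + frac)
        return 2.0 * (len(profile) - 1)

    w_row = _fwhm(r[c0, c0:])
    w_col = _fwhm(r[c0:, c0])
    fwhm = 0.5 * (w_row + w_col)
    # autocorrelation of a Gaussian of std sigma_b has std sigma_b*sqrt(2)
    sigma_b = max(fwhm / (2.355 * np.sqrt(2.0)), 0.3)
    return float(2.0 * n / (np.pi * sigma_b))


def dynamic_phase_filter(cross_spectrum: np.ndarray, effective_diameter: float) -> np.ndarray:
    """Phase-normalize a cross-power spectrum and re-weight it with a
    DC-centered Gaussian spectral-energy envelope.

    Each element is divided by its own magnitude (zeros pass as zeros), then
    multiplied by ``exp(-rho^2 / (2*sigma^2))`` where ``rho`` is the
    DC-centered radial sample index and ``sigma = effective_diameter / 4``
    (so the envelope's e^-2 diameter equals ``effective_diameter``).  An
    infinite diameter reduces to plain phase correlation.
    """
    cs = np.asarray(cross_spectrum, dtype=complex)
    if effective_diameter <= 0:
        raise ValueError("effective_diameter must be positive")
    mag = np.abs(cs)
    if not np.any(mag > 0):
        raise ValueError("all-zero cross spectrum")
    phase = np.where(mag > 0, cs / np.where(mag > 0, mag, 1.0), 0.0)
    if not np.isfinite(effective_diameter):
        return phase
    ny, nx = cs.shape
    fy = np.fft.fftfreq(ny) * ny
    fx = np.fft.fftfreq(nx) * nx
    rho2 = fy[:, None] ** 2 + fx[None, :] ** 2
    sigma = effective_diameter / 4.0
    env = np.exp(-rho2 / (2.0 * sigma**2))
    return phase * env


def peak_ratio(plane: np.ndarray, exclusion: int = 5) -> float:
    """Primary-to-secondary peak height ratio of a correlation plane.

    The secondary peak is the maximum outside a ``(2*exclusion+1)``-sided
    neighborhood of the primary; values are measured above the plane
    minimum so the ratio is always >= 1.
    """
    p = np.asarray(plane, dtype=float)
    jmax, imax = np.unravel_index(np.argmax(p), p.shape)
    base = p.min()
    primary = p[jmax, imax] - base
    masked = p.copy()
    j0, j1 = max(0, jmax - exclusion), min(p.shape[0], jmax + exclusion + 1)
    i0, i1 = max(0, imax - exclusion), min(p.shape[1], imax + exclusion + 1)
    masked[j0:j1, i0:i1] = -np.inf
    secondary = masked.max() - base
    if not np.isfinite(secondary) or secondary <= 0:
        return np.inf
    return float(max(primary / secondary, 1.0))


def subpixel_peak(plane: np.ndarray) -> tuple[float, float]:
    """Subpixel correlation-peak location relative to the plane center.

    The integer argmax is refined independently per axis by a three-point
    Gaussian fit; when neighbor values are non-positive the fit falls back
    to a parabolic one.  Errors if the peak sits on the plane border or the
    plane is flat / has tied global maxima.
    """
    p = np.asarray(plane, dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("flat correlation plane; no peak")
    pmax = p.max()
    ties = np.count_nonzero(p == pmax)
    if ties > 1:
        raise ValueError(f"{ties} tied correlation maxima; peak ambiguous")
    jmax, imax = np.unravel_index(np.argmax(p), p.shape)
    ny, nx = p.shape
    if jmax in (0, ny - 1) or imax in (0, nx - 1):
        raise ValueError("correlation peak on the plane border")

    def _refine(m1: float, c0: float, p1: float) -> float:
        if m1 > 0 and c0 > 0 and p1 > 0:
            lm, lc, lp = np.log(m1), np.log(c0), np.log(p1)
        else:
            lm, lc, lp = m1, c0, p1
        denom = lm + lp - 2.0 * lc
        if denom == 0:
            return 0.0
        return float(np.clip((lm - lp) / (2.0 * denom), -1.0, 1.0))

    dx = _refine(p[jmax, imax - 1], p[jmax, imax], p[jmax, imax + 1])
    dy = _refine(p[jmax - 1, imax], p[jmax, imax], p[jmax + 1, imax])
    cy, cx = ny // 2, nx // 2
    return (imax + dx - cx, jmax + dy - cy)


def spectral_correlate(
    a: np.ndarray,
    b: np.ndarray,
    phase_filter: bool = True,
    envelope_diameter: float | None = None,
) -> CorrelationPlane:
    """Spectral cross-correlation of two equally-sized real images.

    Computes the inverse FT of the conjugate spectral product (the peak at
    ``(dx, dy)`` means ``b`` is ``a`` shifted right/down by that amount),
    optionally applying the dynamic phase filter to the cross spectrum.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    fa = fft2(a - a.mean())
    fb = fft2(b - b.mean())
    cs = np.conj(fa) * fb
    # bins with negligible energy carry no phase information; zero them so
    # they do not inject noise after phase normalization
    cs[np.abs(cs) < 1e-12 * np.abs(cs).max()] = 0.0
    if phase_filter:
        if envelope_diameter is None:
            envelope_diameter = estimate_envelope_diameter(a)
        cs = dynamic_phase_filter(cs, envelope_diameter)
    plane = fftshift(np.real(ifft2(cs)))
    shift = subpixel_peak(plane)
    return CorrelationPlane(values=plane, peak_shift=shift, peak_ratio=peak_ratio(plane))


def ensemble_correlate(
    pairs: list[tuple[LogSpectralImage, LogSpectralImage]],
    phase_filter: bool = True,
    envelope_diameter: float | None = None,
) -> CorrelationPlane:
    """Ensemble phase correlation over matched log-spectral quadrant pairs.

    Each quadrant pair is spectrally cross-correlated with the dynamic
    phase filter applied to its cross spectrum; the real correlation planes
    are averaged sample-wise and the subpixel peak of the mean plane is the
    ensemble shift estimate.

    On log-magnitude images the autocorrelation-width envelope estimate
    collapses (they are smooth), and any narrow envelope broadens the peak
    enough to bias the subpixel fit toward zero shift; the default is
    therefore an unbounded envelope, i.e. pure phase correlation.
    """
    if not pairs:
        raise ValueError("no quadrant pairs supplied")
    shape = pairs[0][0].values.shape
    step = pairs[0][0].log_step
    planes = []
    for la, lb in pairs:
        if la.values.shape != shape or lb.values.shape != shape:
            raise ValueError("quadrant size mismatch")
        if not np.isclose(la.log_step, step) or not np.isclose(lb.log_step, step):
            raise ValueError("quadrant log_step mismatch")
        env = envelope_diameter if envelope_diameter is not None else np.inf
        cp = spectral_correlate(la.values, lb.values, phase_filter=phase_filter,
                                envelope_diameter=env)
        planes.append(cp.values)
    mean_plane = np.mean(planes, axis=0)
    shift = subpixel_peak(mean_plane)
    return CorrelationPlane(values=mean_plane, peak_shift=shift, peak_ratio=peak_ratio(mean_plane))


# --------------------------------------------------------------------------
# strain-rate conversion and the per-pair driver
# --------------------------------------------------------------------------

def shift_to_strain_rate(dy_samples: float, log_step: float, frame_interval: float) -> float:
    """Convert a vertical log-axis shift into a strain rate (1/s).

    ``dy' = dy_samples * log_step`` is the natural-log scale change between
    the pair; the per-pair strain is ``exp(dy') - 1`` and the rate divides
    by the frame interval.  Shortening (scale < 1, dy' < 0) gives a negative
    rate.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    return float((np.exp(dy_samples * log_step) - 1.0) / frame_interval)


def _log_compress(mag: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    """Log-compress a magnitude spectrum and lightly smooth it.

    The raw magnitude fluctuates multiplicatively (spectral speckle with
    O(1) relative variance); log compression turns that into an additive
    floor so the scale-covariant structure dominates the correlation, and
    a one-sample Gaussian blur regularizes the cusps at spectral zeros
    before bilinear resampling.
    """
    out = np.log(mag + 1e-9)
    if smooth > 0:
        out = ndimage.gaussian_filter(out, smooth)
    return out


# The per-pair log-shift is measured as the peak of the log-domain
# correlation profile, evaluated lag by lag: for each log-spaced scale
# hypothesis the second spectrum is rescaled in the *linear* wavenumber
# domain (with a small fixed subsample grid offset) and correlated against
# the first over a fixed annulus.  Resampling both spectra onto one shared
# log grid and phase-correlating instead leaves grid-anchored artifacts
# that are identical in the two frames and attract the peak to zero shift
# once the per-pair shift is subsample-sized; rescaling per hypothesis
# never shares a grid, so no such attractor exists.

_SCAN_GRID_OFFSET = 0.37  # subsample offset decorrelating resampler artifacts


def _prep_log_spectrum(frame: np.ndarray, window: bool, hp: float, crop: int) -> np.ndarray:
    """Padded DC-centered log-magnitude, smoothed, high-passed, cropped to
    the central (2*crop+1) square."""
    spec = ft_magnitude(frame, window=window)
    m = _log_compress(spec.magnitude)
    m = m - ndimage.gaussian_filter(m, hp)
    k = m.shape[0] // 2
    crop = min(crop, k)
    return m[k - crop:k + crop + 1, k - crop:k + crop + 1]


def _scan_scores(
    ma: np.ndarray,
    mb: np.ndarray,
    weights: np.ndarray,
    lags: np.ndarray,
    log_step: float,
    mode: str,
) -> np.ndarray:
    """Normalized correlation of ``ma`` against rescaled ``mb`` per lag.

    ``mode`` selects which spectral axes the hypothesis rescales:
    'iso' (both), 'v' (vertical) or 'h' (horizontal).
    """
    k = ma.shape[0] // 2
    wsum = weights.sum()
    maw = ma * weights
    maw = maw - maw.sum() / wsum * weights
    na = np.sqrt((maw * maw).sum())
    scores = np.empty(len(lags))
    for i, j in enumerate(lags):
        rho = np.exp(j * log_step)
        rv = rho if mode in ("iso", "v") else 1.0
        rh = rho if mode in ("iso", "h") else 1.0
        mat = np.array([[rv, 0.0], [0.0, rh]])
        off = np.array([k - rv * k + _SCAN_GRID_OFFSET, k - rh * k + _SCAN_GRID_OFFSET])
        z = ndimage.affine_transform(mb, mat, offset=off, order=1)
        zw = z * weights
        zw = zw - zw.sum() / wsum * weights
        nb = np.sqrt((zw * zw).sum())
        scores[i] = (maw * zw).sum() / (na * nb) if na > 0 and nb > 0 else 0.0
    return scores


def _score_peak(scores: np.ndarray, lags: np.ndarray, log_step: float) -> tuple[float, float]:
    """Subsample peak of a score curve -> (ln rho_hat, peak score).

    NaN when the peak sits on the scan border or the curve is not locally
    concave (no reliable maximum).
    """
    jm = int(np.argmax(scores))
    if jm in (0, len(lags) - 1):
        return np.nan, float(scores[jm])
    m1, c0, p1 = scores[jm - 1], scores[jm], scores[jm + 1]
    den = m1 + p1 - 2.0 * c0
    if den >= 0:
        return np.nan, float(c0)
    dj = 0.5 * (m1 - p1) / den
    return float((lags[jm] + dj) * log_step), float(c0)


def pairwise_strain(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    band: tuple[float, float] = (0.06, 0.25),
    log_step: float = 0.004,
    n_lags: int = 14,
    window: bool = True,
    hp_sigma: float = 6.0,
    row_filter_strength: float = 0.0,
) -> tuple[float, float, float, float]:
    """Per-pair log-axis shifts and strain for one registered frame pair.

    Returns ``(dx_prime, dy_prime, eps, quality)`` where ``dx'``/``dy'``
    are the horizontal/vertical natural-log scale changes of frame_b
    relative to frame_a, ``eps = exp(dy') - 1`` is the vertical
    (longitudinal) per-pair strain, and ``quality`` is the peak correlation
    score of the accepted scan.

    ``band`` is the spectral annulus used, in cycles per pixel: below
    ~0.06 the aperture and clutter dominate, above ~0.25 the speckle
    envelope has decayed.  Scale hypotheses span ``+-n_lags*log_step``
    (about +-5.7 % by default) on a log grid.

    Axis coupling: single-axis scans on isotropically deforming content
    are biased (the unmatched axis drags the peak), while the isotropic
    scan is exact there; conversely an isotropic scan on single-axis
    deformation splits the change between axes.  Both single-axis scans
    and the isotropic scan are therefore evaluated, and the isotropic
    reading is used when the two axis readings agree (isotropic-looking
    deformation), the axis readings otherwise.
    """
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share a shape")
    n = frame_a.shape[0]
    pad = 2
    r_lo = band[0] * n * pad
    r_hi = band[1] * n * pad
    crop = int(np.ceil(r_hi)) + 2
    ma = _prep_log_spectrum(frame_a, window, hp_sigma, crop)
    mb = _prep_log_spectrum(frame_b, window, hp_sigma, crop)
    k = ma.shape[0] // 2
    yy, xx = np.mgrid[0:2 * k + 1, 0:2 * k + 1]
    r = np.hypot(xx - k, yy - k)
    weights = ((r >= r_lo) & (r <= r_hi)).astype(float)
    if row_filter_strength > 0.0:
        # attenuate low-vertical-wavenumber content (broad horizontal
        # structures surviving the ROI, e.g. RV free wall / LA remnants)
        low_v = np.abs(yy - k) < r_lo
        weights[low_v] *= 1.0 - row_filter_strength
    lags = np.arange(-n_lags, n_lags + 1)

    d_iso, q_iso = _score_peak(_scan_scores(ma, mb, weights, lags, log_step, "iso"),
                               lags, log_step)
    d_v, q_v = _score_peak(_scan_scores(ma, mb, weights, lags, log_step, "v"),
                           lags, log_step)
    d_h, q_h = _score_peak(_scan_scores(ma, mb, weights, lags, log_step, "h"),
                           lags, log_step)

    if np.isnan(d_v) and np.isnan(d_iso):
        return (np.nan, np.nan, np.nan, 0.0)
    # the deformation family that matches the data scores highest: an
    # isotropic scan on single-axis deformation (or vice versa) leaves one
    # axis mismatched and its peak correlation lower
    if not np.isnan(d_v) and not np.isnan(d_iso):
        isotropic = q_iso >= max(q_v, q_h)
    else:
        isotropic = np.isnan(d_v)
    if isotropic:
        dv, dh, q = d_iso, d_iso, q_iso
    else:
        dv = d_v
        dh = d_h if not np.isnan(d_h) else 0.0
        q = q_v
    # the hypothesis rescales B's spectrum; a spatial contraction by s (<1)
    # dilates the spectrum by 1/s, so dy' = ln(s) = -ln(rho_hat)
    dx_prime = -dh
    dy_prime = -dv
    eps = float(np.exp(dy_prime) - 1.0)
    return (float(dx_prime), float(dy_prime), eps, float(q))


def _attenuate_low_rows(q: LogSpectralImage, strength: float) -> LogSpectralImage:
    """Attenuate the low-vertical-wavenumber rows of a log sub-image.

    Suppresses broad horizontal structures (right-ventricular free wall and
    left-atrial remnants) that survive the circular ROI.  ``strength`` in
    [0, 1] scales the attenuation depth; the profile rises from
    ``1 - strength`` at the lowest row to 1 over the first quarter of rows.
    """
    n = q.values.shape[0]
    ramp = np.ones(n)
    k = max(n // 4, 1)
    ramp[:k] = 1.0 - strength * (1.0 - np.arange(k) / k)
    return LogSpectralImage(values=q.values * ramp[:, None], log_step=q.log_step,
                            quadrant_id=q.quadrant_id)


def pairwise_glsr(
    regseq,
    row_filter_strength: float = 0.0,
    max_failed_fraction: float = 0.25,
    **scan_kwargs,
) -> StrainRateSeries:
    """Per-pair GLSr over a registered sequence.

    Measures the vertical log-magnitude scale shift of every consecutive
    frame pair (:func:`pairwise_strain`) and converts it to a strain rate
    (:func:`shift_to_strain_rate`).  Failed pairs are flagged NaN with a
    logged warning; more than ``max_failed_fraction`` failures raises.
    """
    frames = regseq.frames
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 frames")
    dt = regseq.frame_interval
    glsr = np.full(n - 1, np.nan)
    shifts = np.full((n - 1, 2), np.nan)
    quality = np.full(n - 1, np.nan)
    for i in range(n - 1):
        try:
            dx_p, dy_p, eps, q = pairwise_strain(
                frames[i], frames[i + 1],
                row_filter_strength=row_filter_strength, **scan_kwargs,
            )
        except ValueError as exc:  # degenerate pair: flag and continue
            logger.warning("frame pair %d failed: %s", i, exc)
            continue
        if np.isnan(dy_p):
            logger.warning("frame pair %d: no reliable correlation peak", i)
            continue
        glsr[i] = shift_to_strain_rate(dy_p, 1.0, dt)
        shifts[i] = (dx_p, dy_p)
        quality[i] = q
    n_failed = int(np.isnan(glsr).sum())
    if n_failed > max_failed_fraction * (n - 1):
        raise RuntimeError(f"{n_failed}/{n - 1} frame pairs failed correlation")
    times = (np.arange(n - 1) + 0.5) * dt
    return StrainRateSeries(times=times, glsr=glsr, log_shifts=shifts, quality=quality)
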