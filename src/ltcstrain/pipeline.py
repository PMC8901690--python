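"""End-to-end analysis drivers tying the modules into one call.

``analyze_ltc`` runs the full direct-estimation chain on a beat: landmark
tracking, rigid co-registration with the circular LV ROI, per-pair
logarithm-transform correlation, RK4 integration and drift correction.
``analyze_ste`` runs a block-matching baseline (DCC or FTC): displacement
fields, RK4 boundary advection, and arc-length GLS.  Both return the GLS
series, the per-pair GLSr series, and the clinical scalar metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import ltc_core, registration, ste_baselines, strain_series
from .io_frames import FrameSequence

__all__ = ["LtcResult", "analyze_ltc", "analyze_ste"]


@dataclass
class LtcResult:
    """Bundle of per-frame GLS, per-pair GLSr, and scalar metrics."""

    gls: strain_series.StrainSeries
    glsr: ltc_core.StrainRateSeries
    metrics: strain_series.ScalarMetrics
    method: str


def analyze_ltc(
    seq: FrameSequence,
    initial_landmarks: registration.Landmarks,
    tracking_window: int = 96,
    track_smoothing: float = 0.0,
    row_filter_strength: float = 0.0,
    roi_factor: float = 1.3,
) -> LtcResult:
    """Direct GLS/GLSr estimation by logarithm-transform correlation.

    ``track_smoothing`` optionally applies a Gaussian smoother (std in
    frames) to the landmark track before registration; off by default —
    the strain kernel is translation invariant, so tracking jitter is
    harmless, while smoothing lags the track during rapid motion.
    """
    track = registration.track_landmarks(seq, initial_landmarks, window=tracking_window)
    if track_smoothing > 0:
        from scipy.ndimage import gaussian_filter1d
        track = registration.LandmarkTrack(
            positions=gaussian_filter1d(track.positions, track_smoothing, axis=0, mode="nearest")
        )
    regseq = registration.register_frames(seq, track, roi_factor=roi_factor)
    rates = ltc_core.pairwise_glsr(regseq, row_filter_strength=row_filter_strength)
    gls = strain_series.integrate_glsr(rates, seq.frame_interval)
    gls = strain_series.drift_correct(gls)
    gls = replace(gls, meta="ltc")
    metrics = strain_series.peak_metrics(gls, rates)
    return LtcResult(gls=gls, glsr=rates, metrics=metrics, method="ltc")


def analyze_ste(
    seq: FrameSequence,
    initial_boundary: np.ndarray,
    kernel: str = "dcc",
    window: int = 32,
    overlap: float = 0.75,
) -> LtcResult:
    """Baseline speckle-tracking GLS via boundary arc-length change."""
    fields = [
        ste_baselines.displacement_field(seq.frames[k], seq.frames[k + 1],
                                         window=window, overlap=overlap, kernel=kernel)
        for k in range(seq.n_frames - 1)
    ]
    track = ste_baselines.propagate_boundary(initial_boundary, fields, seq.frame_interval)
    gls = ste_baselines.arc_length_gls(track, seq.frame_interval, meta=kernel)
    # per-pair rate from the (pre-drift-corrected) strain increments
    raw = ste_baselines.arc_length_gls(track, seq.frame_interval, meta=kernel,
                                       apply_drift_correction=False)
    glsr_vals = np.diff(raw.gls) / 100.0 / seq.frame_interval
    rates = ltc_core.StrainRateSeries(
        times=(np.arange(len(glsr_vals)) + 0.5) * seq.frame_interval, glsr=glsr_vals
    )
    metrics = strain_series.peak_metrics(gls, rates)
    return LtcResult(gls=gls, glsr=rates, metrics=metrics, method=kernel)
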