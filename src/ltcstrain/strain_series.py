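"""Temporal integration of strain rate into strain and clinical scalars.

Per-pair GLSr estimates are integrated over the beat with classic
fourth-order Runge-Kutta (the integral acts as a smoother), a linear drift
ramp is removed so the strain returns to zero at the undeformed end of the
beat, and the clinical scalar metrics — peak absolute GLS (GLS_P, %) and
peak absolute systolic GLSr (GLSrs, 1/s) — are extracted and averaged
across apical views.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .ltc_core import StrainRateSeries

__all__ = [
    "StrainSeries",
    "ScalarMetrics",
    "integrate_glsr",
    "drift_correct",
    "peak_metrics",
    "average_views",
]


@dataclass
class StrainSeries:
    """Per-frame Lagrange strain in % of the reference length.

    ``times`` start at 0 on the reference (zero-strain) frame and
    ``gls[0] == 0``.
    """

    times: np.ndarray
    gls: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gls = np.asarray(self.gls, dtype=float)
        if self.times.shape != self.gls.shape:
            raise ValueError("times and gls must have equal length")
        if len(self.gls) < 2:
            raise ValueError("need at least 2 samples")
        if abs(self.gls[0]) > 1e-9:
            raise ValueError("gls must start at 0 on the reference frame")

    def __len__(self) -> int:
        return len(self.gls)


@dataclass
class ScalarMetrics:
    """Clinical scalars: peak |GLS| (%) and peak systolic |GLSr| (1/s)."""

    gls_p: float
    glsrs: float

    def __post_init__(self) -> None:
        if self.gls_p < 0 or self.glsrs < 0:
            raise ValueError("peak metrics are absolute values, >= 0")


def _fill_gaps(glsr: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN-flagged failed pairs (endpoints held)."""
    out = glsr.copy()
    bad = np.isnan(out)
    if bad.all():
        raise ValueError("no valid strain-rate samples to integrate")
    if bad.any():
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def integrate_glsr(rates: StrainRateSeries, frame_interval: float) -> StrainSeries:
    """Integrate a per-pair GLSr series into per-frame GLS (%).

    Classic RK4 with step equal to the frame interval; the rate at the RK4
    substep times is obtained by cubic interpolation of the (midpoint-timed)
    rate series, extrapolated at the two half-frame ends.  Gap-flagged
    (NaN) pairs are linearly interpolated first.
    """
    if len(rates) == 0:
        raise ValueError("empty strain-rate series")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    glsr = _fill_gaps(rates.glsr)
    if len(glsr) == 1:
        rate = lambda t: np.full_like(np.asarray(t, dtype=float), glsr[0])  # noqa: E731
    else:
        rate = CubicSpline(rates.times, glsr, extrapolate=True)
    n_frames = len(glsr) + 1
    h = frame_interval
    gls = np.zeros(n_frames)
    for k in range(n_frames - 1):
        t = k * h
        k1 = rate(t)
        k2 = rate(t + h / 2)
        k3 = k2
        k4 = rate(t + h)
        gls[k + 1] = gls[k] + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return StrainSeries(times=np.arange(n_frames) * h, gls=gls * 100.0)


def drift_correct(series: StrainSeries) -> StrainSeries:
    """Remove the accumulated integration drift.

    Subtracts a linear-in-time ramp running from 0 at the reference frame
    to the final value at the last frame, so the strain ends exactly at the
    undeformed state.  Idempotent.
    """
    t = series.times
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("degenerate time axis")
    ramp = series.gls[-1] * (t - t[0]) / span
    return replace(series, gls=series.gls - ramp)


def peak_metrics(
    series: StrainSeries,
    rates: StrainRateSeries,
    systole_end: float | None = None,
) -> ScalarMetrics:
    """Peak absolute GLS and peak absolute systolic GLSr.

    ``systole_end`` bounds the strain-rate search; when valve timing is not
    available it defaults to the time of peak |GLS| (the end-systolic
    surrogate).
    """
    if len(series) == 0 or len(rates) == 0:
        raise ValueError("empty inputs")
    gls_p = float(np.max(np.abs(series.gls)))
    if systole_end is None:
        systole_end = float(series.times[int(np.argmax(np.abs(series.gls)))])
    if not (series.times[0] <= systole_end <= series.times[-1]):
        raise ValueError("systole_end outside the record")
    in_systole = rates.times <= systole_end
    if not in_systole.any():
        in_systole[0] = True  # degenerate: earliest pair stands in
    valid = np.abs(rates.glsr[in_systole])
    glsrs = float(np.nanmax(valid)) if np.any(np.isfinite(valid)) else 0.0
    return ScalarMetrics(gls_p=gls_p, glsrs=glsrs)


def average_views(metrics: list[ScalarMetrics]) -> ScalarMetrics:
    """Arithmetic mean of scalar metrics across apical views.

    Repeated measurements within a view are expected to be pre-averaged by
    the caller.
    """
    if not metrics:
        raise ValueError("no metrics to average")
    return ScalarMetrics(
        gls_p=float(np.mean([m.gls_p for m in metrics])),
        glsrs=float(np.mean([m.glsrs for m in metrics])),
    )
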