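"""Signal conditioning chain for raw IMU blocks.

The chain has three stages, applied channel-wise in fixed order:

1. **PCHIP interpolation** onto a uniform grid at the nominal rate.  Wireless
   links drop and jitter samples; a shape-preserving piecewise cubic Hermite
   interpolant restores uniform sampling without overshooting between knots.
2. **Zero-phase Butterworth low-pass** (2nd order, 10 Hz cut-off by default,
   applied forward-backward).  Wrist rotation lives near 2 Hz; everything
   above 10 Hz is sensor noise.  Zero-phase application matters because the
   metrics depend on peak timing.
3. **Scalar Kalman smoothing** with a local-level (random-walk state) model
   per channel.  This is a light final denoising pass: with the default
   automatic noise parameters its gain stays near 1 for the band-limited
   rotation signal and well below 1 for residual wide-band noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .io_model import IMU_CHANNELS, ImuSeries

__all__ = [
    "WristBlockSeries",
    "interpolate_pchip",
    "butterworth_lowpass",
    "kalman_smooth",
    "estimate_noise_variance",
    "preprocess_block",
]


@dataclass
class WristBlockSeries:
    """A conditioned single-wrist, single-block series on a uniform grid.

    ``provenance`` records the applied conditioning steps in order.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    rate: float
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) >= 2 else 0.0


def _as_uniform_series(series: ImuSeries) -> None:
    dt = np.diff(series.t)
    if dt.size and not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise ValueError("series must be uniformly sampled; interpolate first")


def interpolate_pchip(series: ImuSeries, rate: float | None = None) -> ImuSeries:
    """Resample every channel onto a uniform grid spanning [t0, t_end].

    Uses the shape-preserving piecewise cubic Hermite interpolant, which
    passes through every sample and introduces no overshoot on monotone
    segments.
    """
    if len(series) < 2:
        raise ValueError(f"need >= 2 samples to interpolate, got {len(series)}")
    rate = rate or series.nominal_rate
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t0, t1 = float(series.t[0]), float(series.t[-1])
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    out = {}
    for ch in IMU_CHANNELS:
        out[ch] = PchipInterpolator(series.t, getattr(series, ch))(grid)
    return ImuSeries(t=grid, nominal_rate=rate, **out)


def butterworth_lowpass(
    series: ImuSeries, cutoff: float = 10.0, order: int = 2
) -> ImuSeries:
    """Zero-phase (forward-backward) Butterworth low-pass on every channel.

    The forward-backward pass squares the magnitude response and cancels the
    phase, so a noiseless sinusoid keeps its peak times.  Edges are handled by
    odd reflection over one settling length (the ``filtfilt`` default).
    """
    _as_uniform_series(series)
    rate = series.nominal_rate
    if not 0 < cutoff < rate / 2:
        raise ValueError(
            f"cutoff must be in (0, Nyquist={rate / 2} Hz), got {cutoff}"
        )
    b, a = butter(order, cutoff, btype="low", fs=rate)
    out = {ch: filtfilt(b, a, getattr(series, ch)) for ch in IMU_CHANNELS}
    return ImuSeries(t=series.t, nominal_rate=rate, **out)


def estimate_noise_variance(x: np.ndarray) -> float:
    """Robust white-noise variance estimate from second differences.

    For white noise the second difference has variance ``6 sigma^2``; for a
    smooth band-limited signal the second difference is small, so the
    estimator isolates the noise floor without being fooled by the signal's
    own slope.  Uses the median absolute deviation for outlier robustness.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return 0.0
    d2 = np.diff(x, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    sigma = mad / 0.6745 / np.sqrt(6.0)
    return float(sigma**2)


def kalman_smooth(
    series: ImuSeries, q: float | None = None, r: float | None = None
) -> ImuSeries:
    """Per-channel scalar Kalman filter with a local-level state model.

    The state is the underlying channel level, modelled as a random walk with
    process-noise variance ``q``; the measurement noise variance is ``r``.
    Defaults: ``q = 1e-2 * var(channel)`` (the level can move a few percent of
    the signal's spread per step) and ``r`` estimated per channel from second
    differences (:func:`estimate_noise_variance`).

    Large ``q / r`` drives the steady-state gain toward 1 (trust the
    measurement); small ``q / r`` smooths harder.
    """
    _as_uniform_series(series)
    if q is not None and q <= 0:
        raise ValueError("q must be > 0")
    if r is not None and r <= 0:
        raise ValueError("r must be > 0")
    out = {}
    for ch in IMU_CHANNELS:
        y = getattr(series, ch)
        if y.size == 0:
            out[ch] = y.copy()
            continue
        q_ch = q if q is not None else max(1e-2 * float(np.var(y)), 1e-12)
        r_ch = r if r is not None else max(estimate_noise_variance(y), 1e-12)
        out[ch] = _kalman_local_level(y, q_ch, r_ch)
    res = ImuSeries(t=series.t, nominal_rate=series.nominal_rate, **out)
    return res


def _kalman_local_level(y: np.ndarray, q: float, r: float) -> np.ndarray:
    xhat = np.empty_like(y)
    x = y[0]
    p = r
    for i, yi in enumerate(y):
        p = p + q
        k = p / (p + r)
        x = x + k * (yi - x)
        p = (1.0 - k) * p
        xhat[i] = x
    return xhat


def preprocess_block(
    raw: ImuSeries,
    rate: float | None = None,
    cutoff: float = 10.0,
    order: int = 2,
    q: float | None = None,
    r: float | None = None,
) -> WristBlockSeries:
    """Run the full conditioning chain on one raw block segment.

    Order: PCHIP interpolation -> zero-phase Butterworth -> Kalman smoothing,
    with each applied step recorded in the output's provenance.
    """
    if len(raw) < 2:
        raise ValueError(f"block segment too short ({len(raw)} samples)")
    step1 = interpolate_pchip(raw, rate)
    step2 = butterworth_lowpass(step1, cutoff=cutoff, order=order)
    step3 = kalman_smooth(step2, q=q, r=r)
    provenance = ["pchip", f"butterworth({order},{cutoff:g}Hz)", "kalman"]
    return WristBlockSeries(
        t=step3.t,
        ax=step3.ax,
        ay=step3.ay,
        az=step3.az,
        gx=step3.gx,
        gy=step3.gy,
        gz=step3.gz,
        rate=step3.nominal_rate,
        provenance=provenance,
    )
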