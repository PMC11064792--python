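"""Synthetic wrist-rotation-imitation session generator.

No public recordings of the WRI task exist, so every downstream stage is
exercised against sessions synthesised here.  The generator models what the
task actually produces: an oscillatory pronation/supination of each wrist at
roughly 2 Hz, sustained for some fraction of each 20-second block, with the
non-dominant wrist lagging the dominant one in amplitude and frequency.  Group
presets encode the direction of the clinical findings — autistic children
sustain the rotation for less time, rotate through a smaller angle, and are
less symmetric between wrists — so that cohort-level analyses on simulated
data recover those contrasts.

The kinematic model per wrist is

    theta(t) = Theta_w * w(tau) * sin(2 pi f_w tau)

with ``tau`` the time since block onset and ``w`` an envelope that is 1 until
``sustain_s`` then ramps to 0 over 1 s (raised cosine).  The gyroscope y-axis
reports the analytic derivative d(theta)/dt plus bias and white noise; the
accelerometer reports gravity re-projected through theta (rotation about the
wrist axis) plus white noise.  Rest periods are noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io_model import (
    AGE_BANDS,
    ImuSeries,
    ProtocolSchedule,
    SessionRecording,
)

__all__ = [
    "SimParams",
    "GroupPreset",
    "DEFAULT_PRESETS",
    "STUDY_CELL_COUNTS",
    "simulate_session",
    "simulate_cohort",
]

RAMP_S = 1.0  # envelope ramp-down length after sustain_s, seconds


@dataclass(frozen=True)
class SimParams:
    """Per-participant generative parameters.

    theta_amp : peak rotation angle Theta of the dominant wrist, deg
    freq : rotation frequency, Hz (the task pace is ~2)
    sustain_s : seconds of sustained rotation within each block
    lr_amp_ratio / lr_freq_ratio : non-dominant over dominant wrist
        amplitude / frequency, each in (0, 1]
    gyro_noise_sd : white gyroscope noise, deg/s
    accel_noise_sd : white accelerometer noise, g
    gyro_bias : constant offset on the rotation-axis gyro channel, deg/s
    seed : RNG seed for the noise draws
    """

    theta_amp: float = 45.0
    freq: float = 2.0
    sustain_s: float = 20.0
    lr_amp_ratio: float = 1.0
    lr_freq_ratio: float = 1.0
    gyro_noise_sd: float = 8.0
    accel_noise_sd: float = 0.05
    gyro_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_amp <= 0:
            raise ValueError("theta_amp must be > 0")
        if self.freq <= 0:
            raise ValueError("freq must be > 0")
        if self.sustain_s < 0:
            raise ValueError("sustain_s must be >= 0")
        for name in ("lr_amp_ratio", "lr_freq_ratio"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def _envelope(tau: np.ndarray, sustain_s: float, block_duration: float) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine sustain envelope w(tau) and its derivative, on block-local time."""
    w = np.zeros_like(tau)
    dw = np.zeros_like(tau)
    sustain = min(sustain_s, block_duration)
    on = tau < sustain
    w[on] = 1.0
    ramp = (tau >= sustain) & (tau < sustain + RAMP_S)
    u = (tau[ramp] - sustain) / RAMP_S
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * u))
    dw[ramp] = -0.5 * np.pi / RAMP_S * np.sin(np.pi * u)
    return w, dw


def _wrist_signals(
    t: np.ndarray,
    schedule: ProtocolSchedule,
    theta_amp: float,
    freq: float,
    sustain_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic rotation angle theta(t) [deg] and its derivative [deg/s]."""
    theta = np.zeros_like(t)
    dtheta = np.zeros_like(t)
    period = schedule.block_duration + schedule.rest_duration
    for k in range(schedule.n_blocks):
        start, end = schedule.block_window(k)
        in_block = (t >= start) & (t < end)
        tau = t[in_block] - start
        w, dw = _envelope(tau, sustain_s, schedule.block_duration)
        phase = 2.0 * np.pi * freq * tau
        theta[in_block] = theta_amp * w * np.sin(phase)
        dtheta[in_block] = theta_amp * (
            dw * np.sin(phase) + w * 2.0 * np.pi * freq * np.cos(phase)
        )
    return theta, dtheta


def simulate_session(
    params: SimParams,
    schedule: ProtocolSchedule | None = None,
    group: str = "TD",
    participant_id: str = "sim",
    age_months: float = 60.0,
    rate: float = 50.0,
) -> SessionRecording:
    """Generate one dual-wrist session; deterministic given ``params.seed``.

    The right wrist is the dominant one (all study participants were
    right-handed): it rotates at the full ``theta_amp``/``freq``; the left
    wrist is scaled down by the left/right ratios.
    """
    schedule = schedule or ProtocolSchedule()
    rng = np.random.default_rng(params.seed)
    n = int(round(schedule.total_duration * rate)) + 1
    t = np.arange(n) / rate

    wrists: dict[str, ImuSeries] = {}
    for wrist, amp_scale, freq_scale in (
        ("right", 1.0, 1.0),
        ("left", params.lr_amp_ratio, params.lr_freq_ratio),
    ):
        theta, dtheta = _wrist_signals(
            t,
            schedule,
            params.theta_amp * amp_scale,
            params.freq * freq_scale,
            params.sustain_s,
        )
        gy = dtheta + params.gyro_bias
        if params.gyro_noise_sd > 0:
            gy = gy + rng.normal(0.0, params.gyro_noise_sd, n)
        gx = rng.normal(0.0, params.gyro_noise_sd, n) if params.gyro_noise_sd > 0 else np.zeros(n)
        gz = rng.normal(0.0, params.gyro_noise_sd, n) if params.gyro_noise_sd > 0 else np.zeros(n)
        # Gravity seen through a rotation of theta about the wrist (y) axis.
        th = np.deg2rad(theta)
        ax = -np.sin(th)
        ay = np.zeros(n)
        az = np.cos(th)
        if params.accel_noise_sd > 0:
            ax = ax + rng.normal(0.0, params.accel_noise_sd, n)
            ay = ay + rng.normal(0.0, params.accel_noise_sd, n)
            az = az + rng.normal(0.0, params.accel_noise_sd, n)
        wrists[wrist] = ImuSeries(
            t=t, ax=ax, ay=ay, az=az, gx=gx, gy=gy, gz=gz, nominal_rate=rate
        )

    return SessionRecording(
        participant_id=participant_id,
        group=group,
        age_months=age_months,
        left=wrists["left"],
        right=wrists["right"],
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPreset:
    """Population of :class:`SimParams` for one group: means plus coefficients
    of variation for the log-normal per-participant draws.

    ``age_amp_scale`` applies a multiplicative amplitude gradient across the
    three age bands (youngest to oldest), reflecting that rotation amplitude
    grows with age while sustain time and symmetry do not.
    """

    mean: SimParams
    sustain_cv: float = 0.35
    amp_cv: float = 0.25
    ratio_cv: float = 0.10
    freq_cv: float = 0.05
    age_amp_scale: tuple[float, float, float] = (0.9, 1.0, 1.1)


#: Group presets for the cohort simulator.  Typically-developing children
#: sustain the full block at a wide amplitude with near-symmetric wrists;
#: autistic children stop earlier, rotate less, and are less symmetric.
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "TD": GroupPreset(
        mean=SimParams(theta_amp=60.0, sustain_s=20.0, lr_amp_ratio=0.95, lr_freq_ratio=0.95),
        sustain_cv=0.50,
        ratio_cv=0.10,
    ),
    "ASD": GroupPreset(
        mean=SimParams(theta_amp=40.0, sustain_s=11.5, lr_amp_ratio=0.75, lr_freq_ratio=0.75),
        sustain_cv=0.80,
        ratio_cv=0.18,
    ),
}

#: Cell sizes of the study cohort (age band -> {group -> n}); totals 108.
STUDY_CELL_COUNTS: dict[str, dict[str, int]] = {
    "3.5-4.5": {"ASD": 15, "TD": 19},
    "4.5-5.5": {"ASD": 15, "TD": 20},
    "5.5-6.5": {"ASD": 19, "TD": 20},
}

#: Age (months) mean and sd per band, used to draw ages within each band.
_AGE_DISTRIBUTIONS = {
    "3.5-4.5": (48.9, 3.82),
    "4.5-5.5": (59.3, 3.21),
    "5.5-6.5": (71.5, 3.82),
}


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw from a log-normal with the given arithmetic mean and CV."""
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _draw_params(
    rng: np.random.Generator, preset: GroupPreset, band_index: int, base: SimParams
) -> SimParams:
    amp = _lognormal(rng, preset.mean.theta_amp, preset.amp_cv)
    amp *= preset.age_amp_scale[band_index]
    sustain = _lognormal(rng, preset.mean.sustain_s, preset.sustain_cv)
    freq = _lognormal(rng, preset.mean.freq, preset.freq_cv)
    amp_ratio = np.clip(_lognormal(rng, preset.mean.lr_amp_ratio, preset.ratio_cv), 0.05, 1.0)
    freq_ratio = np.clip(_lognormal(rng, preset.mean.lr_freq_ratio, preset.ratio_cv), 0.05, 1.0)
    return replace(
        base,
        theta_amp=amp,
        freq=freq,
        sustain_s=sustain,
        lr_amp_ratio=float(amp_ratio),
        lr_freq_ratio=float(freq_ratio),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_cohort(
    n_per_cell: int | Mapping[str, Mapping[str, int]] = None,
    presets: Mapping[str, GroupPreset] | None = None,
    seed: int = 0,
    schedule: ProtocolSchedule | None = None,
) -> list[SessionRecording]:
    """Simulate a 2 (group) x 3 (age band) cohort.

    Parameters
    ----------
    n_per_cell : int or mapping
        Either a single per-cell count, or ``{age_band: {group: n}}`` (e.g.
        :data:`STUDY_CELL_COUNTS`, which mirrors the study's demographic
        table and totals 108 children).  Defaults to the study counts.
    presets : mapping group -> GroupPreset
        Parameter populations per group; defaults to :data:`DEFAULT_PRESETS`.
    seed : int
        Master seed; the whole cohort is deterministic given it.
    """
    presets = dict(presets) if presets is not None else DEFAULT_PRESETS
    for g in ("ASD", "TD"):
        if g not in presets:
            raise ValueError(f"preset for group {g!r} missing")
    if n_per_cell is None:
        counts = STUDY_CELL_COUNTS
    elif isinstance(n_per_cell, int):
        counts = {band: {"ASD": n_per_cell, "TD": n_per_cell} for band in AGE_BANDS}
    else:
        counts = {b: dict(v) for b, v in n_per_cell.items()}
    schedule = schedule or ProtocolSchedule()
    rng = np.random.default_rng(seed)

    sessions: list[SessionRecording] = []
    idx = 0
    for band_index, band in enumerate(AGE_BANDS):
        cell = counts.get(band, {})
        lo, hi = AGE_BANDS[band]
        age_mean, age_sd = _AGE_DISTRIBUTIONS[band]
        for group in ("ASD", "TD"):
            for _ in range(int(cell.get(group, 0))):
                params = _draw_params(rng, presets[group], band_index, presets[group].mean)
                age = float(np.clip(rng.normal(age_mean, age_sd), lo, hi - 1e-6))
                sessions.append(
                    simulate_session(
                        params,
                        schedule=schedule,
                        group=group,
                        participant_id=f"P{idx:03d}",
                        age_months=age,
                    )
                )
                idx += 1
    return sessions
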