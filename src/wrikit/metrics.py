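"""The three wrist-rotation-imitation metrics: TRT, RoA and Symmetry.

All three are computed per 20-second imitation block from the conditioned
rotation-axis angular velocity ``gy`` (deg/s), and a participant's value for
each metric is the **maximum over the three blocks**.

* **Total rotation time (TRT)** — seconds of sustained rotation within a
  block, measured as the time the moving-RMS activity envelope of ``gy``
  stays above an activity threshold.  Longer TRT = better sustained
  imitation.
* **Rotation amplitude (RoA)** — the mean absolute rotation angle between
  adjacent extrema of the integrated angle trace,

      RoA = 1/(N-1) * sum_i | integral_{P_i}^{P_{i+1}} omega(t) dt |,

  i.e. the average per-half-cycle swing, in degrees.  ``P_i`` are the angle
  extrema (equivalently the zero crossings of omega) and ``N`` their count.
* **Symmetry** — agreement of rotation between the wrists,

      Symmetry = (1 - 0.7*|RoA_l - RoA_r|/max(RoA_l, RoA_r)
                    - 0.3*|RoF_l - RoF_r|/max(RoF_l, RoF_r))^2,

  clipped to [0, 1], where RoF is the rotation frequency (full cycles per
  second) estimated from the extrema count.  1 means identical wrists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .io_model import SessionRecording, segment_blocks
from .preprocess import WristBlockSeries, preprocess_block

__all__ = [
    "ExtremaSequence",
    "WristCycleStats",
    "WriFeatures",
    "detect_angle_extrema",
    "compute_rotation_amplitude",
    "compute_rotation_frequency",
    "compute_total_rotation_time",
    "compute_symmetry",
    "block_cycle_stats",
    "extract_features",
]

#: Weights of the amplitude and frequency terms in the Symmetry formula.
SYM_W_AMP = 0.7
SYM_W_FREQ = 0.3


@dataclass(frozen=True)
class ExtremaSequence:
    """Extrema of the integrated rotation-angle trace of one block."""

    times: np.ndarray  # seconds, strictly increasing
    angles: np.ndarray  # deg, detrended integrated angle at each extremum

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.size != a.size:
            raise ValueError("times and angles must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("extrema times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)

    @property
    def n_extrema(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class WristCycleStats:
    """Per-wrist, per-block rotation statistics entering Symmetry."""

    roa: float  # deg, >= 0
    rof: float  # Hz, >= 0
    trt: float  # seconds within [0, block duration]
    wrist: str = ""


@dataclass(frozen=True)
class WriFeatures:
    """Per-participant feature triple: max over blocks of each metric."""

    trt: float
    roa: float
    symmetry: float
    low_motion: bool = False


def integrated_angle(block: WristBlockSeries) -> np.ndarray:
    """Rotation angle trace (deg): trapezoid-integrated gy, linearly detrended.

    The linear detrend removes the ramp a constant gyro bias would leave in
    the integral, so extrema amplitudes are bias-invariant.
    """
    theta = cumulative_trapezoid(block.gy, block.t, initial=0.0)
    if theta.size >= 2:
        coef = np.polyfit(block.t, theta, 1)
        theta = theta - np.polyval(coef, block.t)
    return theta


def detect_angle_extrema(
    block: WristBlockSeries,
    prominence_deg: float = 10.0,
    min_gap_s: float = 0.15,
) -> ExtremaSequence:
    """Locate the angle extrema P_i of one conditioned block.

    Integrates gy to an angle trace, detrends it, then finds local maxima and
    minima with prominence >= ``prominence_deg`` (rejects noise wiggles) and
    spacing >= ``min_gap_s`` (safe for ~2 Hz rotation, whose extrema are
    0.25 s apart).  An empty sequence is a valid result for a motionless
    block.
    """
    theta = integrated_angle(block)
    if theta.size < 3:
        return ExtremaSequence(times=np.empty(0), angles=np.empty(0))
    distance = max(1, int(round(min_gap_s * block.rate)))
    maxima, _ = find_peaks(theta, prominence=prominence_deg, distance=distance)
    minima, _ = find_peaks(-theta, prominence=prominence_deg, distance=distance)
    idx = np.sort(np.concatenate([maxima, minima]))
    return ExtremaSequence(times=block.t[idx], angles=theta[idx])


def compute_rotation_amplitude(ext: ExtremaSequence) -> float:
    """RoA (deg): mean absolute angle change between adjacent extrema.

    With fewer than 2 extrema there is no rotation to average; the metric is
    reported as 0 (callers flag this via :class:`WriFeatures.low_motion`).
    """
    if ext.n_extrema < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(ext.angles))))


def compute_rotation_frequency(ext: ExtremaSequence, duration: float) -> float:
    """RoF (Hz): full rotation cycles per second from the extrema sequence.

    Adjacent extrema are half a cycle apart, so the ``n-1`` inter-extrema
    intervals spanning ``times[-1] - times[0]`` seconds contain
    ``(n-1)/2`` cycles.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if ext.n_extrema < 2:
        return 0.0
    span = float(ext.times[-1] - ext.times[0])
    if span <= 0:
        return 0.0
    return (ext.n_extrema - 1) / (2.0 * span)


def compute_total_rotation_time(
    block: WristBlockSeries,
    window_s: float = 0.5,
    threshold_floor_dps: float = 15.0,
    threshold_frac: float = 0.2,
    gap_tol_s: float = 0.5,
) -> float:
    """TRT (s): time the gy activity envelope stays above threshold.

    The envelope is a centred moving RMS of gy over ``window_s``.  The
    activity threshold adapts to the block —
    ``max(threshold_floor_dps, threshold_frac * 95th percentile of the
    envelope)`` — so it sits well above the noise floor of a quiet block yet
    scales with vigorous rotation.  Pauses shorter than ``gap_tol_s`` are
    bridged: a momentary hesitation does not split the rotation bout.
    """
    if len(block) == 0:
        return 0.0
    size = max(1, int(round(window_s * block.rate)))
    rms = np.sqrt(uniform_filter1d(block.gy**2, size=size, mode="nearest"))
    threshold = max(threshold_floor_dps, threshold_frac * np.percentile(rms, 95))
    active = rms > threshold
    if gap_tol_s > 0 and active.any():
        active = _bridge_gaps(active, max_len=int(round(gap_tol_s * block.rate)))
    dt = 1.0 / block.rate
    return float(min(active.sum() * dt, block.duration + dt))


def _bridge_gaps(active: np.ndarray, max_len: int) -> np.ndarray:
    """Fill inactive runs shorter than ``max_len`` samples between active runs."""
    out = active.copy()
    idx = np.flatnonzero(np.diff(active.astype(int)) == -1)
    for start in idx:
        nxt = np.flatnonzero(active[start + 1 :])
        if nxt.size == 0:
            break
        gap = nxt[0]
        if gap < max_len:
            out[start + 1 : start + 1 + gap] = True
    return out


def compute_symmetry(left: WristCycleStats, right: WristCycleStats) -> float:
    """Symmetry in [0, 1] from both wrists' RoA and RoF.

    Each normalised difference term is defined as 0 when both of its
    arguments are 0 (no motion on either wrist contributes no asymmetry);
    the squared result is clipped to [0, 1].
    """

    def ratio(a: float, b: float) -> float:
        m = max(a, b)
        if m == 0:
            return 0.0
        return abs(a - b) / m

    val = 1.0 - SYM_W_AMP * ratio(left.roa, right.roa) - SYM_W_FREQ * ratio(
        left.rof, right.rof
    )
    return float(np.clip(val, 0.0, 1.0) ** 2)


def block_cycle_stats(
    block: WristBlockSeries,
    wrist: str = "",
    prominence_deg: float = 10.0,
    min_gap_s: float = 0.15,
    **trt_kwargs,
) -> WristCycleStats:
    """RoA, RoF and TRT of a single conditioned block."""
    ext = detect_angle_extrema(block, prominence_deg=prominence_deg, min_gap_s=min_gap_s)
    duration = max(block.duration, 1.0 / block.rate)
    return WristCycleStats(
        roa=compute_rotation_amplitude(ext),
        rof=compute_rotation_frequency(ext, duration),
        trt=compute_total_rotation_time(block, **trt_kwargs),
        wrist=wrist,
    )


def extract_features(
    session: SessionRecording,
    wrist_policy: str = "right",
    prominence_deg: float = 10.0,
    min_gap_s: float = 0.15,
    cutoff_hz: float = 10.0,
    order: int = 2,
) -> WriFeatures:
    """Per-participant WRI features: max over blocks of TRT, RoA, Symmetry.

    Each wrist's raw series is segmented into the protocol blocks and
    conditioned; TRT and RoA are taken from the dominant (right) wrist
    (all participants were right-handed), or from the better wrist per block
    with ``wrist_policy='max'``; Symmetry uses both wrists.  If no block of
    the scoring wrist shows two angle extrema the participant is flagged
    ``low_motion`` and scored (0, 0, 0).
    """
    if wrist_policy not in ("right", "max"):
        raise ValueError("wrist_policy must be 'right' or 'max'")
    left_blocks = segment_blocks(session.left, session.schedule)
    right_blocks = segment_blocks(session.right, session.schedule)

    trts, roas, syms = [], [], []
    any_motion = False
    for lb, rb in zip(left_blocks, right_blocks):
        lp = preprocess_block(lb, cutoff=cutoff_hz, order=order)
        rp = preprocess_block(rb, cutoff=cutoff_hz, order=order)
        ls = block_cycle_stats(lp, "left", prominence_deg, min_gap_s)
        rs = block_cycle_stats(rp, "right", prominence_deg, min_gap_s)
        if wrist_policy == "right":
            scoring = rs
            if rs.roa > 0:
                any_motion = True
        else:
            scoring = max((ls, rs), key=lambda s: s.roa)
            if max(ls.roa, rs.roa) > 0:
                any_motion = True
        trts.append(scoring.trt)
        roas.append(scoring.roa)
        syms.append(compute_symmetry(ls, rs))

    if not any_motion:
        return WriFeatures(trt=0.0, roa=0.0, symmetry=0.0, low_motion=True)
    return WriFeatures(
        trt=float(max(trts)),
        roa=float(max(roas)),
        symmetry=float(max(syms)),
        low_motion=False,
    )
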