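"""Sensor calibration: accelerometer least-squares fit and gyroscope Allan deviation.

Before each experiment the sensors sit static on a table; those static
recordings drive two standard characterisations.  The accelerometer is fitted
with a per-axis bias and diagonal scale so that the corrected static readings
have magnitude 1 g in any orientation.  The gyroscope's noise processes are
profiled with the overlapping Allan deviation, whose log-log slope identifies
the noise type (-1/2 white angle-rate noise, +1/2 rate random walk).

Calibration is optional in the analysis pipeline — simulated data is born
calibrated — and is applied when a calibration file accompanies a recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .io_model import ImuSeries

__all__ = [
    "AccelCalibration",
    "AllanCurve",
    "IdentifiabilityError",
    "fit_accel_calibration",
    "apply_accel_calibration",
    "allan_deviation",
]


class IdentifiabilityError(ValueError):
    """Too few or too-degenerate static poses to identify bias and scale."""


@dataclass(frozen=True)
class AccelCalibration:
    """Accelerometer correction: corrected = scale * (raw - bias), per axis."""

    bias: tuple[float, float, float]
    scale: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.bias) != 3 or len(self.scale) != 3:
            raise ValueError("bias and scale must be 3-vectors")
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale components must be > 0")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Correct an (n, 3) array of raw accelerometer samples (g)."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.bias)) * np.asarray(self.scale)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"bias": list(self.bias), "scale": list(self.scale)}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AccelCalibration":
        d = json.loads(Path(path).read_text())
        return cls(bias=tuple(d["bias"]), scale=tuple(d["scale"]))


@dataclass(frozen=True)
class AllanCurve:
    """Overlapping Allan deviation per averaging time tau."""

    taus: np.ndarray  # seconds, strictly increasing
    adev: np.ndarray  # deg/s, >= 0

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        adev = np.asarray(self.adev, dtype=float)
        if taus.size != adev.size:
            raise ValueError("taus and adev must have equal length")
        if np.any(np.diff(taus) <= 0):
            raise ValueError("taus must be strictly increasing")
        if np.any(adev < 0):
            raise ValueError("adev must be non-negative")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "adev", adev)

    def slope(self, tau_min: float | None = None, tau_max: float | None = None) -> float:
        """Log-log slope of adev vs tau over an optional tau window."""
        mask = np.ones_like(self.taus, dtype=bool)
        if tau_min is not None:
            mask &= self.taus >= tau_min
        if tau_max is not None:
            mask &= self.taus <= tau_max
        x = np.log(self.taus[mask])
        y = np.log(np.maximum(self.adev[mask], 1e-300))
        return float(np.polyfit(x, y, 1)[0])


def _pose_means(static_poses: Sequence[ImuSeries | np.ndarray]) -> np.ndarray:
    means = []
    for pose in static_poses:
        if isinstance(pose, ImuSeries):
            means.append([pose.ax.mean(), pose.ay.mean(), pose.az.mean()])
        else:
            arr = np.asarray(pose, dtype=float)
            means.append(arr.mean(axis=0) if arr.ndim == 2 else arr)
    return np.asarray(means, dtype=float)


def fit_accel_calibration(
    static_poses: Sequence[ImuSeries | np.ndarray],
) -> AccelCalibration:
    """Least-squares bias + diagonal-scale accelerometer calibration.

    Each static pose contributes its mean reading ``a`` (in g); the fit
    minimises ``sum_poses (||s * (a - b)|| - 1)^2`` over bias ``b`` and scale
    ``s``.  At least 6 poses with distinct orientations are required for the
    6 parameters to be identifiable.

    Raises
    ------
    IdentifiabilityError
        Fewer than 6 poses, or poses whose orientations do not constrain all
        six parameters (rank-deficient Jacobian at the solution).
    """
    a = _pose_means(static_poses)
    if a.shape[0] < 6:
        raise IdentifiabilityError(
            f"need >= 6 static poses for bias+scale, got {a.shape[0]}"
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        b, s = x[:3], x[3:]
        return np.linalg.norm(s * (a - b), axis=1) - 1.0

    x0 = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    jac_rank = np.linalg.matrix_rank(sol.jac, tol=1e-8)
    if jac_rank < 6:
        raise IdentifiabilityError(
            f"pose set is degenerate: Jacobian rank {jac_rank} < 6 "
            "(orientations do not span enough directions)"
        )
    return AccelCalibration(bias=tuple(sol.x[:3]), scale=tuple(sol.x[3:]))


def apply_accel_calibration(series: ImuSeries, cal: AccelCalibration) -> ImuSeries:
    """Return a copy of the series with calibrated accelerometer channels."""
    xyz = cal.apply(np.column_stack([series.ax, series.ay, series.az]))
    return series.replace(ax=xyz[:, 0], ay=xyz[:, 1], az=xyz[:, 2])


def allan_deviation(
    signal: np.ndarray,
    rate: float,
    n_taus: int = 50,
) -> AllanCurve:
    """Overlapping Allan deviation of a rate signal (e.g. a gyro channel).

    Averaging times tau are log-spaced from ``2/rate`` to one ninth of the
    record length, so every cluster size has enough overlapping pairs for a
    stable estimate.

    Raises
    ------
    ValueError
        If the record is too short for even the smallest cluster.
    """
    y = np.asarray(signal, dtype=float)
    n = y.size
    if rate <= 0:
        raise ValueError("rate must be > 0")
    max_m = n // 9
    if max_m < 2:
        raise ValueError(
            f"signal of {n} samples too short for Allan analysis (need >= 18)"
        )
    ms = np.unique(
        np.round(np.logspace(np.log10(2), np.log10(max_m), n_taus)).astype(int)
    )
    # cumulative sum gives O(1) cluster means
    c = np.concatenate([[0.0], np.cumsum(y)])
    taus = []
    adevs = []
    for m in ms:
        ybar = (c[m:] - c[:-m]) / m  # overlapping cluster means
        d = ybar[m:] - ybar[:-m]
        if d.size < 1:
            continue
        avar = 0.5 * np.mean(d**2)
        taus.append(m / rate)
        adevs.append(np.sqrt(avar))
    return AllanCurve(taus=np.asarray(taus), adev=np.asarray(adevs))
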