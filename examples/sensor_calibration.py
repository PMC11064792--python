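"""Pre-experiment sensor characterisation: accelerometer fit + Allan deviation.

Fits a bias + diagonal-scale accelerometer calibration from eight static
poses of a deliberately mis-calibrated sensor, then profiles a noisy gyro
channel with the overlapping Allan deviation (white noise shows the classic
-1/2 log-log slope).
"""

import numpy as np

from wrikit import allan_deviation, fit_accel_calibration

rng = np.random.default_rng(0)

# static poses: gravity along +-x, +-y, +-z and two tilted directions
dirs = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
     [0, 0, 1], [0, 0, -1], [1, 1, 1], [-1, 1, -1]], float
)
dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
true_bias = np.array([0.02, -0.01, 0.03])   # g
true_scale = np.array([1.01, 0.99, 1.02])
poses = [u / true_scale + true_bias + rng.normal(0, 1e-4, 3) for u in dirs]

cal = fit_accel_calibration(poses)
print("fitted bias  (g):", np.round(cal.bias, 4), " true:", true_bias)
print("fitted scale    :", np.round(cal.scale, 4), " true:", true_scale)

gyro = rng.normal(0, 0.5, 120_000)  # 40 min of white rate noise at 50 Hz
curve = allan_deviation(gyro, rate=50.0)
print(f"Allan slope over short taus: {curve.slope(tau_max=10):+.2f} (white noise -> -0.5)")
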