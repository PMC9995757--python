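"""Switched-gain tilt observer: segment inclination + gyro-bias estimation.

Each body segment's sagittal tilt is estimated by fusing the
accelerometer (reliable at low frequency, where measured specific force
is dominated by gravity) with the pitch gyroscope (reliable at high
frequency, but biased).  The discrete observer propagates the gyro and
corrects toward the accelerometer-derived inclination:

    theta[k+1] = theta[k] + dt * (omega[k] - b[k]) + K_theta[k] * (theta_acc[k] - theta[k])
    b[k+1]     = b[k] - K_b[k] * (theta_acc[k] - theta[k])

with theta_acc = atan2(ax, az).  The correction gain switches by regime:
when the specific-force magnitude stays near gravity the segment is
quasi-static and the accelerometer is trusted (high gain); when it
deviates by more than a threshold the motion is dynamic, the gravity
direction is corrupted by linear acceleration, and the observer leans on
the gyro (low gain).  The bias state makes the estimate asymptotically
unbiased under constant gyro bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import GRAVITY, ImuTrace, Placement, SessionRecording, ValidationError

__all__ = ["ObserverGains", "TiltSeries", "estimate_tilt", "estimate_session_tilt"]


@dataclass(frozen=True)
class ObserverGains:
    """Gain schedule for the switched observer.

    Attributes
    ----------
    k_theta_high : accelerometer-trusting tilt gain per step (quasi-static regime)
    k_theta_low  : gyro-trusting tilt gain per step (dynamic regime)
    k_bias_ratio : bias gain as a fraction of the active tilt gain
    switch_threshold : |  ||accel|| - g | above which the dynamic regime engages, m/s^2

    Defaults are tuned for a 100 Hz grid (gains are per 10 ms step).
    """

    k_theta_high: float = 0.02
    k_theta_low: float = 0.002
    k_bias_ratio: float = 0.1
    switch_threshold: float = 1.5

    def __post_init__(self) -> None:
        if min(self.k_theta_high, self.k_theta_low, self.k_bias_ratio, self.switch_threshold) <= 0:
            raise ValidationError("observer gains and switch threshold must be positive")


@dataclass
class TiltSeries:
    """Observer output for one trace: tilt, bias trajectory, regime flags."""

    placement: Placement
    t: np.ndarray
    theta: np.ndarray  # rad, estimated sagittal tilt at every grid point
    bias: np.ndarray  # rad/s, gyro-bias estimate trajectory
    dynamic: np.ndarray  # bool, True where the low (gyro-trusting) gain was active
    gains: ObserverGains

    @property
    def bias_hat(self) -> float:
        """Final gyro-bias estimate, rad/s."""
        return float(self.bias[-1])


def estimate_tilt(trace: ImuTrace, gains: ObserverGains | None = None) -> TiltSeries:
    """Run the switched-gain observer over one uniformly sampled trace.

    Initialization: tilt from the first accelerometer sample, bias 0.
    Raises :class:`ValidationError` if the trace is not on a uniform grid.
    """
    gains = gains or ObserverGains()
    if len(trace) < 2:
        raise ValidationError("trace too short for tilt estimation")
    dts = np.diff(trace.t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=0, atol=1e-6):
        raise ValidationError("tilt estimation requires a uniform sampling grid")

    # gains are specified per 10 ms step; rescale for other grids
    scale = dt / 0.01
    k_hi = gains.k_theta_high * scale
    k_lo = gains.k_theta_low * scale

    ax, az = trace.accel[:, 0], trace.accel[:, 2]
    theta_acc = np.arctan2(ax, az)
    omega = trace.gyro[:, 1]
    dyn = np.abs(trace.accel_magnitude() - GRAVITY) > gains.switch_threshold
    k_theta = np.where(dyn, k_lo, k_hi)
    k_b = gains.k_bias_ratio * k_theta

    n = len(trace)
    theta = np.empty(n)
    bias = np.empty(n)
    theta[0] = theta_acc[0]
    bias[0] = 0.0
    for k in range(n - 1):
        innov = theta_acc[k] - theta[k]
        theta[k + 1] = theta[k] + dt * (omega[k] - bias[k]) + k_theta[k] * innov
        bias[k + 1] = bias[k] - k_b[k] * innov
    np.clip(theta, -np.pi, np.pi, out=theta)
    return TiltSeries(
        placement=trace.placement, t=trace.t.copy(), theta=theta, bias=bias,
        dynamic=dyn, gains=gains,
    )


def estimate_session_tilt(
    session: SessionRecording, gains: ObserverGains | None = None
) -> dict[Placement, TiltSeries]:
    """Tilt-estimate all five traces of a synchronized session."""
    return {p: estimate_tilt(tr, gains) for p, tr in session.traces.items()}
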