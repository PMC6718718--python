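"""Proportional myoelectric control of a simulated knee-exoskeleton joint.

The control chain mirrors the device architecture: the calibrated envelope
maps proportionally to a desired knee angle theta_d (Bias -> 0 deg, MVE ->
90 deg, capped at 60% effort so the training range is 0..54 deg); a PD
position controller turns the angle error into a desired velocity omega_d;
an inner PID velocity controller produces the motor command omega_com; and
a first-order velocity plant integrates the joint angle.

Angle convention: 0 deg is the seated posture (shank perpendicular to
thigh); 90 deg is full extension (thigh and shank in line); hyperextension
is negative.  Safety is layered as in the device: software range/speed
limits, simulated overtravel-limit switches that cut power at the
mechanical stops, and an emergency stop.  Numerical gains of the position
and velocity loops are artifacts of this simulation (chosen for a stable
loop with ~100 ms tracking lag), not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibrationResult

__all__ = [
    "MappingConfig",
    "ControllerGains",
    "PlantConfig",
    "JointState",
    "emg_to_angle",
    "pd_position",
    "pid_velocity",
    "plant_step",
    "emergency_stop",
    "reset_estop",
    "closed_loop_run",
]


@dataclass(frozen=True)
class MappingConfig:
    """Proportional EMG -> angle map: full Bias..MVE range spans 0..90 deg."""

    full_range_angle: float = 90.0
    min_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.full_range_angle <= self.min_angle:
            raise ValueError("full_range_angle must exceed min_angle")


@dataclass
class ControllerGains:
    """PD position / PID velocity gains plus the velocity-loop PID state."""

    pos_kp: float = 8.0     # 1/s: desired velocity per degree of angle error
    pos_kd: float = 0.05    # damping on measured velocity
    vel_kp: float = 1.0
    vel_ki: float = 5.0
    vel_kd: float = 0.0
    integrator_clamp: float = 200.0  # deg/s, anti-windup bound on ki * integral
    # mutable PID state
    integral: float = field(default=0.0, compare=False)
    prev_error: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if min(self.pos_kp, self.pos_kd, self.vel_kp, self.vel_ki, self.vel_kd) < 0:
            raise ValueError("controller gains must be nonnegative")
        if self.integrator_clamp <= 0:
            raise ValueError("integrator clamp must be positive")

    def reset_state(self) -> None:
        self.integral = 0.0
        self.prev_error = 0.0


@dataclass(frozen=True)
class PlantConfig:
    """Simulated joint: first-order velocity lag plus layered travel limits."""

    time_constant: float = 0.05   # s, velocity-loop lag
    omega_max: float = 120.0      # deg/s, software speed limit
    theta_min: float = 0.0        # deg, software range (training range)
    theta_max: float = 54.0
    mech_min: float = -10.0       # deg, limit-switch positions
    mech_max: float = 110.0
    dt: float = 0.005             # s, control/integration step (200 Hz)

    def __post_init__(self) -> None:
        if not (self.mech_min < self.theta_min < self.theta_max < self.mech_max):
            raise ValueError("require mech_min < theta_min < theta_max < mech_max")
        if self.dt <= 0 or self.omega_max <= 0 or self.time_constant <= 0:
            raise ValueError("dt, omega_max and time_constant must be positive")


@dataclass(frozen=True)
class JointState:
    theta_a: float = 0.0      # deg, actual joint angle
    omega_meas: float = 0.0   # deg/s, measured joint velocity
    powered: bool = True
    estop: bool = False


def emg_to_angle(
    envelope_value: float,
    calib: CalibrationResult,
    mapping: MappingConfig = MappingConfig(),
) -> float:
    """Proportional map with the fatigue cap.

    theta_d = range * clamp((env - bias) / (mve - bias), 0, effort_cap), so
    at defaults rest maps to 0 deg and envelopes at or above the 60% effort
    level (including MVE itself) map to 54 deg.
    """
    frac = (envelope_value - calib.bias) / calib.signal_range
    frac = min(max(frac, 0.0), calib.effort_cap)
    span = mapping.full_range_angle - mapping.min_angle
    return mapping.min_angle + span * frac


def pd_position(
    theta_d: float,
    theta_a: float,
    gains: ControllerGains,
    omega_meas: float = 0.0,
    omega_max: float = 120.0,
) -> float:
    """PD position loop: omega_d from angle error, derivative on measurement."""
    omega_d = gains.pos_kp * (theta_d - theta_a) - gains.pos_kd * omega_meas
    return min(max(omega_d, -omega_max), omega_max)


def pid_velocity(
    omega_d: float,
    omega_meas: float,
    gains: ControllerGains,
    dt: float,
    omega_max: float = 120.0,
) -> float:
    """Discrete PID velocity loop with clamped (anti-windup) integrator."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    err = omega_d - omega_meas
    gains.integral += err * dt
    if gains.vel_ki > 0:
        bound = gains.integrator_clamp / gains.vel_ki
        gains.integral = min(max(gains.integral, -bound), bound)
    deriv = (err - gains.prev_error) / dt
    gains.prev_error = err
    out = gains.vel_kp * err + gains.vel_ki * gains.integral + gains.vel_kd * deriv
    return min(max(out, -omega_max), omega_max)


def plant_step(state: JointState, omega_com: float, plant: PlantConfig) -> JointState:
    """One Euler step of the joint: velocity lag, range limits, power cutoff.

    Safety outcomes are returned as state, never raised: a software stop pins
    the angle and zeroes velocity; reaching a mechanical limit trips the
    simulated overtravel switch (powered = False).
    """
    if state.estop or not state.powered:
        return state
    omega_com = min(max(omega_com, -plant.omega_max), plant.omega_max)
    alpha = min(plant.dt / plant.time_constant, 1.0)
    omega = state.omega_meas + alpha * (omega_com - state.omega_meas)
    omega = min(max(omega, -plant.omega_max), plant.omega_max)
    theta = state.theta_a + omega * plant.dt
    powered = True
    if theta <= plant.mech_min:
        theta, omega, powered = plant.mech_min, 0.0, False
    elif theta >= plant.mech_max:
        theta, omega, powered = plant.mech_max, 0.0, False
    elif theta < plant.theta_min:
        theta, omega = plant.theta_min, 0.0
    elif theta > plant.theta_max:
        theta, omega = plant.theta_max, 0.0
    return replace(state, theta_a=theta, omega_meas=omega, powered=powered)


def emergency_stop(state: JointState) -> JointState:
    """Experimenter e-stop: power off, freeze the joint where it is."""
    return replace(state, estop=True, powered=False, omega_meas=0.0)


def reset_estop(state: JointState) -> JointState:
    return replace(state, estop=False, powered=True)


def closed_loop_run(
    envelope,
    calib: CalibrationResult,
    mapping: MappingConfig = MappingConfig(),
    gains: ControllerGains | None = None,
    plant: PlantConfig = PlantConfig(),
    initial: JointState = JointState(),
) -> tuple[np.ndarray, np.ndarray]:
    """Run mapping -> PD -> PID -> plant over an envelope sampled at 1/dt.

    Returns aligned (theta_d, theta_a) traces for tracking metrics.  The
    envelope is assumed sampled at the control rate ``1 / plant.dt``.
    """
    env = np.asarray(envelope, dtype=float)
    if env.ndim != 1 or env.size == 0:
        raise ValueError("envelope must be a non-empty 1-D sequence")
    g = replace(gains) if gains is not None else ControllerGains()
    g.reset_state()
    state = initial
    theta_d = np.empty(env.size)
    theta_a = np.empty(env.size)
    for k, e in enumerate(env):
        theta_d[k] = emg_to_angle(e, calib, mapping)
        omega_d = pd_position(theta_d[k], state.theta_a, g,
                              omega_meas=state.omega_meas, omega_max=plant.omega_max)
        omega_com = pid_velocity(omega_d, state.omega_meas, g, plant.dt,
                                 omega_max=plant.omega_max)
        state = plant_step(state, omega_com, plant)
        theta_a[k] = state.theta_a
    return theta_d, theta_a
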