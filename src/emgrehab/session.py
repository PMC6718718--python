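"""Closed-loop training sessions with a virtual subject.

Reproduces the study protocol in simulation: for each leg, a relax/contract
calibration run determines Bias and MVE, then ten game blocks of four lives
each are played with 30 s rests in between, and the legs are done in a
configurable order.  The human is replaced by a :class:`VirtualSubject`
that looks at the game state, picks the activation level that would center
the bird in the next gap, and pursues it with a first-order lag, a reaction
delay and multiplicative noise — the knobs that make one virtual subject
"better" than another.

The loop runs EMG synthesis, Kalman filtering, the proportional mapping and
the servo/plant at 200 Hz (the EMG rate) and ticks the game at 50 Hz with a
zero-order hold of the joint angle in between.  Everything derives from a
single master seed, so a session log is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import calibration as cal
from . import exo_control as exo
from . import game as gm
from . import kalman as kf
from . import metrics as mt
from . import synth_emg as se

__all__ = [
    "VirtualSubjectParams",
    "VirtualSubject",
    "SessionConfig",
    "BlockLog",
    "SessionLog",
    "subject_policy",
    "calibrate_leg",
    "run_block",
    "run_session",
]


@dataclass(frozen=True)
class VirtualSubjectParams:
    """Human stand-in: pursuit dynamics, reaction delay and motor noise."""

    reaction_delay: float = 0.15        # s before a new target is acted on
    pursuit_time_constant: float = 0.25  # s, first-order approach to target
    activation_noise_sd: float = 0.05   # multiplicative, fraction of level
    skill_drift_per_block: float = 0.0  # fractional noise decay per block
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reaction_delay < 0 or self.activation_noise_sd < 0:
            raise ValueError("delay and noise must be nonnegative")
        if self.pursuit_time_constant <= 0:
            raise ValueError("pursuit time constant must be positive")


def subject_policy(state: gm.GameState, config: gm.GameConfig,
                   full_range_angle: float = 90.0) -> float:
    """Target activation fraction that would center the bird in the next gap.

    Inverse of the bird-altitude and EMG-to-angle maps: gap center -> bird y
    -> knee angle -> fraction of the full (uncapped) Bias..MVE range.  A gap
    at mid-screen corresponds to 27 deg, i.e. activation 0.3.
    """
    y_target = gm.perfect_bird_y(state, config)
    frac = y_target / (config.screen_h - config.bird_size)
    theta = min(max(frac, 0.0), 1.0) * config.max_angle_deg
    return min(max(theta / full_range_angle, 0.0), 1.0)


class VirtualSubject:
    """Stateful pursuit of the policy target with delay and noise."""

    def __init__(self, params: VirtualSubjectParams, config: gm.GameConfig,
                 rng: np.random.Generator | None = None,
                 noise_scale: float = 1.0):
        self.params = params
        self.config = config
        self.rng = np.random.default_rng(params.seed) if rng is None else rng
        self.noise_scale = noise_scale
        self.activation = 0.0
        self._delay_buf: list[float] = []

    def step(self, state: gm.GameState, dt: float) -> float:
        """One control-rate step; returns the commanded activation in [0, 1]."""
        target = subject_policy(state, self.config)
        self._delay_buf.append(target)
        n_delay = max(1, round(self.params.reaction_delay / dt) + 1)
        while len(self._delay_buf) > n_delay:
            self._delay_buf.pop(0)
        delayed = self._delay_buf[0]
        if np.isfinite(self.params.pursuit_time_constant):
            gain = min(dt / self.params.pursuit_time_constant, 1.0)
            self.activation += gain * (delayed - self.activation)
        sd = self.params.activation_noise_sd * self.noise_scale
        noisy = self.activation * (1.0 + self.rng.normal(0.0, sd)) if sd else self.activation
        return min(max(noisy, 0.0), 1.0)


@dataclass(frozen=True)
class SessionConfig:
    blocks_per_leg: int = 10
    rest_between_blocks: float = 30.0   # s, recorded in the log, not slept
    leg_order: tuple[str, ...] = ("left", "right")
    hover_duration: float = 1.0         # s before auto-resume of the next life
    max_block_duration: float = 120.0   # s wall-time watchdog per block
    control_fs: float = 200.0           # Hz, EMG/control rate
    game_cfg: gm.GameConfig = field(default_factory=gm.GameConfig)
    filter_params: kf.FilterParams = field(default_factory=kf.FilterParams)
    protocol: cal.CalibrationProtocol = field(default_factory=cal.CalibrationProtocol)
    mapping: exo.MappingConfig = field(default_factory=exo.MappingConfig)
    gains: exo.ControllerGains = field(default_factory=exo.ControllerGains)
    plant: exo.PlantConfig = field(default_factory=exo.PlantConfig)
    effort_cap: float = cal.DEFAULT_EFFORT_CAP
    n_channels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks_per_leg < 1:
            raise ValueError("need at least one block per leg")


@dataclass
class BlockLog:
    """Event timeline of one block plus aligned angle traces."""

    events: list[gm.GameEvent]
    theta_d: np.ndarray
    theta_a: np.ndarray

    def events_to_jsonl(self) -> str:
        return "\n".join(json.dumps(ev.to_dict()) for ev in self.events)


@dataclass
class SessionLog:
    config_seed: int
    legs: dict  # leg -> {"calibration": dict, "blocks": [BlockMetrics dicts]}
    errors: list = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return sum(len(leg["blocks"]) for leg in self.legs.values())

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.config_seed, "legs": self.legs, "errors": self.errors},
            sort_keys=True,
        )


def calibrate_leg(channels: list[se.ChannelModel],
                  cfg: SessionConfig) -> cal.CalibrationResult:
    """Run the relax/contract pattern through synthesis and filtering."""
    pattern = se.mve_test_pattern(fs=cfg.control_fs)
    raw = se.synthesize_raw_emg(pattern, channels)
    env = kf.control_signal(kf.filter_trace(raw, cfg.filter_params))
    return cal.calibrate(env, cfg.control_fs, cfg.protocol, cfg.effort_cap)


def run_block(
    subject: VirtualSubject,
    calib: cal.CalibrationResult,
    channels: list[se.ChannelModel],
    cfg: SessionConfig,
    seed: int,
) -> tuple[BlockLog, mt.BlockMetrics]:
    """Play one block closed-loop until lives run out or the watchdog fires."""
    ss = np.random.SeedSequence(seed)
    synth_seeds = ss.generate_state(len(channels) + 1)
    synth = se.EmgSynthesizer(
        [replace(ch, seed=int(s)) for ch, s in zip(channels, synth_seeds)]
    )
    game_rng = np.random.default_rng(int(synth_seeds[-1]))
    bank = kf.KalmanBank(len(channels), cfg.filter_params)
    gains = replace(cfg.gains)
    gains.reset_state()
    joint = exo.JointState()
    state, game_rng = gm.new_game(cfg.game_cfg, game_rng)
    dt_ctrl = 1.0 / cfg.control_fs
    ticks_per_game = max(1, round(cfg.control_fs / cfg.game_cfg.tick_rate))
    dt_game = dt_ctrl * ticks_per_game

    events: list[gm.GameEvent] = [gm.GameEvent(0.0, "life_start")]
    theta_d_log, theta_a_log, mal_log = [], [], []
    hover_elapsed = 0.0
    k = 0
    max_steps = round(cfg.max_block_duration * cfg.control_fs)
    while state.phase != "over" and k < max_steps:
        a_cmd = subject.step(state, dt_ctrl)
        y = synth.sample(a_cmd)
        env = float(bank.step(y).mean())
        th_d = exo.emg_to_angle(env, calib, cfg.mapping)
        om_d = exo.pd_position(th_d, joint.theta_a, gains,
                               omega_meas=joint.omega_meas,
                               omega_max=cfg.plant.omega_max)
        om_c = exo.pid_velocity(om_d, joint.omega_meas, gains, dt_ctrl,
                                omega_max=cfg.plant.omega_max)
        joint = exo.plant_step(joint, om_c, cfg.plant)
        theta_d_log.append(th_d)
        theta_a_log.append(joint.theta_a)
        if state.phase == "flying":
            mal_log.append(float(mt.mal(env, calib)))
        k += 1
        if k % ticks_per_game == 0:
            bird_y = gm.angle_to_bird_y(joint.theta_a, cfg.game_cfg)
            state, evs = gm.game_tick(state, bird_y, dt_game, cfg.game_cfg, game_rng)
            events.extend(evs)
            if state.phase == "hover":
                hover_elapsed += dt_game
                if hover_elapsed >= cfg.hover_duration:
                    state = gm.resume(state, cfg.game_cfg)
                    events.append(gm.GameEvent(state.t, "life_start"))
                    hover_elapsed = 0.0
    if state.phase != "over":
        # watchdog: close the block (and the open flight) explicitly
        state.phase = "over"
        events.append(gm.GameEvent(state.t, "block_over", {"score": state.score}))
    log = BlockLog(events=events, theta_d=np.array(theta_d_log),
                   theta_a=np.array(theta_a_log))
    metrics = mt.BlockMetrics(
        score=state.score,
        mmal=mt.mmal(mal_log) if mal_log else 0.0,
        bat=mt.block_activation_time(events),
        mal_trace=np.array(mal_log),
    )
    return log, metrics


def run_session(
    cfg: SessionConfig = SessionConfig(),
    subject_params: VirtualSubjectParams | dict | None = None,
) -> SessionLog:
    """Full two-leg session: calibration then blocks_per_leg blocks per leg.

    ``subject_params`` may be a single parameter set (used for both legs) or
    a mapping leg -> params.  A failed calibration aborts that leg with a
    structured error record rather than an exception.
    """
    if subject_params is None:
        subject_params = VirtualSubjectParams()
    master = np.random.SeedSequence(cfg.seed)
    leg_seeds = master.generate_state(2 * len(cfg.leg_order) * (cfg.blocks_per_leg + 2))
    log = SessionLog(config_seed=cfg.seed, legs={})
    idx = 0
    for leg in cfg.leg_order:
        params = subject_params[leg] if isinstance(subject_params, dict) else subject_params
        channels = se.default_channels(cfg.n_channels, seed=int(leg_seeds[idx]))
        idx += 1
        try:
            calib = calibrate_leg(channels, cfg)
        except cal.InsufficientSignalRangeError as err:
            log.errors.append({"leg": leg, "stage": "calibration", "error": str(err)})
            log.legs[leg] = {"calibration": None, "blocks": []}
            continue
        subject = VirtualSubject(params, cfg.game_cfg,
                                 rng=np.random.default_rng(int(leg_seeds[idx])))
        idx += 1
        blocks = []
        for b in range(cfg.blocks_per_leg):
            decay = (1.0 - params.skill_drift_per_block) ** b
            subject.noise_scale = decay
            _, bm = run_block(subject, calib, channels, cfg, int(leg_seeds[idx]))
            idx += 1
            blocks.append(bm.to_dict())
        log.legs[leg] = {"calibration": calib.to_dict(), "blocks": blocks}
    return log
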