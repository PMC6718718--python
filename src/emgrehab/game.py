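"""Headless Flappy Bird training game driven by the simulated knee angle.

The bird (a 48 px axis-aligned square at a fixed horizontal station) rises
and falls proportionally to the knee joint angle: 0 deg is the bottom of
the screen, 54 deg (the effort-capped training range) the top.  Pipe pairs
appear at seeded-random heights; flying through a gap scores one point,
hitting a pipe costs one of the four lives per block and parks the bird in
a "hover" phase until the next life is started.  Difficulty grows linearly
with score — the gap narrows from 300 px to 190 px and the horizontal
speed rises to 2.5x — and freezes once the score exceeds 100.

Everything is deterministic given (seed, input trace); sounds and haptic
pulses are emitted as events, never rendered.  The y axis points up from
the screen bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameConfig",
    "PipePair",
    "GameState",
    "GameEvent",
    "difficulty",
    "angle_to_bird_y",
    "spawn_pipe",
    "new_game",
    "game_tick",
    "resume",
    "perfect_bird_y",
]


@dataclass(frozen=True)
class GameConfig:
    screen_w: float = 480.0
    screen_h: float = 800.0
    bird_size: float = 48.0
    gap_start: float = 300.0          # px, gap at score 0
    gap_end: float = 190.0            # px, gap at/after the difficulty cap
    speed_mult_end: float = 2.5       # horizontal speed multiplier at the cap
    difficulty_cap_score: int = 100   # score beyond which difficulty freezes
    base_speed: float = 120.0         # px/s at score 0
    pipe_width: float = 80.0
    pipe_spacing: float = 320.0       # px between successive pipe leading edges
    lives_per_block: int = 4
    vertical_margin: float = 60.0     # px kept clear at top and bottom
    tick_rate: float = 50.0           # Hz
    bird_station_frac: float = 0.2    # bird x position as a fraction of width
    max_angle_deg: float = 54.0       # knee angle mapped to the top of screen
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_end >= self.gap_start:
            raise ValueError("gap_end must be smaller than gap_start")
        if self.gap_start + 2 * self.vertical_margin > self.screen_h:
            raise ValueError("initial gap plus margins exceeds screen height")
        if self.bird_size >= self.gap_end:
            raise ValueError("bird must fit through the final gap")
        if self.lives_per_block < 1:
            raise ValueError("need at least one life per block")

    @property
    def bird_x(self) -> float:
        return self.bird_station_frac * self.screen_w

    @property
    def grace_distance(self) -> float:
        return self.pipe_spacing


@dataclass
class PipePair:
    x: float            # px, leading (left) edge
    gap_center: float   # px, from screen bottom
    gap_size: float
    scored: bool = False

    @property
    def gap_bottom(self) -> float:
        return self.gap_center - self.gap_size / 2.0

    @property
    def gap_top(self) -> float:
        return self.gap_center + self.gap_size / 2.0


@dataclass(frozen=True)
class GameEvent:
    time: float
    kind: str   # point | collision | life_lost | haptic_pulse | life_start | block_over
    payload: dict | None = None

    def to_dict(self) -> dict:
        d = {"t": self.time, "kind": self.kind}
        if self.payload is not None:
            d["payload"] = self.payload
        return d


@dataclass
class GameState:
    phase: str = "flying"   # flying | hover | over
    bird_y: float = 0.0
    score: int = 0
    lives_left: int = 4
    pipes: list[PipePair] = field(default_factory=list)
    elapsed_active: float = 0.0   # s spent flying
    t: float = 0.0                # s wall time within the block


def difficulty(score: int, config: GameConfig = GameConfig()) -> tuple[float, float]:
    """(speed multiplier, gap px) at a score; linear, frozen beyond the cap."""
    if score < 0:
        raise ValueError("score cannot be negative")
    frac = min(score, config.difficulty_cap_score) / config.difficulty_cap_score
    mult = 1.0 + (config.speed_mult_end - 1.0) * frac
    gap = config.gap_start - (config.gap_start - config.gap_end) * frac
    return mult, gap


def angle_to_bird_y(theta_deg: float, config: GameConfig = GameConfig()) -> float:
    """Map the knee angle to the bird's bottom edge, measured up from 0."""
    frac = min(max(theta_deg / config.max_angle_deg, 0.0), 1.0)
    return frac * (config.screen_h - config.bird_size)


def spawn_pipe(
    rng: np.random.Generator,
    config: GameConfig,
    current_score: int,
    rightmost_x: float | None = None,
) -> PipePair:
    """Spawn the next pipe pair at a uniform feasible gap height."""
    _, gap = difficulty(current_score, config)
    lo = config.vertical_margin + gap / 2.0
    hi = config.screen_h - config.vertical_margin - gap / 2.0
    if lo > hi:
        raise ValueError("no feasible gap position for this configuration")
    center = lo if lo == hi else float(rng.uniform(lo, hi))
    x = config.screen_w if rightmost_x is None else rightmost_x + config.pipe_spacing
    return PipePair(x=x, gap_center=center, gap_size=gap)


def _top_up_pipes(state: GameState, config: GameConfig, rng: np.random.Generator) -> None:
    """Keep at least one screen-width of pipe lookahead spawned."""
    horizon = config.screen_w + config.pipe_spacing
    while True:
        rightmost = max((p.x for p in state.pipes), default=None)
        if rightmost is not None and rightmost >= horizon:
            break
        state.pipes.append(spawn_pipe(rng, config, state.score, rightmost))


def new_game(config: GameConfig = GameConfig(),
             rng: np.random.Generator | None = None) -> tuple[GameState, np.random.Generator]:
    """Fresh block: full lives, bird at the floor, pipe field spawned."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    state = GameState(lives_left=config.lives_per_block)
    _top_up_pipes(state, config, rng)
    return state, rng


def game_tick(
    state: GameState,
    bird_y_input: float,
    dt: float,
    config: GameConfig,
    rng: np.random.Generator,
) -> tuple[GameState, list[GameEvent]]:
    """Advance the world by ``dt``; returns the state and any events.

    Hover/over phases advance wall time only.  During flight, pipes move
    left, collisions cost a life (collision + life_lost + haptic_pulse
    events) and cleanly passed pipes score one point each.
    """
    if not np.isfinite(bird_y_input):
        raise ValueError("bird_y_input must be finite")
    state.t += dt
    if state.phase != "flying":
        return state, []
    events: list[GameEvent] = []
    mult, _ = difficulty(state.score, config)
    dx = config.base_speed * mult * dt
    for p in state.pipes:
        p.x -= dx
    by = min(max(bird_y_input, 0.0), config.screen_h - config.bird_size)
    state.bird_y = by
    bx = config.bird_x
    hit = None
    for p in state.pipes:
        overlap_x = p.x < bx + config.bird_size and p.x + config.pipe_width > bx
        if overlap_x and (by < p.gap_bottom or by + config.bird_size > p.gap_top):
            hit = p
            break
    if hit is not None:
        state.lives_left -= 1
        events.append(GameEvent(state.t, "collision", {"pipe_x": hit.x}))
        events.append(GameEvent(state.t, "life_lost", {"lives_left": state.lives_left}))
        events.append(GameEvent(state.t, "haptic_pulse"))
        if state.lives_left <= 0:
            state.phase = "over"
            events.append(GameEvent(state.t, "block_over", {"score": state.score}))
        else:
            state.phase = "hover"
    else:
        for p in state.pipes:
            if not p.scored and p.x + config.pipe_width <= bx:
                p.scored = True
                state.score += 1
                events.append(GameEvent(state.t, "point", {"score": state.score}))
    state.pipes = [p for p in state.pipes if p.x + config.pipe_width > 0.0]
    _top_up_pipes(state, config, rng)
    state.elapsed_active += dt
    return state, events


def resume(state: GameState, config: GameConfig) -> GameState:
    """Start the next life after a hover (the space-key press, scripted).

    Unscored pipes within a grace distance ahead of the bird are cleared so
    the new life cannot begin inside an obstacle.
    """
    if state.phase != "hover":
        raise ValueError(f"can only resume from hover, not {state.phase!r}")
    if state.lives_left < 1:
        raise ValueError("no lives left to resume")
    clear_until = config.bird_x + config.bird_size + config.grace_distance
    state.pipes = [p for p in state.pipes if p.scored or p.x >= clear_until]
    state.phase = "flying"
    return state


def perfect_bird_y(state: GameState, config: GameConfig) -> float:
    """Oracle policy: center the bird in the next unpassed gap."""
    ahead = [p for p in state.pipes if p.x + config.pipe_width > config.bird_x]
    if not ahead:
        return state.bird_y
    nxt = min(ahead, key=lambda p: p.x)
    return nxt.gap_center - config.bird_size / 2.0
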