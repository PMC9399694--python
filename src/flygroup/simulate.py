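"""Agent-based simulator of fly group formation in a circular arena.

Each agent alternates between a walking state (correlated random walk with an
optional heading bias toward the centroid of visible neighbours) and a
stopping state (zero displacement plus small positional jitter emulating tracker
noise).  The propensity to stop grows with the number of neighbours inside
the proximal radius, which is the single mechanism that produces grouping:
agents that wander near others tend to stop there, and dense neighbourhoods
hold them.  The simulator is a test harness for the analysis pipeline, not a
model of fly cognition; its presets instantiate the strong-grouping,
weak-grouping and non-interacting regimes the analysis is meant to tell
apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectories import ChamberConfig, SpeciesParams, TrajectorySet, get_species


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one simulated chamber.

    Rate-like parameters (``stop_base_prob``, ``restart_prob``) are
    per-second probabilities, converted to per-frame via
    ``p_frame = 1 - (1 - p_sec)**(1/fps)``.  ``attraction_strength`` is the
    fraction of the bearing error toward the centroid of the neighbours
    within ``visual_range_mm`` corrected per second (0 disables attraction);
    seeking the visible centroid rather than a single fly makes larger
    aggregates proportionally more attractive.  ``stop_gain`` multiplies the
    stopping propensity by ``(1 + stop_gain)`` for every neighbour inside
    the proximal radius.  ``heading_persistence``
    in [0, 1] damps the per-frame heading noise: 1 is straight-line walking.
    ``refractory_s`` gives a fly that resumes walking a short free-walking
    bout (no attraction, no stopping, fresh random heading) before it
    re-engages with neighbours; without it a stopped pair is an absorbing
    state and clusters can never exchange members or merge.
    """

    species: SpeciesParams
    n_flies: int = 20
    duration_s: float = 1200.0
    fps: int = 30
    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    walk_speed_mm_s: float = 8.0
    heading_persistence: float = 0.95
    stop_base_prob: float = 0.05
    stop_gain: float = 0.0
    restart_prob: float = 0.5
    attraction_strength: float = 0.0
    visual_range_mm: float = 0.0
    refractory_s: float = 0.0
    stop_jitter_mm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        for name in ("stop_base_prob", "restart_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.walk_speed_mm_s < 0 or self.attraction_strength < 0:
            raise ValueError("speeds and attraction_strength must be >= 0")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValueError("heading_persistence must be in [0, 1]")


def _per_frame(p_sec: float, fps: int) -> float:
    return 1.0 - (1.0 - p_sec) ** (1.0 / fps)


#: Base heading-noise scale for a fully unpersistent walker (rad per frame).
_TURN_SD_RAD = 0.8


def simulate(config: SimConfig) -> TrajectorySet:
    """Run the simulation; deterministic for a given ``config.seed``.

    Returns a frame-rate :class:`TrajectorySet` that passes trajectory
    validation (all positions inside the chamber disc).  Ellipse fields are
    emitted as ``body_len x (1, 0.4)`` with angle = heading.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_flies
    n_frames = int(round(config.duration_s * config.fps))
    body = config.species.body_len_mm
    r_prox = config.species.proximal_factor * body
    # Keep whole bodies inside the arena wall.
    r_max = config.chamber.radius_mm - body / 2.0

    p_stop0 = _per_frame(config.stop_base_prob, config.fps)
    p_restart = _per_frame(config.restart_prob, config.fps)
    step_len = config.walk_speed_mm_s / config.fps
    turn_sd = _TURN_SD_RAD * (1.0 - config.heading_persistence)
    attract = min(1.0, config.attraction_strength / config.fps)

    # Initial positions: uniform over the usable disc.
    rad = r_max * np.sqrt(rng.random(n))
    ang = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    heading = rng.uniform(0, 2 * np.pi, n)
    walking = np.ones(n, dtype=bool)
    rest_pos = pos.copy()  # anchor for stopped flies: jitter does not drift
    refract_frames = int(round(config.refractory_s * config.fps))
    refract = np.zeros(n, dtype=int)

    xs = np.empty((n, n_frames))
    ys = np.empty((n, n_frames))
    angles = np.empty((n, n_frames))

    for f in range(n_frames):
        xs[:, f] = pos[:, 0]
        ys[:, f] = pos[:, 1]
        angles[:, f] = heading

        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)

        # State transitions: stopping propensity scales with proximal crowding.
        # Each proximal neighbour multiplies the stopping propensity by
        # (1 + stop_gain): group capture is supralinear in crowding, so
        # chance pairs are weak traps but triples and larger nucleate groups.
        n_prox = (dist <= r_prox).sum(axis=1)
        p_stop = np.clip(
            p_stop0 * (1.0 + config.stop_gain) ** n_prox, 0.0, 1.0
        )
        u = rng.random(n)
        fresh = rng.uniform(0, 2 * np.pi, n)
        stopping_now = walking & (refract == 0) & (u < p_stop)
        restarting = ~walking & (u < p_restart)
        walking = (walking & ~stopping_now) | restarting
        if refract_frames > 0:
            heading = np.where(restarting, fresh, heading)
            refract = np.where(restarting, refract_frames,
                               np.maximum(refract - 1, 0))

        # Heading update: noise, plus bias toward the centroid of visible
        # neighbours (larger aggregates therefore attract more strongly).
        noise = rng.normal(0.0, turn_sd, n) if turn_sd > 0 else 0.0
        heading = heading + noise
        if attract > 0 and config.visual_range_mm > 0:
            vis = dist <= config.visual_range_mm
            n_vis = vis.sum(axis=1)
            has = (n_vis > 0) & (refract == 0)
            cx = (vis @ pos[:, 0]) / np.maximum(n_vis, 1)
            cy = (vis @ pos[:, 1]) / np.maximum(n_vis, 1)
            bearing = np.arctan2(cy - pos[:, 1], cx - pos[:, 0])
            err = np.angle(np.exp(1j * (bearing - heading)))
            heading = heading + np.where(has, attract * err, 0.0)

        # Displacement.  A fly that stops is anchored at its rest position;
        # the jitter emulates tracker noise and does not accumulate.
        rest_pos = np.where(walking[:, None], pos, rest_pos)
        jitter = rng.normal(0.0, config.stop_jitter_mm, (n, 2))
        new = np.where(
            walking[:, None],
            pos + step_len * np.column_stack([np.cos(heading), np.sin(heading)]),
            rest_pos + jitter,
        )

        # Wall: reflect the heading about the tangent and retake the step.
        out = np.hypot(new[:, 0], new[:, 1]) > r_max
        if out.any():
            nrm = pos[out] / np.maximum(
                np.hypot(pos[out, 0], pos[out, 1])[:, None], 1e-12
            )
            d = np.column_stack([np.cos(heading[out]), np.sin(heading[out])])
            d -= 2.0 * (d * nrm).sum(axis=1)[:, None] * nrm
            heading[out] = np.arctan2(d[:, 1], d[:, 0])
            new[out] = np.where(
                walking[out, None], pos[out] + step_len * d, new[out]
            )
            # Rare corner case (started at the wall): clamp radially.
            still = np.hypot(new[:, 0], new[:, 1]) > r_max
            if still.any():
                rr = np.hypot(new[still, 0], new[still, 1])
                new[still] *= (r_max / rr)[:, None]
        pos = new

    shape = (n, n_frames)
    return TrajectorySet(
        x=xs,
        y=ys,
        ell_len=np.full(shape, body),
        ell_wid=np.full(shape, 0.4 * body),
        ell_angle=angles,
        chamber=config.chamber,
        dt_s=1.0 / config.fps,
    )


def _presets() -> dict[str, SimConfig]:
    return {
        # Strong grouping: steep crowd-dependent stopping, whole-arena
        # visual attraction, long stop bouts with occasional free-walking
        # excursions -> fast, dense, stable groups.
        "calo_like": SimConfig(
            species=get_species("calo_white"),
            walk_speed_mm_s=8.0,
            heading_persistence=0.97,
            stop_base_prob=0.002,
            stop_gain=8.0,
            restart_prob=0.01,
            attraction_strength=5.0,
            visual_range_mm=127.0,
            refractory_s=6.0,
        ),
        # Weak grouping: mild crowd-dependent stopping, short-range weak
        # attraction, short stop bouts -> small transient clusters.
        "dmel_like": SimConfig(
            species=get_species("dmel_white"),
            walk_speed_mm_s=10.0,
            heading_persistence=0.95,
            stop_base_prob=0.05,
            stop_gain=2.0,
            restart_prob=0.2,
            attraction_strength=1.0,
            visual_range_mm=20.0,
            refractory_s=2.0,
        ),
        # Independent walkers: neighbours have no effect at all.
        "noninteracting": SimConfig(
            species=get_species("calo_white"),
            walk_speed_mm_s=8.0,
            heading_persistence=0.95,
            stop_base_prob=0.05,
            stop_gain=0.0,
            restart_prob=0.5,
            attraction_strength=0.0,
            visual_range_mm=0.0,
        ),
        # Vision-deprived strong-grouper: attraction removed, stopping only
        # weakly crowd-dependent (contact-range cues), threshold 2 mm/s.
        "calo_ir_like": SimConfig(
            species=get_species("calo_ir"),
            walk_speed_mm_s=8.0,
            heading_persistence=0.95,
            stop_base_prob=0.05,
            stop_gain=2.0,
            restart_prob=0.3,
            attraction_strength=0.0,
            visual_range_mm=0.0,
        ),
    }


def preset(name: str, **overrides) -> SimConfig:
    """Return a named regime preset, optionally with field overrides.

    Known presets: ``calo_like``, ``dmel_like``, ``noninteracting``,
    ``calo_ir_like``.
    """
    table = _presets()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(table)}")
    cfg = table[name]
    return replace(cfg, **overrides) if overrides else cfg
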