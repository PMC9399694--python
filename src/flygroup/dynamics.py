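"""Speed-distance dynamics and neighbour-count statistics by motion state.

Positions are sampled on a 128-frame (4.27 s at 30 fps) grid.  The mean
speed v̄(t) is the average over flies of the displacement per interval, and
d̄(t) the average of all pairwise inter-individual distances, giving the
speed-distance trajectory of a chamber.  At each grid time every fly is
classified Walking or Stopping by its interval speed against the species
threshold; the number of other flies within the surrounding radius (4x body
length; 5x/6x for robustness) is tallied per state, and each state's count
distribution is summarized by the Poisson mean λ fitted by maximum
likelihood (the sample mean, in closed form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .trajectories import SpeciesParams, TrajectorySet

INTERVAL_FRAMES = 128
SURROUND_FACTORS = (4, 5, 6)


@dataclass
class SpeedDistanceTrace:
    """Chamber-level v̄(t) and d̄(t) on the 128-frame grid."""

    t: np.ndarray  # seconds, end of each interval
    v_bar: np.ndarray  # mm/s
    d_bar: np.ndarray  # mm


@dataclass
class NeighborStatePMF:
    """Neighbour-count distributions for walking vs stopping states.

    ``pmf_walk``/``pmf_stop`` are probability masses over counts
    0..max(count); each sums to 1 within its state.  ``lambda_walk``/
    ``lambda_stop`` are the Poisson maximum-likelihood means (sample means),
    None when a state was never observed.
    """

    counts_walk: np.ndarray
    counts_stop: np.ndarray
    pmf_walk: np.ndarray | None
    pmf_stop: np.ndarray | None
    lambda_walk: float | None
    lambda_stop: float | None
    surround_radius_mm: float


def surround_radius(species: SpeciesParams, factor: int = 4) -> float:
    """Surrounding-area radius in mm: factor x body length, factor in {4,5,6}."""
    if factor not in SURROUND_FACTORS:
        raise ValueError(f"surround factor must be one of {SURROUND_FACTORS}")
    return factor * species.body_len_mm


def _grid(traj: TrajectorySet, interval_frames: int) -> np.ndarray:
    idx = np.arange(0, traj.n_frames, interval_frames)
    if idx.size < 2:
        raise ValueError("recording shorter than one sampling interval")
    return idx


def interval_speeds(
    traj: TrajectorySet, interval_frames: int = INTERVAL_FRAMES
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fly speeds over each full interval of the 128-frame grid.

    Returns ``(t, v)`` with ``t`` the interval-end times (s) and ``v`` of
    shape ``(n_flies, len(t))``; the final partial interval is discarded.
    """
    idx = _grid(traj, interval_frames)
    dt = interval_frames * traj.dt_s
    x = traj.x[:, idx]
    y = traj.y[:, idx]
    v = np.hypot(np.diff(x, axis=1), np.diff(y, axis=1)) / dt
    return idx[1:] * traj.dt_s, v


def speed_distance_trace(
    traj: TrajectorySet, interval_frames: int = INTERVAL_FRAMES
) -> SpeedDistanceTrace:
    """v̄(t) and d̄(t) for one chamber on the 128-frame grid."""
    idx = _grid(traj, interval_frames)
    t, v = interval_speeds(traj, interval_frames)
    d_bar = np.array(
        [pdist(traj.positions(f)).mean() for f in idx[1:]]
    )
    return SpeedDistanceTrace(t=t, v_bar=v.mean(axis=0), d_bar=d_bar)


def neighbor_counts(
    traj: TrajectorySet,
    species: SpeciesParams,
    factor: int = 4,
    interval_frames: int = INTERVAL_FRAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbour counts and walking states on the 128-frame grid.

    Returns ``(counts, walking)`` each of shape ``(n_flies, n_times)``:
    the number of other flies within the surrounding radius at each grid
    time, and whether the fly's speed over the preceding interval strictly
    exceeded the walking threshold.
    """
    idx = _grid(traj, interval_frames)
    r = surround_radius(species, factor)
    _, v = interval_speeds(traj, interval_frames)
    counts = np.empty((traj.n_flies, idx.size - 1), dtype=int)
    for k, f in enumerate(idx[1:]):
        d = squareform(pdist(traj.positions(f)))
        np.fill_diagonal(d, np.inf)
        counts[:, k] = (d <= r).sum(axis=1)
    return counts, v > species.walk_thresh_mm_s


def _pmf(samples: np.ndarray, k_max: int) -> np.ndarray | None:
    if samples.size == 0:
        return None
    return np.bincount(samples, minlength=k_max + 1) / samples.size


def neighbor_state_pmf(
    traj: TrajectorySet,
    species: SpeciesParams,
    factor: int = 4,
    interval_frames: int = INTERVAL_FRAMES,
) -> NeighborStatePMF:
    """State-split neighbour-count PMFs with Poisson MLE λ per state."""
    counts, walking = neighbor_counts(traj, species, factor, interval_frames)
    cw = counts[walking]
    cs = counts[~walking]
    k_max = int(counts.max()) if counts.size else 0
    return NeighborStatePMF(
        counts_walk=cw,
        counts_stop=cs,
        pmf_walk=_pmf(cw, k_max),
        pmf_stop=_pmf(cs, k_max),
        lambda_walk=float(cw.mean()) if cw.size else None,
        lambda_stop=float(cs.mean()) if cs.size else None,
        surround_radius_mm=surround_radius(species, factor),
    )


def poisson_lambda_mle(counts: np.ndarray) -> float:
    """Maximum-likelihood Poisson mean of count data: the sample mean."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("no counts to fit")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return float(counts.mean())


def pmf_overlap(pmf_walk: np.ndarray, pmf_stop: np.ndarray) -> float:
    """Overlap coefficient of two PMFs: sum over k of min(p_w(k), p_s(k)).

    1 for identical distributions, 0 for disjoint supports.
    """
    a = np.asarray(pmf_walk, dtype=float)
    b = np.asarray(pmf_stop, dtype=float)
    n = max(a.size, b.size)
    a = np.pad(a, (0, n - a.size))
    b = np.pad(b, (0, n - b.size))
    return float(np.minimum(a, b).sum())
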