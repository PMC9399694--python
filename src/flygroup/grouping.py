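"""Group-membership calling: proximal-area rule, gap bridging, stay events.

A fly belongs to a group at a 1-s sample when at least two *other* flies lie
within its proximal area, the disc of radius twice the body length around its
body centre.  Tracking noise fragments membership runs, so interior gaps
shorter than 5 s that are flanked by membership on both sides are bridged.
A stay event is a bridged membership run lasting at least 10 s; the total
grouping duration of a fly is the summed length of its stay events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .trajectories import SpeciesParams, TrajectorySet

MAX_BRIDGE_GAP_S = 5
MIN_STAY_S = 10
MIN_OTHERS_IN_GROUP = 2


@dataclass
class GroupingSeries:
    """Per-fly membership series at 1 Hz plus derived stay events."""

    fly_id: int
    t: np.ndarray
    belongs: np.ndarray  # bool, post-bridging
    stay_events: list[tuple[int, int]]  # (start_s, end_s), end exclusive
    total_grouping_duration_s: float
    n_stay: int


def proximal_radius(species: SpeciesParams) -> float:
    """Radius of the proximal area in mm (proximal_factor x body length)."""
    return species.proximal_factor * species.body_len_mm


def one_hz_step(traj: TrajectorySet) -> int:
    """Frame stride giving the 1-s analysis grid."""
    step = round(1.0 / traj.dt_s)
    if step < 1 or abs(step * traj.dt_s - 1.0) > 1e-9:
        raise ValueError(
            f"sampling interval {traj.dt_s} s does not divide the 1-s grid"
        )
    return int(step)


def belongs_raw(traj: TrajectorySet, species: SpeciesParams, t_s: float) -> np.ndarray:
    """Raw membership of every fly at one time: >= 2 others within radius."""
    pos = traj.positions_at_time(t_s)
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    return (d <= proximal_radius(species)).sum(axis=1) >= MIN_OTHERS_IN_GROUP


def belongs_raw_series(
    traj: TrajectorySet, species: SpeciesParams
) -> tuple[np.ndarray, np.ndarray]:
    """Raw membership on the full 1-Hz grid.

    Returns ``(belongs, t)`` with ``belongs`` boolean of shape
    ``(n_flies, n_samples)`` and ``t`` the sample times in seconds.
    """
    step = one_hz_step(traj)
    idx = np.arange(0, traj.n_frames, step)
    r = proximal_radius(species)
    out = np.empty((traj.n_flies, idx.size), dtype=bool)
    for k, f in enumerate(idx):
        pos = traj.positions(f)
        d = squareform(pdist(pos))
        np.fill_diagonal(d, np.inf)
        out[:, k] = (d <= r).sum(axis=1) >= MIN_OTHERS_IN_GROUP
    return out, idx * traj.dt_s


def _runs(series: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal constant runs as (start, end_exclusive, value)."""
    series = np.asarray(series, dtype=bool)
    if series.size == 0:
        return []
    change = np.flatnonzero(np.diff(series)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [series.size]])
    return [(int(s), int(e), bool(series[s])) for s, e in zip(starts, ends)]


def bridge_gaps(raw: np.ndarray, max_gap_s: int = MAX_BRIDGE_GAP_S) -> np.ndarray:
    """Bridge interior non-membership gaps strictly shorter than 5 s.

    A maximal false run is filled only when it is flanked by membership on
    both sides; leading and trailing false runs are never bridged (the fly
    was not previously in a group).  Idempotent.
    """
    raw = np.asarray(raw, dtype=bool)
    out = raw.copy()
    runs = _runs(raw)
    for i, (s, e, val) in enumerate(runs):
        if val or i == 0 or i == len(runs) - 1:
            continue
        if (e - s) < max_gap_s:
            out[s:e] = True
    return out


def stay_events(
    bridged: np.ndarray, min_stay_s: int = MIN_STAY_S
) -> list[tuple[int, int]]:
    """Membership runs of length >= 10 s, as (start_s, end_s) at 1 Hz."""
    return [
        (s, e) for s, e, val in _runs(np.asarray(bridged, dtype=bool))
        if val and (e - s) >= min_stay_s
    ]


def grouping_series(
    traj: TrajectorySet, species: SpeciesParams
) -> list[GroupingSeries]:
    """Full membership pipeline for every fly in a chamber."""
    raw, t = belongs_raw_series(traj, species)
    out = []
    for i in range(traj.n_flies):
        bridged = bridge_gaps(raw[i])
        events = stay_events(bridged)
        total = float(sum(e - s for s, e in events))
        out.append(
            GroupingSeries(
                fly_id=int(traj.fly_ids[i]),
                t=t,
                belongs=bridged,
                stay_events=events,
                total_grouping_duration_s=total,
                n_stay=len(events),
            )
        )
    return out


def grouped_count_series(series: list[GroupingSeries]) -> np.ndarray:
    """Number of flies with (bridged) membership at each second."""
    if not series:
        raise ValueError("no grouping series given")
    return np.sum([s.belongs for s in series], axis=0)


def mean_grouping_duration(series: GroupingSeries) -> float | None:
    """Total grouping duration / number of stay events; None without events."""
    if series.n_stay == 0:
        return None
    return series.total_grouping_duration_s / series.n_stay
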