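"""End-of-observation spatial statistics and the resampled random baseline.

Two summaries of where flies sit at the end of the 20-min observation:
an accumulative relative-position map (all other flies plotted around each
focal fly as the origin, pooled over flies and chambers) and the histogram
of all pairwise inter-individual distances per chamber, both at 2-mm bins.
The random baseline resamples sets of 20 positions from the pooled empirical
positions of all flies, times and chambers, giving the distance distribution
expected if flies occupied space independently with the observed marginal
density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .grouping import one_hz_step, proximal_radius
from .trajectories import SpeciesParams, TrajectorySet

BIN_MM = 2.0


@dataclass
class DistanceHistogram:
    """Pairwise-distance histogram per chamber plus the cross-chamber mean.

    ``counts`` is shaped ``(n_chambers, n_bins)``; each chamber's counts sum
    to C(n_flies, 2).  ``proximal_diameter_mm`` (2x the proximal radius,
    i.e. 4x body length) marks the grouping criterion on the distance axis.
    """

    bin_edges_mm: np.ndarray
    counts: np.ndarray
    mean_curve: np.ndarray
    proximal_diameter_mm: float | None = None


@dataclass
class RelativePositionMap:
    """2-D histogram of other flies' positions relative to each focal fly."""

    bin_edges_mm: np.ndarray  # shared x/y edges, 2-mm grid centred on origin
    counts: np.ndarray  # (n_bins, n_bins)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_list(trajs) -> list[TrajectorySet]:
    return [trajs] if isinstance(trajs, TrajectorySet) else list(trajs)


def relative_position_map(
    trajs, t_s: float = 1200.0, bin_mm: float = BIN_MM
) -> RelativePositionMap:
    """Accumulative relative-position distribution at time ``t_s``.

    For every focal fly, the positions of the other flies are translated so
    the focal fly is the origin; offsets are accumulated over all focal flies
    and chambers and binned on a square 2-mm grid.  The total count equals
    n_flies x (n_flies - 1) x n_chambers.
    """
    trajs = _as_list(trajs)
    d = trajs[0].chamber.diameter_mm
    half = bin_mm * np.ceil(d / bin_mm)
    edges = np.arange(-half, half + bin_mm / 2, bin_mm)
    counts = np.zeros((edges.size - 1, edges.size - 1))
    for traj in trajs:
        pos = traj.positions_at_time(t_s)
        n = pos.shape[0]
        for i in range(n):
            off = np.delete(pos, i, axis=0) - pos[i]
            h, _, _ = np.histogram2d(off[:, 0], off[:, 1], bins=(edges, edges))
            counts += h
    return RelativePositionMap(bin_edges_mm=edges, counts=counts)


def pairwise_distance_histogram(
    trajs,
    t_s: float = 1200.0,
    bin_mm: float = BIN_MM,
    species: SpeciesParams | None = None,
) -> DistanceHistogram:
    """Histogram of all C(n, 2) inter-individual distances at time ``t_s``.

    Accepts one chamber or a list; per-chamber curves are kept alongside
    their mean.  Bins are half-open ``[k*2, (k+1)*2)`` mm from 0.
    """
    trajs = _as_list(trajs)
    d = trajs[0].chamber.diameter_mm
    edges = np.arange(0.0, bin_mm * np.ceil(d / bin_mm) + bin_mm, bin_mm)
    counts = np.vstack(
        [np.histogram(pdist(t.positions_at_time(t_s)), bins=edges)[0] for t in trajs]
    )
    return DistanceHistogram(
        bin_edges_mm=edges,
        counts=counts,
        mean_curve=counts.mean(axis=0),
        proximal_diameter_mm=(
            2.0 * proximal_radius(species) if species is not None else None
        ),
    )


def pooled_positions(trajs) -> np.ndarray:
    """All flies' positions at all 1-Hz samples of all chambers, (M, 2) mm.

    Positions are already aligned on the chamber centre (the storage
    convention), so chambers pool directly.
    """
    pts = []
    for traj in _as_list(trajs):
        step = one_hz_step(traj)
        pts.append(
            np.column_stack(
                [traj.x[:, ::step].ravel(), traj.y[:, ::step].ravel()]
            )
        )
    return np.vstack(pts)


def make_random_data(
    trajs, n_replicates: int, seed: int, n_positions: int | None = None
) -> list[TrajectorySet]:
    """Resampled random baseline: sets of 20 positions from the pooled cloud.

    Each replicate draws ``n_positions`` (default: the chamber's fly count)
    positions uniformly *without* replacement from the pool; replicates are
    independent (with replacement across replicates).  The replicate count
    should match the condition's chamber count.  Returns single-frame
    TrajectorySets so the end-of-period spatial operations apply unchanged.
    """
    trajs = _as_list(trajs)
    n_positions = n_positions or trajs[0].n_flies
    pool = pooled_positions(trajs)
    if pool.shape[0] < n_positions:
        raise ValueError(
            f"pooled cloud has {pool.shape[0]} positions; need {n_positions}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        pick = pool[rng.choice(pool.shape[0], size=n_positions, replace=False)]
        shape = (n_positions, 1)
        out.append(
            TrajectorySet(
                x=pick[:, [0]],
                y=pick[:, [1]],
                ell_len=np.full(shape, np.nan),
                ell_wid=np.full(shape, np.nan),
                ell_angle=np.zeros(shape),
                chamber=trajs[0].chamber,
                dt_s=1.0,
            )
        )
    return out
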