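"""Encounter detection, join/leave classification and group-size dependence.

An encounter is a transition of a fly from "not belonging to a group" to
"belonging" that was preceded by at least 5 s of continuous walking (speed
over each preceding 1-s interval strictly above the species threshold).  The
outcome is *join* when the fly then remains grouped for 10 s or longer,
*leave* otherwise.  The size of the encountered group is measured by
partitioning the grouped flies' positions with x-means clustering and
counting the members of the cluster nearest the focal fly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .grouping import GroupingSeries, grouping_series, one_hz_step, proximal_radius
from .trajectories import SpeciesParams, TrajectorySet

MIN_WALK_S = 5
MIN_JOIN_S = 10


@dataclass
class EncounterRecord:
    """One encounter event and its outcome.

    ``group_size`` may be None when too few flies were themselves grouped at
    the encounter for a group size to be defined; such records still count
    toward the joining percentage but are excluded from the size-conditioned
    curve.  ``outcome`` is None for censored events (still grouped at the end
    of the recording, less than 10 s elapsed).
    """

    fly_id: int
    t_s: int
    group_size: int | None
    outcome: str | None  # "join" | "leave" | None (censored)
    stay_len_s: int


def speeds_1s(traj: TrajectorySet) -> np.ndarray:
    """Speed over each preceding 1-s interval, shape (n_flies, n_samples).

    The speed at sample k (k >= 1) is the displacement between samples k-1
    and k divided by 1 s; sample 0 has no preceding interval and gets 0.
    """
    step = one_hz_step(traj)
    x = traj.x[:, ::step]
    y = traj.y[:, ::step]
    v = np.zeros_like(x)
    v[:, 1:] = np.hypot(np.diff(x, axis=1), np.diff(y, axis=1))
    return v


def walking_mask(traj: TrajectorySet, species: SpeciesParams) -> np.ndarray:
    """True where 1-s speed strictly exceeds the walking threshold."""
    return speeds_1s(traj) > species.walk_thresh_mm_s


def detect_encounters(
    series: GroupingSeries, walking: np.ndarray, min_walk_s: int = MIN_WALK_S
) -> list[tuple[int, int]]:
    """Candidate encounters of one fly as (fly_id, t) pairs.

    A candidate is a false->true transition of the bridged membership series
    at second t with the fly walking through seconds t-5 .. t-1.
    """
    b = series.belongs
    out = []
    for t in np.flatnonzero(b[1:] & ~b[:-1]) + 1:
        if t >= min_walk_s and walking[t - min_walk_s : t].all():
            out.append((series.fly_id, int(t)))
    return out


def classify_outcome(
    event: tuple[int, int], series: GroupingSeries, min_join_s: int = MIN_JOIN_S
) -> EncounterRecord:
    """Join iff the fly stays grouped >= 10 s from the event; censored when
    the recording ends, still grouped, before 10 s elapsed."""
    fly_id, t = event
    b = series.belongs
    run = 0
    while t + run < b.size and b[t + run]:
        run += 1
    if run >= min_join_s:
        outcome = "join"
    elif t + run >= b.size:
        outcome = None  # censored at recording end
    else:
        outcome = "leave"
    return EncounterRecord(
        fly_id=fly_id, t_s=t, group_size=None, outcome=outcome, stay_len_s=run
    )


def percent_joining(records: list[EncounterRecord]) -> float | None:
    """100 x N_join / N_encounter for one fly; None with zero encounters.

    Censored records are excluded from both counts (their outcome is
    undefined); flies without any encounter carry no value rather than 0%.
    """
    decided = [r for r in records if r.outcome is not None]
    if not decided:
        return None
    n_join = sum(r.outcome == "join" for r in decided)
    return 100.0 * n_join / len(decided)


# ---------------------------------------------------------------------------
# X-means clustering (BIC-guided splitting on top of k-means)


class XMeans:
    """X-means clustering: k-means with BIC-accepted binary splits.

    Starts from a single cluster and recursively splits each cluster in two
    (k-means++, ``n_init`` restarts, fixed seed) whenever a two-component
    spherical Gaussian mixture has lower BIC than a single Gaussian on that
    cluster's points, up to ``k_max`` clusters.  ``min_scale`` (mm) floors
    the component variance: spatial structure finer than tracking noise and
    body size can never justify a split, which keeps a tight cluster of a
    few flies from being shattered.  The sklearn estimator idiom is
    followed: :meth:`fit` sets ``labels_``, ``cluster_centers_`` and
    ``n_clusters_``.
    """

    def __init__(
        self,
        k_max: int = 10,
        n_init: int = 10,
        random_state: int = 0,
        min_scale: float = 0.5,
    ):
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state
        self.min_scale = min_scale

    def fit(self, X: np.ndarray) -> "XMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("X must be a non-empty 2-D array")
        clusters = [np.arange(X.shape[0])]
        done: list[np.ndarray] = []
        while clusters and len(clusters) + len(done) < self.k_max:
            idx = clusters.pop(0)
            split = self._try_split(X[idx])
            if split is None:
                done.append(idx)
            else:
                left, right = split
                clusters.append(idx[left])
                clusters.append(idx[right])
        done.extend(clusters)
        labels = np.empty(X.shape[0], dtype=int)
        centers = np.empty((len(done), X.shape[1]))
        for j, idx in enumerate(done):
            labels[idx] = j
            centers[j] = X[idx].mean(axis=0)
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.n_clusters_ = len(done)
        return self

    def fit_predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).labels_

    def _try_split(self, Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        n = Xc.shape[0]
        if n < 3 or np.allclose(Xc, Xc[0]):
            return None
        # Points all within min_scale of their centroid are one cluster by
        # definition of the resolution floor; skip the mixture fit.
        if (np.linalg.norm(Xc - Xc.mean(axis=0), axis=1) <= self.min_scale).all():
            return None
        reg = self.min_scale**2
        gm1 = GaussianMixture(
            1, covariance_type="spherical", reg_covar=reg,
            random_state=self.random_state,
        ).fit(Xc)
        gm2 = GaussianMixture(
            2, covariance_type="spherical", reg_covar=reg,
            n_init=min(self.n_init, 5), random_state=self.random_state,
        ).fit(Xc)
        if gm2.bic(Xc) >= gm1.bic(Xc):
            return None
        km = KMeans(
            n_clusters=2,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(Xc)
        if len(np.unique(km.labels_)) < 2:
            return None
        return np.flatnonzero(km.labels_ == 0), np.flatnonzero(km.labels_ == 1)


def group_size_at(
    traj: TrajectorySet,
    grouped_ids: np.ndarray,
    t_s: int,
    encountered_fly: int,
    k_max: int = 10,
    random_state: int = 0,
    min_scale: float | None = None,
) -> int:
    """Size of the group the focal fly encountered.

    Partitions the grouped flies' positions at second ``t_s`` (the second
    before the transition) and returns the member count of the cluster whose
    centroid lies nearest the focal fly; ties go to the larger cluster.
    Flies separated by more than the proximal radius cannot share a group,
    so the points are first split into connected components at that cutoff;
    x-means then subdivides each component.  ``min_scale`` is the x-means
    resolution floor; by default half the proximal radius (structure tighter
    than the grouping criterion is one group, not several), inferred from
    the recorded body lengths.
    """
    grouped_ids = np.asarray(grouped_ids)
    grouped_ids = grouped_ids[grouped_ids != encountered_fly]
    if grouped_ids.size < 2:
        raise ValueError("fewer than 2 grouped flies: no group to encounter")
    id_to_row = {int(f): i for i, f in enumerate(traj.fly_ids)}
    rows = [id_to_row[int(f)] for f in grouped_ids]
    pos = traj.positions_at_time(t_s)
    if min_scale is None:
        min_scale = float(np.median(traj.ell_len))  # = proximal radius / 2
    pts = pos[rows]
    adj = squareform(pdist(pts)) <= 2.0 * min_scale
    n_cc, cc = connected_components(adj, directed=False)
    clusters: list[np.ndarray] = []
    for comp in range(n_cc):
        idx = np.flatnonzero(cc == comp)
        if idx.size >= 3:
            xm = XMeans(k_max=k_max, random_state=random_state,
                        min_scale=min_scale).fit(pts[idx])
            clusters.extend(idx[xm.labels_ == j] for j in range(xm.n_clusters_))
        else:
            clusters.append(idx)
    focal = pos[id_to_row[int(encountered_fly)]]
    centers = np.vstack([pts[c].mean(axis=0) for c in clusters])
    sizes = np.array([c.size for c in clusters])
    d = np.hypot(*(centers - focal).T)
    # A group has at least two members; a stray singleton among the grouped
    # flies is not a group the focal fly can have encountered.
    d = np.where(sizes >= 2, d, np.inf)
    if not np.isfinite(d).any():
        raise ValueError("no cluster of >= 2 grouped flies to encounter")
    order = np.lexsort((-sizes, d))  # nearest centroid, ties -> larger cluster
    return int(sizes[order[0]])


def encounter_records(
    traj: TrajectorySet,
    species: SpeciesParams,
    series: list[GroupingSeries] | None = None,
    k_max: int = 10,
    random_state: int = 0,
) -> list[EncounterRecord]:
    """Detect, classify and size-annotate every encounter in a chamber."""
    if series is None:
        series = grouping_series(traj, species)
    walking = walking_mask(traj, species)
    belongs = np.vstack([s.belongs for s in series])
    row_of = {s.fly_id: i for i, s in enumerate(series)}
    records: list[EncounterRecord] = []
    for s in series:
        i = row_of[s.fly_id]
        for event in detect_encounters(s, walking[i]):
            rec = classify_outcome(event, s)
            t = rec.t_s
            # Membership of the others at the second before the transition;
            # fall back to the transition second for just-formed groups.
            for t_ref in (t - 1, t):
                if t_ref < 0:
                    continue
                grouped = np.array(
                    [q.fly_id for j, q in enumerate(series)
                     if belongs[j, t_ref] and q.fly_id != s.fly_id]
                )
                if grouped.size >= 2:
                    try:
                        rec.group_size = group_size_at(
                            traj, grouped, t_ref, s.fly_id,
                            k_max=k_max, random_state=random_state,
                            min_scale=proximal_radius(species) / 2.0,
                        )
                    except ValueError:
                        continue  # only stray singletons; try next second
                    break
            records.append(rec)
    return records


def join_prob_by_size(
    records: list[EncounterRecord],
) -> pd.DataFrame:
    """Mean joining percentage per encountered group size.

    For each fly the joining percentage is computed per group size, and those
    per-fly percentages are averaged (unweighted) over the flies that had at
    least one encounter at that size.  Sizes without any encounter are
    absent.  Columns: ``group_size``, ``mean_join_pct``, ``n_events``.
    """
    rows = [
        (r.fly_id, r.group_size, r.outcome == "join")
        for r in records
        if r.outcome is not None and r.group_size is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["group_size", "mean_join_pct", "n_events"])
    df = pd.DataFrame(rows, columns=["fly_id", "group_size", "joined"])
    per_fly = (
        df.groupby(["group_size", "fly_id"])["joined"].mean().mul(100.0)
    )
    out = per_fly.groupby("group_size").mean().rename("mean_join_pct").reset_index()
    out["n_events"] = (
        df.groupby("group_size").size().reindex(out["group_size"]).to_numpy()
    )
    return out
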