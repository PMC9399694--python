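"""Trajectory containers and Ctrax-dialect CSV I/O.

Trajectories are per-fly time series of body-centre positions and fitted
ellipse geometry for one circular chamber recording.  Coordinates are stored
in millimetres with the origin at the chamber centre and the y axis pointing
up; the Ctrax CSV dialect (pixel units, origin at the top-left corner of the
chamber bounding box, y down) is converted at load and restored at write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Column order of the Ctrax-export CSV dialect.
CSV_COLUMNS = ["id", "frame", "x", "y", "ell_len", "ell_wid", "ell_angle"]

#: Positions may stick out of the nominal chamber disc by this much (mm)
#: before a calibration warning is raised.
CHAMBER_TOLERANCE_MM = 2.0


class TrajectoryFormatError(ValueError):
    """The input file does not follow the expected CSV dialect."""


class TrajectoryGapError(ValueError):
    """A fly is missing from one or more frames."""


class CalibrationWarning(UserWarning):
    """Positions fall outside the chamber disc beyond tolerance."""


@dataclass(frozen=True)
class ChamberConfig:
    """Geometry and recording constants of one behavioural chamber.

    The default values describe a sloped-wall circular arena, 127 mm in
    diameter and 3.50 mm deep, filmed at 30 frames per second, of which the
    first 20 minutes are analysed.
    """

    diameter_mm: float = 127.0
    depth_mm: float = 3.50
    fps: int = 30
    duration_s: float = 1200.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class SpeciesParams:
    """Body size and analysis conventions for one species/light condition.

    ``proximal_factor`` scales body length into the proximal radius used for
    group membership (2x body length); ``surround_factor`` scales it into the
    surrounding radius used for neighbour counting (4x, with 5x and 6x as
    robustness settings).  ``walk_thresh_mm_s`` is the locomotor-speed
    threshold separating walking from stopping.
    """

    name: str
    body_len_mm: float
    body_len_sd_mm: float
    walk_thresh_mm_s: float
    proximal_factor: float = 2.0
    surround_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.body_len_mm <= 0:
            raise ValueError("body_len_mm must be positive")
        if self.walk_thresh_mm_s <= 0:
            raise ValueError("walk_thresh_mm_s must be positive")
        if self.proximal_factor < 1 or self.surround_factor < 1:
            raise ValueError("proximal_factor and surround_factor must be >= 1")


#: Species/condition presets: C. alocasiae under white light, D. melanogaster
#: under white light, and C. alocasiae under infrared light (vision deprived,
#: walking threshold 2 mm/s).
SPECIES_PRESETS: dict[str, SpeciesParams] = {
    "calo_white": SpeciesParams("calo_white", 1.93, 0.12, 1.0),
    "dmel_white": SpeciesParams("dmel_white", 2.58, 0.20, 1.0),
    "calo_ir": SpeciesParams("calo_ir", 1.93, 0.12, 2.0),
}


def get_species(name: str) -> SpeciesParams:
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown species preset {name!r}; available: {sorted(SPECIES_PRESETS)}"
        ) from None


@dataclass
class TrajectorySet:
    """Complete, frame-aligned trajectories of all flies in one chamber.

    Arrays are shaped ``(n_flies, n_frames)``.  ``dt_s`` is the sampling
    interval in seconds (1/fps for native recordings; larger after
    :func:`subsample`).  Every fly has a value at every frame; identities are
    stable across frames.
    """

    x: np.ndarray
    y: np.ndarray
    ell_len: np.ndarray
    ell_wid: np.ndarray
    ell_angle: np.ndarray
    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    fly_ids: np.ndarray | None = None
    dt_s: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.ell_len = np.asarray(self.ell_len, dtype=float)
        self.ell_wid = np.asarray(self.ell_wid, dtype=float)
        self.ell_angle = np.asarray(self.ell_angle, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("trajectory arrays must be 2-D (n_flies, n_frames)")
        for arr in (self.y, self.ell_len, self.ell_wid, self.ell_angle):
            if arr.shape != self.x.shape:
                raise ValueError("all trajectory arrays must share one shape")
        if self.x.shape[0] < 1 or self.x.shape[1] < 1:
            raise ValueError("TrajectorySet needs at least one fly and one frame")
        if self.fly_ids is None:
            self.fly_ids = np.arange(self.n_flies)
        else:
            self.fly_ids = np.asarray(self.fly_ids)
            if self.fly_ids.shape != (self.n_flies,):
                raise ValueError("fly_ids must have one entry per fly")
        if self.dt_s is None:
            self.dt_s = 1.0 / self.chamber.fps
        cx, cy = self.chamber.center_xy
        r = np.hypot(self.x - cx, self.y - cy)
        if np.nanmax(r) > self.chamber.radius_mm + CHAMBER_TOLERANCE_MM:
            warnings.warn(
                "positions fall outside the chamber disc beyond tolerance; "
                "check the mm-per-pixel calibration",
                CalibrationWarning,
                stacklevel=2,
            )

    @property
    def n_flies(self) -> int:
        return self.x.shape[0]

    @property
    def n_frames(self) -> int:
        return self.x.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds (frame index x dt_s)."""
        return np.arange(self.n_frames) * self.dt_s

    def positions(self, frame: int) -> np.ndarray:
        """Body-centre positions at one frame, shape ``(n_flies, 2)``, mm."""
        return np.column_stack([self.x[:, frame], self.y[:, frame]])

    def frame_at_time(self, t_s: float) -> int:
        """Index of the sample closest to time ``t_s``, clipped to the record."""
        return int(min(round(t_s / self.dt_s), self.n_frames - 1))

    def positions_at_time(self, t_s: float) -> np.ndarray:
        return self.positions(self.frame_at_time(t_s))


def _px_origin_offset(chamber: ChamberConfig, calibration: float) -> float:
    # Ctrax pixel origin: top-left of the chamber bounding box, y down.
    return chamber.radius_mm / calibration


def read_trajectories(
    path, calibration: float, chamber: ChamberConfig | None = None
) -> TrajectorySet:
    """Load a Ctrax-dialect trajectory CSV.

    Parameters
    ----------
    path : path-like
        CSV with header ``id,frame,x,y,ell_len,ell_wid,ell_angle``, one row
        per fly per frame, coordinates in pixels.
    calibration : float
        Millimetres per pixel.  Required: recordings do not embed it.
    chamber : ChamberConfig, optional
        Chamber geometry; defaults to the standard 127-mm arena.

    Raises
    ------
    TrajectoryFormatError
        If a required column is missing.
    TrajectoryGapError
        If any fly is absent from one or more frames (gaps are rejected, not
        interpolated: the analysis assumes complete tracks).
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive (mm per pixel)")
    chamber = chamber or ChamberConfig()
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(
            f"missing required column(s) {missing} in {path}"
        )
    fly_ids = np.sort(df["id"].unique())
    frames = np.sort(df["frame"].unique())
    n_frames = int(frames.max()) + 1
    expected = np.arange(n_frames)
    gaps = []
    for fid, sub in df.groupby("id"):
        present = np.zeros(n_frames, dtype=bool)
        present[sub["frame"].to_numpy(dtype=int)] = True
        if not present.all():
            miss = expected[~present]
            gaps.append((fid, _format_ranges(miss)))
    if gaps:
        desc = "; ".join(f"fly {fid}: frames {r}" for fid, r in gaps)
        raise TrajectoryGapError(f"incomplete tracks: {desc}")

    df = df.sort_values(["id", "frame"])
    shape = (len(fly_ids), n_frames)
    off = _px_origin_offset(chamber, calibration)
    cx, cy = chamber.center_xy
    x = (df["x"].to_numpy() - off) * calibration + cx
    y = (off - df["y"].to_numpy()) * calibration + cy
    return TrajectorySet(
        x=x.reshape(shape),
        y=y.reshape(shape),
        ell_len=df["ell_len"].to_numpy().reshape(shape) * calibration,
        ell_wid=df["ell_wid"].to_numpy().reshape(shape) * calibration,
        ell_angle=-df["ell_angle"].to_numpy().reshape(shape),
        chamber=chamber,
        fly_ids=fly_ids,
    )


def write_trajectories(traj: TrajectorySet, path, calibration: float = 1.0) -> None:
    """Write a TrajectorySet back to the Ctrax CSV dialect.

    Inverse of :func:`read_trajectories` at the same calibration: a
    write/read round trip reproduces positions to numerical tolerance.
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive (mm per pixel)")
    if traj.n_flies < 1:
        raise ValueError("refusing to write an empty TrajectorySet")
    off = _px_origin_offset(traj.chamber, calibration)
    cx, cy = traj.chamber.center_xy
    n, m = traj.n_flies, traj.n_frames
    df = pd.DataFrame(
        {
            "id": np.repeat(traj.fly_ids, m),
            "frame": np.tile(np.arange(m), n),
            "x": ((traj.x - cx) / calibration + off).ravel(),
            "y": (off - (traj.y - cy) / calibration).ravel(),
            "ell_len": (traj.ell_len / calibration).ravel(),
            "ell_wid": (traj.ell_wid / calibration).ravel(),
            "ell_angle": (-traj.ell_angle).ravel(),
        }
    )
    df.to_csv(path, index=False)


def subsample(traj: TrajectorySet, step_frames: int) -> TrajectorySet:
    """Keep frames 0, step, 2*step, ...; dt_s grows accordingly.

    ``subsample(subsample(t, a), b) == subsample(t, a*b)``.
    """
    if step_frames < 1:
        raise ValueError("step_frames must be >= 1")
    if step_frames > traj.n_frames:
        raise ValueError(
            f"step_frames={step_frames} exceeds recording length {traj.n_frames}"
        )
    if step_frames == 1:
        return traj
    sl = np.s_[:, ::step_frames]
    return replace(
        traj,
        x=traj.x[sl],
        y=traj.y[sl],
        ell_len=traj.ell_len[sl],
        ell_wid=traj.ell_wid[sl],
        ell_angle=traj.ell_angle[sl],
        dt_s=traj.dt_s * step_frames,
    )


def _format_ranges(idx: np.ndarray) -> str:
    """Compress sorted integers into 'a-b, c, d-e' range notation."""
    parts = []
    start = prev = int(idx[0])
    for v in idx[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = v
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ", ".join(parts)
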