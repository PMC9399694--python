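import numpy as np
import pytest
from hypothesis import settings

from flygroup.simulate import preset, simulate
from flygroup.trajectories import ChamberConfig, SpeciesParams, TrajectorySet

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


CALO = SpeciesParams("calo_white", 1.93, 0.12, 1.0)
DMEL = SpeciesParams("dmel_white", 2.58, 0.20, 1.0)
CALO_IR = SpeciesParams("calo_ir", 1.93, 0.12, 2.0)


def make_traj(
    positions: np.ndarray,
    fps: int = 1,
    chamber: ChamberConfig | None = None,
    body_len: float = 1.93,
) -> TrajectorySet:
    """Build a TrajectorySet from a (n_flies, n_frames, 2) position array."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:  # single frame given as (n_flies, 2)
        positions = positions[:, None, :]
    n, m, _ = positions.shape
    return TrajectorySet(
        x=positions[..., 0],
        y=positions[..., 1],
        ell_len=np.full((n, m), body_len),
        ell_wid=np.full((n, m), 0.4 * body_len),
        ell_angle=np.zeros((n, m)),
        chamber=chamber or ChamberConfig(fps=fps),
        dt_s=1.0 / fps,
    )


def static_traj(points, duration_s: int, fps: int = 1, **kw) -> TrajectorySet:
    """Flies frozen at fixed points for duration_s seconds."""
    pts = np.asarray(points, dtype=float)
    pos = np.repeat(pts[:, None, :], int(duration_s * fps), axis=1)
    return make_traj(pos, fps=fps, **kw)


@pytest.fixture(scope="session")
def regime_sims():
    """Five full-length chambers per behavioural regime (shared, read-only)."""
    return {
        name: [
            simulate(preset(name, seed=s, duration_s=1200.0))
            for s in range(1, 6)
        ]
        for name in ("calo_like", "dmel_like", "noninteracting")
    }


@pytest.fixture(scope="session")
def short_sims():
    """Five quick 120-s mixed-regime chambers for oracle-equivalence checks."""
    names = ["calo_like", "dmel_like", "noninteracting", "calo_like", "dmel_like"]
    return [
        simulate(preset(name, seed=100 + k, duration_s=120.0))
        for k, name in enumerate(names)
    ]
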