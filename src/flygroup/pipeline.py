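"""End-to-end orchestration: simulate/load chambers, run every analysis
stage, and write CSV/JSON outputs with deterministic seeding.

One chamber corresponds to one trajectory CSV file; a condition is a
directory of such files (replicate counts are inferred from the directory,
matching the 9 / 12 / 11 chamber design of the three conditions).  All
randomness flows from a single master seed recorded in the summary, and the
summary JSON is byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, encounters, grouping, simulate as sim, spatial
from .trajectories import (
    SpeciesParams,
    TrajectorySet,
    get_species,
    read_trajectories,
)

log = logging.getLogger("flygroup")

STAGES = ("grouping", "encounters", "spatial", "dynamics")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``input_dir`` (directory of trajectory CSVs, with
    ``calibration`` in mm/px) or ``preset`` (simulator regime, with
    ``n_chambers`` replicates) supplies the chambers.
    """

    species: str = "calo_white"
    input_dir: str | None = None
    calibration: float = 1.0
    preset: str | None = None
    n_chambers: int = 3
    duration_s: float = 1200.0
    seed: int = 0
    out_dir: str = "flygroup_out"
    stages: tuple[str, ...] = STAGES
    surround_factor: int = 4

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_chambers(config: RunConfig) -> list[TrajectorySet]:
    """Read the condition's chambers from disk or simulate them."""
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no CSV files in {config.input_dir}")
        return [read_trajectories(p, calibration=config.calibration) for p in paths]
    if config.preset is None:
        raise ValueError("RunConfig needs input_dir or preset")
    return [
        sim.simulate(
            sim.preset(
                config.preset, seed=config.seed + k, duration_s=config.duration_s
            )
        )
        for k in range(config.n_chambers)
    ]


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage and write outputs under ``config.out_dir``.

    Returns the summary dict (also written as ``summary.json``); per-stage
    CSVs are written alongside.  The encounter stage depends on grouping and
    refuses to run without it.
    """
    stages = tuple(config.stages)
    if "encounters" in stages and "grouping" not in stages:
        raise ValueError("the encounters stage requires the grouping stage")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species = get_species(config.species)
    chambers = load_chambers(config)
    log.info("loaded %d chambers (%s)", len(chambers), config.species)

    summary: dict = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "species": config.species,
        "n_chambers": len(chambers),
    }

    series_by_chamber = None
    if "grouping" in stages:
        series_by_chamber = [
            grouping.grouping_series(tr, species) for tr in chambers
        ]
        rows, counts = [], []
        for c, series in enumerate(series_by_chamber):
            for s in series:
                for a, b in s.stay_events:
                    rows.append((c, s.fly_id, a, b))
            counts.append(grouping.grouped_count_series(series))
        pd.DataFrame(rows, columns=["chamber", "fly_id", "start_s", "end_s"]).to_csv(
            out / "stay_events.csv", index=False
        )
        cdf = pd.DataFrame(np.column_stack(counts),
                           columns=[f"chamber_{c}" for c in range(len(counts))])
        cdf.insert(0, "t_s", series_by_chamber[0][0].t.astype(int))
        cdf.to_csv(out / "grouped_counts.csv", index=False)
        durations = [
            s.total_grouping_duration_s
            for series in series_by_chamber for s in series
        ]
        mean_durs = [
            grouping.mean_grouping_duration(s)
            for series in series_by_chamber for s in series
        ]
        mean_durs = [m for m in mean_durs if m is not None]
        summary["grouping"] = {
            "median_total_duration_s": float(np.median(durations)),
            "mean_grouping_duration_s": (
                float(np.mean(mean_durs)) if mean_durs else None
            ),
            "n_stay_events": int(sum(
                s.n_stay for series in series_by_chamber for s in series
            )),
        }
        log.info("grouping: %d stay events", summary["grouping"]["n_stay_events"])

    if "encounters" in stages:
        all_records, join_pcts = [], []
        n_censored = 0
        for c, (tr, series) in enumerate(zip(chambers, series_by_chamber)):
            recs = encounters.encounter_records(tr, species, series=series)
            n_censored += sum(r.outcome is None for r in recs)
            for r in recs:
                all_records.append((c, r.fly_id, r.t_s, r.group_size,
                                    r.outcome, r.stay_len_s))
            for fid in tr.fly_ids:
                pct = encounters.percent_joining(
                    [r for r in recs if r.fly_id == fid]
                )
                if pct is not None:
                    join_pcts.append(pct)
        pd.DataFrame(
            all_records,
            columns=["chamber", "fly_id", "t_s", "group_size", "outcome",
                     "stay_len_s"],
        ).to_csv(out / "encounters.csv", index=False)
        flat = [
            encounters.EncounterRecord(f, t, g, o, sl)
            for _, f, t, g, o, sl in all_records
        ]
        curve = encounters.join_prob_by_size(flat)
        curve.to_csv(out / "join_by_size.csv", index=False)
        summary["encounters"] = {
            "n_encounters": int(sum(1 for r in flat if r.outcome is not None)),
            "n_censored": n_censored,
            "join_pct_per_fly": [round(p, 6) for p in join_pcts],
            "median_join_pct": (
                float(np.median(join_pcts)) if join_pcts else None
            ),
        }
        log.info(
            "encounters: %d events (%d censored)",
            summary["encounters"]["n_encounters"], n_censored,
        )

    if "spatial" in stages:
        hist = spatial.pairwise_distance_histogram(
            chambers, t_s=config.duration_s, species=species
        )
        rmap = spatial.relative_position_map(chambers, t_s=config.duration_s)
        rand = spatial.make_random_data(
            chambers, n_replicates=len(chambers), seed=config.seed
        )
        rhist = spatial.pairwise_distance_histogram(
            rand, t_s=0.0, species=species
        )
        hdf = pd.DataFrame(
            {
                "bin_lo": hist.bin_edges_mm[:-1],
                "bin_hi": hist.bin_edges_mm[1:],
                **{f"chamber_{c}": hist.counts[c] for c in range(len(chambers))},
                "mean": hist.mean_curve,
                "random_mean": rhist.mean_curve,
            }
        )
        hdf.to_csv(out / "distance_histogram.csv", index=False)
        pd.DataFrame(rmap.counts).to_csv(out / "relative_position_map.csv",
                                         index=False)
        summary["spatial"] = {
            "pairs_per_chamber": int(hist.counts[0].sum()),
            "map_total": rmap.total,
            "proximal_diameter_mm": hist.proximal_diameter_mm,
        }

    if "dynamics" in stages:
        lam_rows = []
        traces = []
        pmf_rows = []
        for c, tr in enumerate(chambers):
            pmf = dynamics.neighbor_state_pmf(
                tr, species, factor=config.surround_factor
            )
            lam_rows.append((c, pmf.lambda_walk, pmf.lambda_stop))
            if pmf.pmf_walk is not None and pmf.pmf_stop is not None:
                for k, (pw, ps) in enumerate(zip(pmf.pmf_walk, pmf.pmf_stop)):
                    pmf_rows.append((c, k, pw, ps))
            trace = dynamics.speed_distance_trace(tr)
            traces.append(
                pd.DataFrame(
                    {"chamber": c, "t_s": trace.t, "v_bar": trace.v_bar,
                     "d_bar": trace.d_bar}
                )
            )
        pd.concat(traces).to_csv(out / "speed_distance.csv", index=False)
        lam = pd.DataFrame(lam_rows,
                           columns=["chamber", "lambda_walk", "lambda_stop"])
        lam.to_csv(out / "lambda.csv", index=False)
        pd.DataFrame(
            pmf_rows, columns=["chamber", "k", "pmf_walk", "pmf_stop"]
        ).to_csv(out / "neighbor_pmf.csv", index=False)
        summary["dynamics"] = {
            "lambda_pairs": [
                [None if w is None else round(w, 6),
                 None if s is None else round(s, 6)]
                for _, w, s in lam_rows
            ],
            "surround_factor": config.surround_factor,
        }

    text = json.dumps(summary, sort_keys=True, indent=2)
    (out / "summary.json").write_text(text + "\n")
    return summary
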