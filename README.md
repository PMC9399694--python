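# flygroup

Group-formation analysis for multi-animal fly trajectory recordings, with an
agent-based simulator for testing the whole chain end to end.

Walking flies placed in a circular arena aggregate — some species into one
dense, stable cluster, others into small transient knots.  `flygroup` turns
raw tracking output (20 flies, 30 fps, 20 min, Ctrax-style CSV) into the
quantities that describe that process and the individual decisions behind
it:

* **Group membership and stay events** — a fly *belongs to a group* when ≥ 2
  other flies lie within its proximal area (radius 2× body length);
  sub-5-s dropouts are bridged as tracking noise, and membership runs of
  ≥ 10 s are *stay events*, summed into each fly's total grouping duration.
* **Encounters and join/leave decisions** — a not-grouped → grouped
  transition after ≥ 5 s of walking is an *encounter*; the fly *joins* if it
  stays ≥ 10 s.  Per-fly joining percentage is 100 · N_join / N_encounter.
* **Group-size dependence of joining** — the encountered group's size is
  read off an x-means partition (BIC-accepted splits) of the grouped flies'
  positions, giving the mean joining percentage as a function of group size
  (2–19).
* **Spatial distributions vs a random baseline** — end-of-period
  relative-position maps and pairwise-distance histograms (2-mm bins,
  C(20,2) = 190 distances per chamber) compared against position sets
  resampled from the pooled empirical positions.
* **Speed–distance dynamics and neighbour statistics** — v̄(t) and d̄(t) on a
  128-frame (4.27 s) grid, and neighbour-count PMFs within the surrounding
  area (4× body length) split by Walking/Stopping state, each summarised by
  a Poisson mean λ (maximum likelihood = sample mean):

  v̄(t) = (1/N) Σᵢ |vᵢ(t)|,  d̄(t) = 2/(N(N−1)) Σᵢ>ⱼ dᵢⱼ(t),  P(X=k) = λᵏe^(−λ)/k!

* **Statistics** — Brunner–Munzel rank tests, paired t-tests, F/Shapiro–Wilk
  assumption checks, and Cohen's d effect sizes.

The simulator (`flygroup.simulate`) provides strong-grouping
(`calo_like`), weak-grouping (`dmel_like`), non-interacting
(`noninteracting`) and vision-deprived (`calo_ir_like`) regimes built from
three couplings: crowd-dependent stopping, attraction toward the visible
centroid, and post-restart free-walking bouts.  See `docs/methods.md` for
the model, every threshold and default, and known limitations.

## Worked example

Simulate three strong-grouping chambers (5 min each, for brevity), run every
analysis stage, and print the machine-readable summary:

```sh
flygroup run-all --preset calo_like --species calo_white \
    --n-chambers 3 --duration 300 --seed 7 --out demo_out
```

Abridged output (`demo_out/summary.json`):

```json
{
  "dynamics": {
    "lambda_pairs": [[3.67027, 9.795062],
                     [4.037037, 9.89678],
                     [4.027322, 10.758422]]
  },
  "encounters": {"median_join_pct": 100.0, "n_encounters": 152,
                 "n_censored": 2},
  "grouping": {"median_total_duration_s": 256.0, "n_stay_events": 190},
  "spatial": {"pairs_per_chamber": 190, "map_total": 1140,
              "proximal_diameter_mm": 7.72}
}
```

Reading it: in each chamber the mean neighbour count of *stopping* flies
(λ_S ≈ 9.8–10.8) far exceeds that of *walking* flies (λ_W ≈ 3.7–4.0) — the
signature of flies that walk while alone and stop when surrounded.  The
median fly already spends 256 s of the 300-s window in a group, and the
median joining percentage is 100%: almost every encounter with a group ends
with the fly staying.  `pairs_per_chamber` and `map_total` are the
bookkeeping identities (190 = C(20,2); 1140 = 20 × 19 × 3 chambers).
Per-chamber CSVs (stay events, encounter records, the size-conditioned
joining curve, distance histograms with the random baseline, speed–distance
traces, λ tables) are written next to the summary.

The same analyses run on real recordings: point `--input-dir` (or the
`analyze` subcommands' `--in`) at a directory of trajectory CSVs and supply
the mm-per-pixel calibration.

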