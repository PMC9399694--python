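# Methods

`flygroup` quantifies how walking flies form groups in a circular arena from
multi-animal tracking output alone.  This note records the analysis
definitions, the model behind the synthetic-data generator, and the
numerical choices that were genuinely open, so that results can be
interpreted and reproduced without reading the source.

## Recording model

A chamber is a sloped-wall circular arena, 127 mm in diameter and 3.50 mm
deep, holding 20 female flies filmed at 30 frames per second; the first
20 minutes of each recording are analysed.  Tracking output is a
Ctrax-dialect CSV (`id,frame,x,y,ell_len,ell_wid,ell_angle`, one row per fly
per frame, pixel units).  On load, coordinates are converted to millimetres
with the origin at the chamber centre and y pointing up; the mm-per-pixel
calibration is a required user input because recordings do not embed it
(synthetic data use 1 px = 1 mm).  Tracks must be complete: a fly missing
from any frame is an error, not an interpolation target, because every
downstream event rule assumes an uninterrupted position series.  Time is
0-based, `t = frame / fps`.

Species presets carry the measured mean body lengths — 1.93 ± 0.12 mm for
*Colocasiomyia alocasiae* and 2.58 ± 0.20 mm for *Drosophila melanogaster*
(mean ± s.d.) — and the walking-speed thresholds: 1 mm s⁻¹ for both species
under white light, 2 mm s⁻¹ for *C. alocasiae* under infrared (vision-
deprived) light.

## Group membership and stay events

All membership analysis runs on a 1-s grid.  The *proximal area* of a fly is
the disc of radius twice its body length around the body centre; a fly
*belongs to a group* at a sample when two or more other flies lie within
that radius (centre-to-centre distance, boundary inclusive — an arbitrary
measure-zero choice fixed for reproducibility).  Tracker jitter fragments
membership runs of genuinely stationary flies, so interior non-membership
gaps strictly shorter than 5 s that are flanked by membership on both sides
are bridged; gaps touching the start or end of the recording are never
bridged, because the flanking evidence is missing.  A *stay event* is a
bridged membership run of at least 10 s ("less than 5 s" is implemented as
< 5 samples, "at least 10 s" as ≥ 10 samples — the literal readings).  The
*total grouping duration* of a fly is the summed length of its stay events,
and its mean grouping duration is that total divided by the number of stay
events (undefined for flies without stay events).

## Encounters, join/leave, and group size

An *encounter* is a false→true transition of the bridged membership series
preceded by five consecutive seconds of walking, where walking at second *k*
means the displacement between samples *k*−1 and *k* strictly exceeds the
species threshold.  Because bridging fills interior gaps before transitions
are read, a bridged excursion can never spawn a new encounter.  The outcome
is *join* when the fly then remains in membership for 10 s or longer,
*leave* otherwise.  An encounter within 10 s of the end of the recording
with the fly still grouped is censored — its outcome is undefined — and is
excluded from both the join and the encounter count (this affects at most
about one event per fly).  The joining percentage of a fly is
100 × N_join / N_encounter; flies with no encounters carry no value rather
than 0%.

The size of the encountered group is measured at the second immediately
before the transition: the flies then in membership (excluding the focal
fly) are partitioned spatially, and the member count of the cluster whose
centroid lies nearest the focal fly is reported, ties resolved toward the
larger cluster.  If fewer than two flies were in membership one second
before, the transition second itself is used; if a group still cannot be
identified, the record keeps its outcome but contributes no group size.  A
"group" must have at least two members; a stray singleton among the grouped
flies is never reported as an encountered group.

Partitioning is x-means — k-means (k-means++ initialisation, 10 restarts,
fixed seed, at most 10 clusters) grown by binary splits accepted under BIC —
with two reliability amendments that matter at this data's scale of 2–19
points per partition:

* **Split acceptance uses Gaussian-mixture BIC.**  The classical
  hard-assignment spherical BIC over-splits a single Gaussian cluster at
  small n, because the truncated halves understate the variance.  A split is
  therefore accepted only when a two-component spherical Gaussian mixture
  has lower BIC than a single Gaussian on the cluster's points, with the
  component variance floored at (0.5 × proximal radius)²: structure finer
  than the grouping criterion itself is one group, not several.  On blob
  fixtures this keeps single clusters of 3–20 points intact while splitting
  all separated pairs down to 2+2.
* **Connected components pre-partition.**  Flies farther apart than the
  proximal radius cannot belong to one group, so the grouped flies are first
  split into connected components at that cutoff (single-linkage), and
  x-means subdivides each component.  This guarantees the x-means sizes
  agree with connected-component sizes whenever clusters are well separated,
  and removes most of the mixture fits from the hot path.

The size-conditioned joining curve averages at the fly level: for each fly
and group size, the fly's own joining percentage is computed, and those
per-fly percentages are averaged (unweighted) over the flies with at least
one encounter at that size.  Sizes never encountered are absent rather than
zero, and each size carries its raw encounter count.

## Spatial distributions and the random baseline

At the end of the observation period (t = 1200 s), two summaries are
computed at a 2-mm bin size: the accumulative relative-position map (each
fly in turn is the origin; the 19 others' offsets are pooled over flies and
chambers, totalling 20 × 19 × chambers points — 3420 for a 9-chamber
condition, 4560 for 12 chambers) and the histogram of all C(20, 2) = 190
pairwise distances per chamber, with the cross-chamber mean.  Bins are
half-open `[2k, 2k+2)` mm.  The proximal diameter (4 × body length) is
attached as metadata for the reference line customarily drawn on these
plots.

The random baseline resamples the pooled empirical positions of all flies
at all 1-s samples in all chambers of a condition: each replicate draws 20
positions without replacement from the pool (replicates are independent),
and the replicate count matches the condition's chamber count.  Pooled
positions are treated as exchangeable points; because storage is already
chamber-centred, no further alignment is needed.  Random data are position
sets, not trajectories — only the end-of-period spatial operations accept
them.

## Speed–distance dynamics and neighbour-count statistics

Dynamics are sampled at 128-frame (4.27 s) intervals; the final partial
interval is discarded.  The mean speed v̄(t) is the average over the 20
flies of the displacement per interval divided by the interval; the mean
distance d̄(t) averages all 190 pairwise distances at the grid time.  Each
fly at each grid time is classified Walking or Stopping by its interval
speed against the species threshold (interval-averaged speed, matching the
grid; the 1-s speeds used for encounter detection apply the same threshold
at the finer grid).  The number of other flies within the surrounding
radius — 4 × body length, with 5 × and 6 × as robustness settings — is
tallied per state, normalised to a PMF per state, and summarised by the
Poisson mean λ fitted by maximum likelihood, which for count data is the
sample mean in closed form.  A state never observed in a chamber has no λ.
The overlap of the two state PMFs is Σₖ min(p_walk(k), p_stop(k)).

## Statistical layer

Between-condition comparisons use the Brunner–Munzel rank test (two-sided,
t approximation with Satterthwaite degrees of freedom); the statistic is
positive when the second sample tends stochastically larger.  Under
complete separation the rank variances vanish and the t approximation is
undefined; the implementation then reports ±∞ with the most extreme
two-sided permutation p-value, 2 / C(n+m, n).  Within-chamber state
comparisons use the classical paired t-test.  Assumption checks are a
two-sided variance-ratio F test plus Shapiro–Wilk per sample; if any check
rejects at α = 0.05 the Brunner–Munzel test is recommended.  Effect sizes
are Cohen's d = |mean difference| / pooled s.d. with (n−1) denominators;
published d values depend on this convention, so it is stated explicitly.

## The synthetic-fly simulator

No mechanistic movement model is available for these species, so the
simulator is a deliberately minimal test harness whose regimes reproduce
the statistical structure the analysis is designed to detect — it makes no
claim about fly cognition.  Each agent alternates between walking (a
correlated random walk at a fixed speed, heading noise damped by
`heading_persistence`) and stopping (anchored at its rest position with
0.05 mm Gaussian jitter per frame emulating tracker noise — the very noise
the 5-s bridging rule exists to absorb).  Per-second rates convert to
per-frame probabilities via `p_frame = 1 − (1 − p_sec)^(1/fps)`.  Three
couplings generate sociality:

* **Crowd-dependent stopping.**  Each neighbour within the proximal radius
  multiplies the stopping propensity by (1 + `stop_gain`).  The
  multiplicative form makes group capture supralinear in crowding, so
  chance pairs are weak traps while triples and larger nucleate groups; a
  linear gain cannot produce that asymmetry.
* **Visual mass attraction.**  A walking fly corrects a fraction
  `attraction_strength` per second of its bearing error toward the centroid
  of the neighbours within `visual_range_mm`.  Seeking the visible centroid
  rather than the single nearest fly makes larger aggregates
  proportionally more attractive; with nearest-fly homing, a stopped pair
  is an absorbing state and groups never coarsen.
* **Post-restart refractory bout.**  A fly that resumes walking takes a
  fresh random heading and walks free of attraction and stopping for
  `refractory_s` seconds, so leavers genuinely leave and clusters can
  exchange members.

Boundaries reflect the heading about the wall tangent.  Positions never
leave the chamber disc, output passes trajectory validation, and identical
seeds give bit-identical trajectories.

Presets fix the regimes the analysis must tell apart.  `calo_like` (strong
grouping: body 1.93 mm, stop_base 0.002 s⁻¹, stop_gain 8, restart
0.01 s⁻¹, attraction 5 s⁻¹ over the whole arena, 6-s refractory) forms
dense stable groups within minutes — median total grouping durations near
1000 s of the 1200-s window, joining percentages near 100%, λ_stop ≈ 9 vs
λ_walk ≈ 3.  `dmel_like` (weak grouping: body 2.58 mm, stop_gain 2, restart
0.2 s⁻¹, attraction 1 s⁻¹ within 20 mm) produces small transient clusters —
joining near 25%, λ gap under 1.  `noninteracting` zeroes both couplings
and is statistically indistinguishable from the resampled random baseline.
`calo_ir_like` models visual deprivation: attraction removed, stopping only
weakly crowd-dependent, walking threshold 2 mm s⁻¹.  These parameters were
chosen to instantiate the qualitative regimes and then frozen; they are not
fits to any recording.

What the simulator does *not* emulate: body-shaped (ellipse) exclusion and
contact forces, wall-following behaviour, olfactory or acoustic channels,
heterogeneous individuals, and identity-swap artefacts.  Passing the
regime-contrast tests therefore shows the pipeline separates the regimes it
was built to separate — not that real recordings will show effects of the
same magnitude.

## Problem sizes and numerical conventions

The test suite verifies event rules on hand-built series, checks every
aggregated quantity against brute-force recomputation on five 120-s
simulations, calibrates the estimators by direct Monte Carlo (Poisson
recovery at n = 10⁴; Brunner–Munzel size over 2000 null draws at
n = m = 20; exhaustive 252-split permutation oracle at n = m = 5), and
recovers the regime contrasts on five full-length (1200 s) chambers per
regime.  `scripts/acceptance.py` simulates the full study layout — 9
strong, 12 weak and 11 vision-deprived chambers plus 5 non-interacting
chambers for the null check — and recomputes every reported quantity from
those trajectories at run time.  Agreement of the Brunner–Munzel p with the
permutation oracle is asserted on moderate-p samples; at n = m = 5 the
permutation distribution has steps of ~1/252 and the t approximation is
anticonservative in the extreme tails, so tail-case agreement to 0.02 is
not attainable in principle.

Known limitations: group sizes are only defined when at least two flies
were themselves in membership around the encounter; sub-second excursions
are invisible on the 1-s grid by construction; and the x-means partition of
one contiguous, elongated aggregate into sub-groups is resolution-limited —
two clusters closer than about the proximal radius merge, by design.
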