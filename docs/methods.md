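# Methods

This document describes the models and procedures implemented in
`aisfish`, the parameters they expose, and the numerical choices made.

## 1. Record linkage and uptake

AIS messages identify vessels by transceiver id, callsign and free-text
name; the fleet register lists callsign, name, length and engine power.
Linkage proceeds in three passes, each one-to-one:

1. **Exact callsign join** on normalized callsigns (case-folded,
   non-alphanumeric characters stripped).
2. **Fuzzy name match** among the residual unmatched vessels.
3. **Fuzzy callsign match** among the remaining residuals.

Fuzzy similarity between two normalized strings is
`max(1 − d/max(|a|,|b|), jaro(a, b))`, where `d` is the Levenshtein edit
distance (computed with `edlib`) and `jaro` is the classic Jaro
similarity. Taking the maximum makes the score robust both to length
differences (Levenshtein) and to transpositions (Jaro). Empty strings
score −1 and can never match.

A fuzzy pair is accepted only if its similarity is at least the
**threshold (default 0.85)** and the pair is a *strict unique mutual
best*: each side is the other's unique argmax, with a positive margin
over the runner-up. Ties are rejected rather than broken arbitrarily, so
a wrong link is never forced; the cost is that genuinely ambiguous
vessels stay unmatched.

**Uptake** is the percentage of registered vessels linked to at least one
AIS-observed vessel, reported per length class (15–18 m, 18–24 m, > 24 m;
boundaries closed on the left) and per calendar month.

## 2. Cleaning filters

Applied in order, each recorded in a `FilterLedger` with rows/vessels
in and out:

1. **speed > 0.5 kn** (strict): removes moored and drifting positions.
2. **> 300 messages per vessel** (strict): vessels observed too briefly
   cannot support a mixture fit or a meaningful effort estimate.
3. **speed ≤ Q3 + 1.5 · IQR per vessel**: removes implausible speed
   spikes (GPS/decoder glitches). Quartiles use linear interpolation
   (`numpy.percentile` default). Vessels with fewer than 4 remaining
   messages are skipped (quartiles are not meaningful) and logged.

The outlier cut targets the extreme upper tail; with fishing and
steaming speeds a few knots apart, Q3 + 1.5 · IQR sits well above the
steaming mode, so legitimate transit speeds survive.

## 3. Fishing detection: two-Gaussian speed mixture

Trawler speed-over-ground distributions are bimodal: a slow mode while
towing gear and a fast mode while steaming. Per vessel, speeds `v` are
modeled as

    f(v) = π N(v; μ₁, σ₁²) + (1 − π) N(v; μ₂, σ₂²),  components sorted μ₁ < μ₂.

Fitting is by expectation–maximization, hand-authored so its numerical
behaviour is fully specified:

- **E-step in log space** (log-sum-exp) for numerical stability.
- **σ floor 0.05 kn**: prevents collapse onto a single data point;
  0.05 kn is below AIS speed resolution, so it never binds on real data.
- **Convergence**: absolute log-likelihood change < 1e-8; **max_iter
  1000** by default (near-unimodal data can legitimately need more; the
  fit reports `converged` and the full log-likelihood path).
- **3 restarts**: one deterministic start from the 25th/75th speed
  percentiles, two from random responsibilities (seeded); the best
  log-likelihood wins. The percentile start is usually in the basin of
  the global optimum for genuinely bimodal data; the random restarts
  guard against the cases where it is not.
- Inputs with n < 4 raise `InsufficientDataError`; all-identical speeds
  raise `DegenerateDataError` (the mixture is unidentifiable).

A fitted model is flagged **bimodal** when |μ₂ − μ₁| ≥ 2 · max(σ₁, σ₂);
only bimodal, converged fits are used for classification.

**Classification**: a message is labeled *fishing* iff its speed lies in
the closed interval [max(0, μ₁ − k σ₁), μ₁ + k σ₁] with **k = 1.5**.
Under the fitted model this captures erf(1.5/√2) ≈ 86.64 % of
slow-component messages while excluding nearly all of the fast
component when the modes are well separated. The lower bound is floored
at 0 because speed is nonnegative.

## 4. Validation against logbooks

For each vessel with at least **5 logbook fishing positions**, a
utilisation distribution (UD) is estimated by separable Gaussian kernel
density on a **0.01° grid**, bandwidth

    h = 0.5 (σ_x + σ_y) n^(−1/6)

(the reference bandwidth for a 2-D kernel UD), floored at one cell
width; the grid is padded by 3h so the density integrates to 1 (checked
to 1e-6 in tests). Every AIS message is scored by the UD value at its
position divided by the raster maximum, giving scores in [0, 1].

Per vessel, the mean score of fishing-labeled messages is paired with
the mean score of non-fishing-labeled messages; a paired t-test across
vessels (`scipy.stats.ttest_rel`, df = n − 1 on complete pairs) tests
whether fishing-labeled positions sit higher on the logbook-derived
grounds. Degenerate cases are handled explicitly: identical pairs give
t = 0, p = 1; zero-variance nonzero differences are reported as
p = 0 with t = ±inf and a flag, rather than NaN.

## 5. Effort mapping

Each fishing-labeled message contributes

    effort = engine power (kW) × reporting interval (s) / 86400   [kW-days]

to its grid cell (5-minute cadence ⇒ 1/288 kW-day per kW). Messages
from vessels with unknown power are skipped and counted.

**Grid anchoring.** The ~1×1 NM grid is anchored to the ICES rectangle
lattice, not to the data: `lat0 = floor(min_lat · 2)/2`,
`lon0 = floor(min_lon)`, `dlat = cell_nm/60`, and
`dlon = 1 / round(60 · cos(lat0 + 0.25) / cell_nm)`. This makes an
integer number of cells fit each 0.5° × 1° rectangle exactly, so
aggregating the fine grid to rectangles is exact (conservation checked
to 1e-9) and AIS effort can be compared with logbook effort without
edge-straddling artifacts. Cell width is ~1 NM at the grid's reference
latitude and varies with cos(lat) across large regions.

**Logbook effort** allocates each trip's duration (days) to its reported
rectangles proportionally to catch × engine power; a zero-catch trip is
split equally and flagged. Allocation sums exactly to trip totals.
AIS and logbook effort are compared per rectangle with Spearman rank
correlation (NaN when fewer than 3 shared rectangles or either side is
constant). Logbook effort counts whole days at sea while AIS effort
counts only fishing-labeled time, so logbook absolute values run higher;
the comparison is about spatial pattern, not scale.

**ICES rectangles**: rows are 0.5° bands from 36° N (codes 01–99);
columns are 1° bands from 44° W (A0–A3, then letters B–M skipping I, one
letter per 10°). Cells are half-open (closed on the south/west edge).
Anchor checks: 44G1 = 57.0–57.5° N, 11–12° E; 01A0 = 36.0–36.5° N,
44–43° W.

## 6. Coverage estimation

Reception probability varies in space (antenna coverage, transmission
interference). Per vessel, messages are split into trajectory segments
at gaps > 6 h or jumps > 20 NM (haversine); each segment is linearly
interpolated at the nominal 300 s cadence (observed timestamps are
retained exactly via a union of time grids, so with perfect reception
observed = expected). Coverage per 0.1° cell is

    ratio = observed messages / expected (interpolated) messages,

NaN (indeterminate) where no traffic is expected. The estimate assumes
vessels move roughly linearly between received fixes; long dropouts over
course changes bias the expected track, which is why segments are broken
at large gaps rather than interpolated across them.

## 7. Simulator

`simulate_fleet` generates a fleet with full ground truth for every
pipeline stage: a register (length, power, callsign, name), AIS messages
with true behavioural state, logbook records (one per fishing
operation, with rectangle, catch and trip times), and optional identifier
typos (`inject_typos`: one substitution, deletion or transposition, with
the operation recorded) and spatial dropout (`DropoutMap`).

What it emulates: bimodal truncated-normal speeds (fishing 3.0 ± 0.5 kn,
steaming 10.0 ± 1.0 kn, per-vessel mode jitter), port dwell at zero
speed, trips of 16–24 h with 1–2 fishing operations on vessel-specific
grounds, fixed 300 s reporting, message loss by location. Segment
durations are rounded to whole multiples of the reporting interval so
expected message counts are exact, which the tests rely on.

What it does not emulate: variable AIS reporting rates (class A rate
depends on speed/manoeuvre), course dynamics within segments (tracks are
locally linear), tides/weather, multi-gear fleets, logbook misreporting,
or transceiver clock error. Conclusions about those effects cannot be
drawn from this simulator.

## 8. Parameter summary

| Parameter | Default | Units | Where |
|---|---|---|---|
| linkage similarity threshold | 0.85 | — | `link_register` |
| speed floor | 0.5 | kn | `clean_messages` |
| min messages per vessel | 300 | messages | `clean_messages` |
| outlier cut | Q3 + 1.5·IQR | kn | `clean_messages` |
| EM tolerance | 1e-8 | log-lik | `fit_speed_mixture` |
| EM max iterations | 1000 | — | `fit_speed_mixture` |
| EM restarts | 3 | — | `fit_speed_mixture` |
| σ floor | 0.05 | kn | `fit_speed_mixture` |
| fishing interval half-width k | 1.5 | SD | `classify_messages` |
| UD cell size | 0.01 | ° | `estimate_ud` |
| min logbook points | 5 | points | `validate_fleet` |
| effort cell size | 1 | NM | `ais_effort` |
| coverage cell size | 0.1 | ° | `coverage_grid` |
| trajectory break: gap / jump | 6 / 20 | h / NM | `build_trajectories` |
| reporting interval | 300 | s | `SimConfig` |

## 9. Limitations

- Speed-only detection misclassifies slow non-fishing behaviour
  (drifting just above 0.5 kn, slow transit) as fishing and fast gear
  deployment as steaming; the k = 1.5 interval deliberately trades ~13 %
  of true fishing messages for specificity.
- The mixture assumes exactly two Gaussian components; vessels with more
  behavioural modes, or genuinely unimodal vessels, are flagged
  (non-bimodal) rather than classified.
- Linkage recall depends on identifier quality; heavily corrupted or
  reused callsigns reduce uptake estimates.
- Effort assumes constant engine power per vessel and attributes the
  full reporting interval to the message position.
- Coverage ratios are undefined where no vessel travels; they measure
  reception only along realized traffic.
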