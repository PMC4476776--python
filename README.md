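# aisfish

Mapping fishing effort from AIS vessel tracking data.

Fisheries management needs to know *where* fishing happens and *how much*,
at finer resolution than logbooks provide. Logbooks record trip totals per
ICES statistical rectangle (0.5° × 1°); AIS transmits a vessel position
every few minutes. `aisfish` implements the full chain that turns raw AIS
position reports into high-resolution fishing-effort maps, together with a
synthetic trawler-fleet simulator that provides ground truth for every
stage. It is aimed at fisheries scientists and anyone working with vessel
movement data.

The pipeline:

1. **Ingest & linkage** — parse AIS messages, then link AIS-observed
   vessels to a fleet register by exact callsign join followed by fuzzy
   matching of names and callsigns (normalized Levenshtein / Jaro
   similarity, threshold 0.85, unique mutual best match). Report AIS
   *uptake* — the share of registered vessels observed on AIS — by vessel
   length class.
2. **Cleaning** — drop messages with speed ≤ 0.5 kn (moored/drifting),
   vessels with ≤ 300 messages, and per-vessel speed outliers above
   Q3 + 1.5 · IQR.
3. **Fishing detection** — trawler speeds are bimodal: towing gear
   (~3 kn) vs steaming (~10 kn). Fit each vessel's speed distribution
   with a two-component Gaussian mixture,

   f(v) = π · N(v; μ₁, σ₁²) + (1 − π) · N(v; μ₂, σ₂²),   μ₁ < μ₂,

   by expectation–maximization, and label as *fishing* every message with
   speed in [μ₁ − 1.5 σ₁, μ₁ + 1.5 σ₁]. Under the model this captures
   erf(1.5/√2) ≈ 86.6 % of true fishing messages.
4. **Validation** — build each vessel's utilisation distribution (kernel
   density) from its logbook fishing positions, score every AIS message by
   the normalized UD value at its position, and compare fishing- vs
   non-fishing-labeled mean scores with a paired t-test across vessels.
5. **Effort mapping** — each fishing message contributes
   engine power (kW) × reporting interval (days) to its grid cell.
   The ~1×1 nautical-mile grid is anchored so cells nest exactly inside
   ICES rectangles, enabling direct comparison with logbook effort
   (trip days × kW allocated to rectangles proportionally to catch).
6. **Coverage** — estimate spatial AIS reception probability as the ratio
   of observed messages to messages expected from linearly interpolated
   trajectories, per 0.1° cell.

## Worked example

```python
import aisfish as af

# Simulate a 30-vessel trawler fleet: AIS messages every 5 minutes,
# a vessel register, logbooks, and full ground truth.
fleet = af.simulate_fleet(af.SimConfig(seed=5))

# Clean and detect fishing.
cleaned, ledger = af.clean_messages(fleet.messages)
labeled, params = af.fit_and_classify_fleet(cleaned, seed=0)

# Validate against logbook fishing grounds.
ais_vessels = (fleet.messages[["ais_vessel_id", "callsign", "name"]]
               .drop_duplicates("ais_vessel_id"))
matches = af.link_register(fleet.register, ais_vessels)
summary, _ = af.validate_fleet(labeled, fleet.logbook, matches)
print(summary.fishing_mean, summary.nonfishing_mean, summary.p_value)

# Map effort in kW-days on a ~1 NM grid.
power = fleet.truth.vessels.set_index("ais_vessel_id")["power_kw"]
grid = af.ais_effort(labeled, power)
print(grid.total)
```

Output the code actually prints (example 04/05 in `examples/`):

```
mean UD score, fishing-labeled:     0.58 ± 0.25
mean UD score, non-fishing-labeled: 0.26 ± 0.15
paired t = 10.08, df = 27, p = 1.19e-10
AIS effort grid: 100x68 cells (~1 NM), total 35144 kW-days
rank correlation: 0.972  (high = same spatial pattern despite the scale gap)
```

Fishing-labeled messages score twice as high on the logbook-derived
utilisation distributions, and the AIS effort map reproduces the logbook
spatial pattern almost perfectly while resolving it at ~1 NM instead of
0.5° × 1°.

The `examples/` directory contains one short narrative script per
capability (simulation, linkage, detection, validation, effort mapping,
coverage); each prints its results with a note on what they mean. A thin
CLI mirrors the library: `aisfish simulate|link|clean|detect|validate|
effort|coverage` (see `aisfish --help`).

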