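"""Synthetic fleet simulator.

Generates a fleet register, AIS position messages, logbook records and the
ground truth behind them, with the statistical structure the downstream
pipeline assumes: per-vessel bimodal speed profiles (slow towing mode vs
fast steaming mode), a fixed 5-minute message cadence, spatially clustered
fishing grounds, register typos, and spatially varying reception dropout.

Each vessel repeats a port -> steam -> fish -> steam -> port cycle.  Speeds
are drawn from the active state's Gaussian truncated at 0 knots; port
messages carry speed 0 exactly so the zero-speed cleaning filter has
something to remove.  Tracks are piecewise linear in latitude/longitude;
marine kinematic fidelity is a non-goal.

Sampling convention: a message is emitted at the segment start and then
every ``nominal_interval`` seconds, half-open at the segment end.  Segment
durations are drawn continuously and rounded to whole multiples of the
interval, so the number of messages a segment emits is exactly
``duration / nominal_interval``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .ices import ices_encode

_SYLLABLES = ["NOR", "VEST", "SKAG", "HAV", "FIS", "KAT", "SOL", "BRIS",
              "STOR", "LILL", "GULL", "MAR", "VIK", "SUND", "HOLM", "STRAND"]


class ConfigurationError(ValueError):
    """Raised for degenerate regions or non-positive counts."""


@dataclass
class DropoutMap:
    """Per-cell AIS reception probability over a lat/lon bounding box.

    ``probs[i, j]`` is the probability that a message emitted in cell
    (lat band i, lon band j) is actually received.  Points outside the
    box are clamped to the nearest cell.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    probs: np.ndarray  # shape (n_lat, n_lon)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ConfigurationError("dropout probs must be 2-D")
        if ((self.probs < 0) | (self.probs > 1)).any():
            raise ConfigurationError("reception probabilities must be in [0, 1]")

    @classmethod
    def uniform(cls, p: float, region: tuple[float, float, float, float]) -> "DropoutMap":
        lon0, lat0, lon1, lat1 = region
        return cls(lat0, lat1, lon0, lon1, np.full((1, 1), float(p)))

    def prob(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        n_lat, n_lon = self.probs.shape
        i = np.clip(((lat - self.lat_min) / (self.lat_max - self.lat_min) * n_lat)
                    .astype(int), 0, n_lat - 1)
        j = np.clip(((lon - self.lon_min) / (self.lon_max - self.lon_min) * n_lon)
                    .astype(int), 0, n_lon - 1)
        return self.probs[i, j]


@dataclass
class SimConfig:
    """Study conditions for one synthetic fleet.

    Speeds are knots, the region is (lon_min, lat_min, lon_max, lat_max) in
    WGS84 decimal degrees, and ``nominal_interval`` is the AIS message
    cadence in seconds.
    """

    n_vessels: int = 30
    region: tuple[float, float, float, float] = (10.0, 57.0, 12.5, 59.0)
    nominal_interval: int = 300
    fishing_speed_mean: float = 3.0
    fishing_speed_sd: float = 0.5
    steaming_speed_mean: float = 10.0
    steaming_speed_sd: float = 1.0
    fishing_fraction: float = 0.6
    trips_per_vessel: int = 4
    dropout_map: DropoutMap | None = None
    typo_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.region
        if not (lon1 > lon0 and lat1 > lat0):
            raise ConfigurationError("region is degenerate")
        if self.n_vessels <= 0 or self.trips_per_vessel <= 0:
            raise ConfigurationError("counts must be positive")
        if self.nominal_interval <= 0:
            raise ConfigurationError("nominal_interval must be positive")
        if not (0.0 < self.fishing_fraction < 1.0):
            raise ConfigurationError("fishing_fraction must be in (0, 1)")
        if not (0.0 <= self.typo_rate <= 1.0):
            raise ConfigurationError("typo_rate must be in [0, 1]")
        if not self.fishing_speed_mean < self.steaming_speed_mean:
            raise ConfigurationError("fishing mode must be slower than steaming mode")
        if min(self.fishing_speed_sd, self.steaming_speed_sd) <= 0:
            raise ConfigurationError("speed SDs must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline has to infer.

    ``messages`` holds every emitted message (received or not) with its
    behavioural state; ``vessels`` the true per-vessel mixture parameters;
    ``grounds`` the true fishing-ground centroids; ``typo_map`` the
    original/corrupted register identifier pairs (empty if no typos).
    """

    messages: pd.DataFrame
    vessels: pd.DataFrame
    grounds: pd.DataFrame
    typo_map: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["register_id", "field", "original", "corrupted", "op"]))


class FleetData(NamedTuple):
    register: pd.DataFrame
    messages: pd.DataFrame
    logbook: pd.DataFrame
    truth: GroundTruth


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _round_interval(seconds: float, interval: int) -> int:
    return max(interval, int(round(seconds / interval)) * interval)


def simulate_fleet(config: SimConfig) -> FleetData:
    """Simulate a fleet: register, AIS messages, logbook and ground truth.

    Identical configs (including seed) produce identical output.  The
    returned message table contains only received messages; the ground
    truth retains every emitted message with a ``received`` flag.
    """
    rng = np.random.default_rng(config.seed)
    lon0, lat0, lon1, lat1 = config.region
    dt = config.nominal_interval
    inset = 0.15
    g_lon0, g_lon1 = lon0 + inset * (lon1 - lon0), lon1 - inset * (lon1 - lon0)
    g_lat0, g_lat1 = lat0 + inset * (lat1 - lat0), lat1 - inset * (lat1 - lat0)

    ports = pd.DataFrame({
        "port_id": [f"PORT{k}" for k in range(3)],
        "port_lat": np.linspace(lat0 + 0.1, lat1 - 0.1, 3),
        "port_lon": np.full(3, lon1 - 0.05),
    })

    reg_rows, msg_rows, log_rows, truth_vessels, truth_grounds = [], [], [], [], []
    t_base = pd.Timestamp("2024-03-01T00:00:00Z")

    for i in range(config.n_vessels):
        register_id = f"REG{i:04d}"
        ais_id = str(265000000 + i)
        callsign = f"S{chr(65 + i % 26)}{chr(65 + (i // 26) % 26)}{1000 + i}"
        name = (_SYLLABLES[int(rng.integers(len(_SYLLABLES)))]
                + _SYLLABLES[int(rng.integers(len(_SYLLABLES)))].capitalize()
                + f" {i + 1}")
        port = ports.iloc[i % 3]
        power = float(np.round(rng.uniform(200, 1000), 0))
        length = float(np.round(rng.uniform(15, 40), 1))
        reg_rows.append(dict(register_id=register_id, callsign=callsign, name=name,
                             length_m=length, power_kw=power, port_id=port.port_id,
                             port_lat=port.port_lat, port_lon=port.port_lon))

        mu_f = config.fishing_speed_mean + rng.normal(0, 0.1)
        mu_s = config.steaming_speed_mean + rng.normal(0, 0.25)
        sd_f, sd_s = config.fishing_speed_sd, config.steaming_speed_sd
        truth_vessels.append(dict(register_id=register_id, ais_vessel_id=ais_id,
                                  fishing_mean=mu_f, fishing_sd=sd_f,
                                  steaming_mean=mu_s, steaming_sd=sd_s,
                                  power_kw=power))

        n_grounds = int(rng.integers(1, 3))
        grounds = np.column_stack([rng.uniform(g_lat0, g_lat1, n_grounds),
                                   rng.uniform(g_lon0, g_lon1, n_grounds)])
        for glat, glon in grounds:
            truth_grounds.append(dict(register_id=register_id,
                                      ground_lat=glat, ground_lon=glon))

        t = t_base + pd.Timedelta(seconds=int(rng.integers(0, 86400 // dt)) * dt)

        def emit(state, trip_id, seg_id, times, lats, lons, speeds):
            for ts, la, lo, sp in zip(times, lats, lons, speeds):
                msg_rows.append((ais_id, register_id, callsign, name, ts, la, lo,
                                 float(sp), state, trip_id, seg_id))

        def segment_times(t_start, duration):
            n = duration // dt
            return [t_start + pd.Timedelta(seconds=int(k) * dt) for k in range(n)]

        seg_counter = 0
        for trip in range(config.trips_per_vessel):
            trip_id = f"{register_id}-T{trip:02d}"
            # port dwell before departure
            dwell = _round_interval(rng.uniform(2, 4) * 3600, dt)
            times = segment_times(t, dwell)
            emit("in-port", trip_id, f"S{seg_counter:03d}",
                 times, [port.port_lat] * len(times), [port.port_lon] * len(times),
                 np.zeros(len(times)))
            seg_counter += 1
            t += pd.Timedelta(seconds=dwell)

            at_sea = _round_interval(rng.uniform(16, 24) * 3600, dt)
            fish_total = _round_interval(config.fishing_fraction * at_sea, dt)
            fish_total = min(fish_total, at_sea - 2 * dt)
            steam_total = at_sea - fish_total
            n_ops = int(rng.integers(1, 3)) if fish_total // dt >= 2 else 1
            # split fishing time across operations, steaming across legs
            fish_durs = _split_duration(rng, fish_total, n_ops, dt)
            steam_durs = _split_duration(rng, steam_total, n_ops + 1, dt)

            op_grounds = grounds[rng.integers(0, len(grounds), n_ops)]
            waypoints = [np.array([port.port_lat, port.port_lon])]
            waypoints += [g for g in op_grounds]
            waypoints.append(np.array([port.port_lat, port.port_lon]))

            departure = t
            for k in range(n_ops):
                # steaming leg towards ground k
                a, b = waypoints[k], waypoints[k + 1]
                times = segment_times(t, steam_durs[k])
                frac = np.arange(len(times)) / max(1, steam_durs[k] // dt)
                emit("steaming", trip_id, f"S{seg_counter:03d}", times,
                     a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]),
                     _truncated_normal(rng, mu_s, sd_s, len(times)))
                seg_counter += 1
                t += pd.Timedelta(seconds=steam_durs[k])

                # fishing operation: slow wander around the ground centroid
                times = segment_times(t, fish_durs[k])
                n = len(times)
                jit = rng.normal(0, 0.004, (n, 2)).cumsum(axis=0)
                if n:
                    jit = np.clip(jit - jit.mean(axis=0), -0.02, 0.02)
                emit("fishing", trip_id, f"S{seg_counter:03d}", times,
                     b[0] + jit[:, 0], b[1] + jit[:, 1],
                     _truncated_normal(rng, mu_f, sd_f, n))
                seg_counter += 1
                t += pd.Timedelta(seconds=fish_durs[k])
                log_rows.append(dict(
                    vessel_id=register_id, trip_id=trip_id,
                    departure=departure,
                    arrival=departure + pd.Timedelta(seconds=at_sea),
                    lat=b[0], lon=b[1],
                    catch_kg=float(np.round(rng.lognormal(6.0, 0.5), 1)),
                    gear="OTB",
                    ices_rectangle=ices_encode(b[0], b[1]).code))

            # final steaming leg home
            a, b = waypoints[-2], waypoints[-1]
            times = segment_times(t, steam_durs[-1])
            frac = np.arange(len(times)) / max(1, steam_durs[-1] // dt)
            emit("steaming", trip_id, f"S{seg_counter:03d}", times,
                 a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1]),
                 _truncated_normal(rng, mu_s, sd_s, len(times)))
            seg_counter += 1
            t += pd.Timedelta(seconds=steam_durs[-1])

    truth_msgs = pd.DataFrame(
        msg_rows, columns=["ais_vessel_id", "register_id", "callsign", "name",
                           "timestamp", "lat", "lon", "speed", "state",
                           "trip_id", "segment_id"])
    if config.dropout_map is not None:
        p = config.dropout_map.prob(truth_msgs["lat"].to_numpy(),
                                    truth_msgs["lon"].to_numpy())
        received = rng.random(len(truth_msgs)) < p
    else:
        received = np.ones(len(truth_msgs), dtype=bool)
    truth_msgs["received"] = received

    messages = (truth_msgs.loc[received,
                               ["ais_vessel_id", "callsign", "name",
                                "timestamp", "lat", "lon", "speed"]]
                .reset_index(drop=True))
    register = pd.DataFrame(reg_rows)
    logbook = pd.DataFrame(log_rows)
    truth = GroundTruth(messages=truth_msgs,
                        vessels=pd.DataFrame(truth_vessels),
                        grounds=pd.DataFrame(truth_grounds))

    if config.typo_rate > 0:
        register, typo_map = inject_typos(register, config.typo_rate,
                                          int(rng.integers(2**31)))
        truth.typo_map = typo_map
    return FleetData(register, messages, logbook, truth)


def _split_duration(rng: np.random.Generator, total: int, parts: int, dt: int) -> list[int]:
    """Split ``total`` (a multiple of dt) into ``parts`` multiples of dt, each >= dt."""
    slots = total // dt
    if parts <= 1 or slots <= parts:
        out = [dt] * parts
        out[0] = total - dt * (parts - 1)
        return out
    cuts = np.sort(rng.choice(np.arange(1, slots), size=parts - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [slots]]))
    return [int(s) * dt for s in sizes]


_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def _one_edit(rng: np.random.Generator, s: str) -> tuple[str, str]:
    """One random single-character substitution, deletion or transposition."""
    ops = ["sub", "del", "trans"] if len(s) >= 2 else ["sub", "del"]
    for _ in range(20):  # retry if the edit happens to reproduce s
        op = ops[int(rng.integers(len(ops)))]
        i = int(rng.integers(len(s)))
        if op == "sub":
            c = _ALPHABET[int(rng.integers(len(_ALPHABET)))]
            out = s[:i] + c + s[i + 1:]
        elif op == "del":
            out = s[:i] + s[i + 1:]
        else:
            i = min(i, len(s) - 2)
            out = s[:i] + s[i + 1] + s[i] + s[i + 2:]
        if out != s:
            return out, op
    return s + "X", "sub"


def inject_typos(register: pd.DataFrame, typo_rate: float, seed: int
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a fraction ``typo_rate`` of register identifiers by one edit.

    Each selected vessel gets one single-character substitution, deletion
    or transposition in either its callsign or its name.  Returns the
    corrupted register and the mapping back to the originals.
    """
    rng = np.random.default_rng(seed)
    out = register.copy()
    pick = rng.random(len(out)) < typo_rate
    rows = []
    for idx in out.index[pick]:
        fld = "callsign" if rng.random() < 0.5 else "name"
        original = out.at[idx, fld]
        corrupted, op = _one_edit(rng, str(original))
        out.at[idx, fld] = corrupted
        rows.append(dict(register_id=out.at[idx, "register_id"], field=fld,
                         original=original, corrupted=corrupted, op=op))
    typo_map = pd.DataFrame(rows, columns=["register_id", "field",
                                           "original", "corrupted", "op"])
    return out, typo_map


def write_fleet(fleet: FleetData, out_dir: str | Path) -> None:
    """Write the three tables and the ground truth as headered CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fleet.register.to_csv(out / "register.csv", index=False)
    m = fleet.messages.copy()
    m["timestamp"] = m["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    m.to_csv(out / "ais_messages.csv", index=False)
    lb = fleet.logbook.copy()
    for c in ("departure", "arrival"):
        lb[c] = lb[c].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    lb.to_csv(out / "logbook.csv", index=False)
    tm = fleet.truth.messages.copy()
    tm["timestamp"] = tm["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    tm.to_csv(out / "truth_messages.csv", index=False)
    fleet.truth.vessels.to_csv(out / "truth_vessels.csv", index=False)
    fleet.truth.grounds.to_csv(out / "truth_grounds.csv", index=False)
    fleet.truth.typo_map.to_csv(out / "truth_typos.csv", index=False)
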