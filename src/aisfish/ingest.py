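"""Reading, validation and record linkage of the three input tables.

AIS transceivers are keyed by whatever identifier the crew typed in, so
linking observed vessels to the official fleet register needs both an
exact callsign join and a fuzzy fallback that tolerates misspelt
identifiers.  The fuzzy step scores candidate pairs with normalized
Levenshtein similarity (1 - d/max(len)) and Jaro similarity, accepting a
pair when either score clears the threshold and the pair is the unique
mutual best on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._text import jaro, levenshtein_similarity, normalize

log = logging.getLogger(__name__)

AIS_COLUMNS = ["ais_vessel_id", "timestamp", "lat", "lon", "speed"]


class FormatError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class RejectionLog:
    """Counts of rows dropped while reading an AIS table."""

    n_read: int = 0
    n_unparsable: int = 0
    n_out_of_range: int = 0
    n_duplicate: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_read - self.n_unparsable - self.n_out_of_range - self.n_duplicate


def read_ais(path) -> tuple[pd.DataFrame, RejectionLog]:
    """Read an AIS message CSV, dropping and counting malformed rows.

    Rows with unparsable timestamps/coordinates/speeds, out-of-range
    coordinates or negative speeds are rejected; duplicate
    (vessel, timestamp) rows are collapsed to the first occurrence.  The
    result is stably sorted by vessel and time.
    """
    df = pd.read_csv(path, dtype={"ais_vessel_id": str})
    missing = [c for c in AIS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    rej = RejectionLog(n_read=len(df))

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    speed = pd.to_numeric(df["speed"], errors="coerce")
    parsable = ts.notna() & lat.notna() & lon.notna() & speed.notna()
    rej.n_unparsable = int((~parsable).sum())

    in_range = (lat.between(-90, 90) & lon.between(-180, 180) & (speed >= 0))
    ok = parsable & in_range.fillna(False)
    rej.n_out_of_range = int((parsable & ~ok).sum())

    out = df.loc[ok].copy()
    out["timestamp"] = ts[ok]
    out["lat"], out["lon"], out["speed"] = lat[ok], lon[ok], speed[ok]
    out = out.sort_values(["ais_vessel_id", "timestamp"], kind="stable")
    dup = out.duplicated(["ais_vessel_id", "timestamp"], keep="first")
    rej.n_duplicate = int(dup.sum())
    out = out.loc[~dup].reset_index(drop=True)
    if rej.n_unparsable or rej.n_out_of_range or rej.n_duplicate:
        log.info("read_ais rejected rows: %s", rej)
    return out, rej


@dataclass
class MatchResult:
    register_id: str
    ais_vessel_id: str | None
    method: str  # exact | fuzzy-name | fuzzy-callsign | unmatched
    similarity: float


def _pair_similarity(a: str, b: str) -> float:
    """Best of normalized Levenshtein and Jaro on normalized strings."""
    a, b = normalize(a), normalize(b)
    if not a or not b:
        return -1.0  # empty identifiers never match fuzzily
    return max(levenshtein_similarity(a, b), jaro(a, b))


def _mutual_best_pairs(reg: pd.DataFrame, ais: pd.DataFrame, reg_col: str,
                       ais_col: str, threshold: float) -> list[tuple]:
    """Pairs that clear the threshold and are the strict argmax on both sides."""
    if reg.empty or ais.empty:
        return []
    scores = np.full((len(reg), len(ais)), -1.0)
    reg_vals = reg[reg_col].tolist()
    ais_vals = ais[ais_col].tolist()
    for i, rv in enumerate(reg_vals):
        for j, av in enumerate(ais_vals):
            scores[i, j] = _pair_similarity(rv, av)
    pairs = []
    for i in range(len(reg)):
        j = int(np.argmax(scores[i]))
        s = scores[i, j]
        if s < threshold:
            continue
        # strict uniqueness: runner-up margin must be > 0 on both axes
        row = np.delete(scores[i], j)
        col = np.delete(scores[:, j], i)
        if row.size and row.max() >= s:
            continue
        if col.size and col.max() >= s:
            continue
        if int(np.argmax(scores[:, j])) != i:
            continue
        pairs.append((reg.index[i], ais.index[j], float(s)))
    return pairs


def link_register(register: pd.DataFrame, ais_vessels: pd.DataFrame,
                  exact_first: bool = True, threshold: float = 0.85
                  ) -> pd.DataFrame:
    """Link register vessels to AIS-observed vessels one-to-one.

    Step 0 joins exactly on normalized callsign; step 1 fuzzy-matches the
    remaining rows on vessel names and step 2 on callsigns.  Each fuzzy
    pair must reach ``threshold`` in normalized Levenshtein or Jaro
    similarity and be the unique mutual best; ties reject both sides.
    Returns one row per register vessel with columns
    (register_id, ais_vessel_id, method, similarity).
    """
    if register.empty or ais_vessels.empty:
        raise ValueError("register and AIS vessel tables must be non-empty")
    reg = register[["register_id", "callsign", "name"]].copy()
    ais = ais_vessels[["ais_vessel_id", "callsign", "name"]].copy()
    reg["_cs"] = reg["callsign"].map(normalize)
    ais["_cs"] = ais["callsign"].map(normalize)

    results: dict[str, MatchResult] = {}
    used_ais: set = set()

    if exact_first:
        # exact join only where the normalized callsign is unique on both sides
        reg_u = reg[(reg["_cs"] != "") & ~reg["_cs"].duplicated(keep=False)]
        ais_u = ais[(ais["_cs"] != "") & ~ais["_cs"].duplicated(keep=False)]
        merged = reg_u.merge(ais_u, on="_cs", suffixes=("_r", "_a"))
        for _, r in merged.iterrows():
            results[r["register_id"]] = MatchResult(r["register_id"],
                                                    r["ais_vessel_id"], "exact", 1.0)
            used_ais.add(r["ais_vessel_id"])

    for method, col in (("fuzzy-name", "name"), ("fuzzy-callsign", "callsign")):
        reg_left = reg[~reg["register_id"].isin(results)]
        ais_left = ais[~ais["ais_vessel_id"].isin(used_ais)]
        for ri, aj, s in _mutual_best_pairs(reg_left, ais_left, col, col, threshold):
            rid = reg.at[ri, "register_id"]
            aid = ais.at[aj, "ais_vessel_id"]
            results[rid] = MatchResult(rid, aid, method, s)
            used_ais.add(aid)

    rows = []
    for rid in reg["register_id"]:
        m = results.get(rid)
        if m is None:
            rows.append(dict(register_id=rid, ais_vessel_id=None,
                             method="unmatched", similarity=np.nan))
        else:
            rows.append(dict(register_id=m.register_id, ais_vessel_id=m.ais_vessel_id,
                             method=m.method, similarity=m.similarity))
    out = pd.DataFrame(rows)
    matched = out["method"] != "unmatched"
    log.info("link_register: %d/%d matched (%.1f%%)", matched.sum(), len(out),
             100 * matched.mean())
    return out


LENGTH_CLASSES = [(15.0, 18.0, "15-18m"), (18.0, 24.0, "18-24m"),
                  (24.0, np.inf, ">24m")]


def length_class(length_m: float) -> str:
    for lo, hi, label in LENGTH_CLASSES:
        if lo <= length_m < hi:
            return label
    return "<15m"


def uptake(register: pd.DataFrame, matches: pd.DataFrame,
           messages: pd.DataFrame, strata: str | pd.Series = "length_class"
           ) -> pd.DataFrame:
    """AIS uptake rate per stratum: percent of registered vessels heard from.

    A vessel counts as "with AIS" iff it is linked to an AIS identity with
    at least one message in the observation window.  ``strata`` is either a
    register column name ("length_class" derives classes from length_m) or
    a Series of stratum labels aligned with the register.
    """
    reg = register.copy()
    if isinstance(strata, pd.Series):
        reg["_stratum"] = strata.values
    elif strata == "length_class" and "length_class" not in reg.columns:
        reg["_stratum"] = reg["length_m"].map(length_class)
    else:
        reg["_stratum"] = reg[strata]

    active = set(messages["ais_vessel_id"].unique())
    linked = matches[matches["method"] != "unmatched"]
    with_ais = set(linked.loc[linked["ais_vessel_id"].isin(active), "register_id"])
    reg["_with_ais"] = reg["register_id"].isin(with_ais)

    rows = []
    for stratum, grp in reg.groupby("_stratum", sort=True):
        n_reg, n_ais = len(grp), int(grp["_with_ais"].sum())
        rate = 100.0 * n_ais / n_reg if n_reg else np.nan
        rows.append(dict(stratum=stratum, n_registered=n_reg, n_with_ais=n_ais,
                         rate=rate, undefined=n_reg == 0))
    return pd.DataFrame(rows)


def uptake_by_month(register: pd.DataFrame, matches: pd.DataFrame,
                    messages: pd.DataFrame) -> pd.DataFrame:
    """Cumulative monthly uptake: a vessel counts from its first message on."""
    linked = matches[matches["method"] != "unmatched"]
    ts = messages["timestamp"].dt.tz_localize(None)
    first = (ts.groupby(messages["ais_vessel_id"]).min().dt.to_period("M"))
    first = linked.merge(first.rename("first_month"), left_on="ais_vessel_id",
                         right_index=True)
    months = pd.period_range(first["first_month"].min(),
                             ts.max().to_period("M"), freq="M")
    n_total = len(register)
    rows = [dict(month=str(m), n_registered=n_total,
                 n_with_ais=int((first["first_month"] <= m).sum()),
                 rate=100.0 * (first["first_month"] <= m).sum() / n_total)
            for m in months]
    return pd.DataFrame(rows)
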