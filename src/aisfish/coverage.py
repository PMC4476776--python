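"""Spatial AIS reception coverage from trajectory reconstruction.

Terrestrial AIS reception degrades with distance from shore stations, so
the raw message density under-represents traffic in poorly covered areas.
The coverage estimate compares, per 0.1-degree cell, the density of
received positions with the density of points expected along the vessels'
reconstructed trajectories: messages are split into track segments at
large time or distance gaps, each segment is linearly interpolated at the
nominal message cadence, and the per-cell ratio observed/expected is the
coverage proxy.  Cells no trajectory crosses are indeterminate — absence
of messages there says nothing about reception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import haversine_nm

DEFAULT_MAX_GAP_S = 6 * 3600.0
DEFAULT_MAX_JUMP_NM = 20.0
DEFAULT_STEP_S = 300.0
DEFAULT_CELL_DEG = 0.1


def build_trajectories(messages: pd.DataFrame,
                       max_gap: float = DEFAULT_MAX_GAP_S,
                       max_jump: float = DEFAULT_MAX_JUMP_NM) -> pd.DataFrame:
    """Split each vessel's message sequence into trajectory segments.

    A new segment starts whenever the time gap exceeds ``max_gap`` seconds
    or the great-circle jump exceeds ``max_jump`` nautical miles — the
    latter also separates two physical ships sharing one identifier.
    Returns the messages (sorted per vessel by time) with a ``segment_id``
    column; singleton segments are allowed.
    """
    out = messages.sort_values(["ais_vessel_id", "timestamp"],
                               kind="stable").reset_index(drop=True)
    seg_ids = np.zeros(len(out), dtype=int)
    counter = 0
    for _, grp in out.groupby("ais_vessel_id", sort=False):
        t = grp["timestamp"].astype("int64").to_numpy() / 1e9
        lat, lon = grp["lat"].to_numpy(), grp["lon"].to_numpy()
        breaks = np.zeros(len(grp), dtype=bool)
        breaks[0] = True
        if len(grp) > 1:
            dt = np.diff(t)
            dist = haversine_nm(lat[:-1], lon[:-1], lat[1:], lon[1:])
            breaks[1:] = (dt > max_gap) | (dist > max_jump)
        ids = counter + np.cumsum(breaks) - 1
        counter = ids[-1] + 1
        seg_ids[grp.index] = ids
    out["segment_id"] = seg_ids
    return out


def interpolate_trajectories(trajectories: pd.DataFrame,
                             step: float = DEFAULT_STEP_S) -> pd.DataFrame:
    """Resample each segment at a fixed time step by linear interpolation.

    Observed points are included; extra points are inserted every ``step``
    seconds of elapsed segment time, linear in latitude and longitude.
    Segments with a single point pass through unchanged.
    """
    rows = []
    for seg, grp in trajectories.groupby("segment_id", sort=False):
        t = grp["timestamp"].astype("int64").to_numpy() / 1e9
        lat, lon = grp["lat"].to_numpy(), grp["lon"].to_numpy()
        vessel = grp["ais_vessel_id"].iloc[0]
        if len(grp) == 1:
            tt = t
        else:
            tt = np.union1d(t, np.arange(t[0], t[-1], step))
        rows.append(pd.DataFrame(dict(
            ais_vessel_id=vessel, segment_id=seg, t=tt,
            lat=np.interp(tt, t, lat), lon=np.interp(tt, t, lon))))
    if not rows:
        return pd.DataFrame(columns=["ais_vessel_id", "segment_id", "t",
                                     "lat", "lon"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class CoverageGrid:
    """Observed vs expected point densities per cell, and their ratio.

    ``ratio`` is NaN where no interpolated trajectory point fell
    (``indeterminate`` True there): such cells may be empty sea or
    reception holes and the data cannot tell the two apart.
    """

    lat0: float
    lon0: float
    cell: float
    observed: np.ndarray
    expected: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.expected > 0, self.observed / self.expected, np.nan)

    @property
    def indeterminate(self) -> np.ndarray:
        return self.expected == 0

    def to_frame(self) -> pd.DataFrame:
        i, j = np.indices(self.observed.shape)
        i, j = i.ravel(), j.ravel()
        return pd.DataFrame(dict(
            lat=self.lat0 + (i + 0.5) * self.cell,
            lon=self.lon0 + (j + 0.5) * self.cell,
            observed=self.observed[i, j], expected=self.expected[i, j],
            ratio=self.ratio[i, j], indeterminate=self.indeterminate[i, j]))


def _bin_counts(lat, lon, lat0, lon0, cell, shape):
    i = np.floor((np.asarray(lat) - lat0) / cell).astype(int)
    j = np.floor((np.asarray(lon) - lon0) / cell).astype(int)
    counts = np.zeros(shape)
    np.add.at(counts, (i, j), 1.0)
    return counts


def coverage_grid(messages: pd.DataFrame, interpolated: pd.DataFrame,
                  cell: float = DEFAULT_CELL_DEG) -> CoverageGrid:
    """Per-cell observed and expected point counts on a ``cell``-degree grid.

    The grid covers both point sets; the ratio observed/expected estimates
    the reception probability where trajectories passed.
    """
    lat_all = np.concatenate([messages["lat"].to_numpy(),
                              interpolated["lat"].to_numpy()])
    lon_all = np.concatenate([messages["lon"].to_numpy(),
                              interpolated["lon"].to_numpy()])
    lat0 = np.floor(lat_all.min() / cell) * cell
    lon0 = np.floor(lon_all.min() / cell) * cell
    n_i = int(np.floor((lat_all.max() - lat0) / cell)) + 1
    n_j = int(np.floor((lon_all.max() - lon0) / cell)) + 1
    obs = _bin_counts(messages["lat"], messages["lon"], lat0, lon0, cell,
                      (n_i, n_j))
    exp = _bin_counts(interpolated["lat"], interpolated["lon"], lat0, lon0,
                      cell, (n_i, n_j))
    return CoverageGrid(lat0=lat0, lon0=lon0, cell=cell, observed=obs,
                        expected=exp)
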