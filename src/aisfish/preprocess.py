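"""Cleaning filters applied to per-vessel AIS message sets.

The chain runs in a fixed order: (1) drop messages at or below 0.5 knots
(vessels idling in port dominate the raw feed and would swamp the slow
fishing mode); (2) drop vessels that retain 300 or fewer messages, too few
for a stable mixture fit; (3) per vessel, drop speeds above
Q3 + 1.5*IQR as transmission errors or outliers.  The chain is defined as
a single pass; the ledger records row and vessel counts at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPEED_FLOOR_KN = 0.5
MIN_MESSAGES = 300


@dataclass
class FilterLedger:
    """Row/vessel counts through the filter chain, in application order."""

    steps: list[dict] = field(default_factory=list)
    skipped_outlier_vessels: list = field(default_factory=list)

    def record(self, name: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        self.steps.append(dict(filter=name,
                               rows_in=len(before), rows_out=len(after),
                               vessels_in=before["ais_vessel_id"].nunique(),
                               vessels_out=after["ais_vessel_id"].nunique()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def filter_speed(messages: pd.DataFrame, floor: float = SPEED_FLOOR_KN) -> pd.DataFrame:
    """Keep only messages with speed strictly greater than ``floor`` knots."""
    return messages.loc[messages["speed"] > floor].copy()


def filter_min_messages(messages: pd.DataFrame, min_count: int = MIN_MESSAGES
                        ) -> pd.DataFrame:
    """Drop vessels with ``min_count`` or fewer messages (strictly more survive)."""
    counts = messages.groupby("ais_vessel_id")["speed"].transform("size")
    return messages.loc[counts > min_count].copy()


def filter_speed_outliers(messages: pd.DataFrame,
                          ledger: FilterLedger | None = None) -> pd.DataFrame:
    """Per vessel, drop speeds strictly above Q3 + 1.5*IQR.

    Quartiles use linear interpolation between order statistics.  Vessels
    with fewer than 4 messages are passed through untouched (quartiles
    ill-defined) and noted in the ledger.
    """
    keep = np.ones(len(messages), dtype=bool)
    pos = {c: i for i, c in enumerate(messages.columns)}
    for vessel, grp in messages.groupby("ais_vessel_id"):
        if len(grp) < 4:
            if ledger is not None:
                ledger.skipped_outlier_vessels.append(vessel)
            log.info("outlier filter skipped for vessel %s (n=%d)", vessel, len(grp))
            continue
        s = grp["speed"].to_numpy()
        q1, q3 = np.percentile(s, [25, 75])
        cutoff = q3 + 1.5 * (q3 - q1)
        idx = messages.index.get_indexer(grp.index[s > cutoff])
        keep[idx] = False
    return messages.loc[keep].copy()


def clean_messages(messages: pd.DataFrame, speed_floor: float = SPEED_FLOOR_KN,
                   min_count: int = MIN_MESSAGES, outliers: bool = True
                   ) -> tuple[pd.DataFrame, FilterLedger]:
    """Run the full single-pass cleaning chain and return (messages, ledger)."""
    ledger = FilterLedger()
    step1 = filter_speed(messages, speed_floor)
    ledger.record("speed>%.1fkn" % speed_floor, messages, step1)
    step2 = filter_min_messages(step1, min_count)
    ledger.record(">%d messages" % min_count, step1, step2)
    if outliers:
        step3 = filter_speed_outliers(step2, ledger)
        ledger.record("speed<=Q3+1.5IQR", step2, step3)
    else:
        step3 = step2
    for s in ledger.steps:
        log.info("filter %(filter)s: rows %(rows_in)d -> %(rows_out)d, "
                 "vessels %(vessels_in)d -> %(vessels_out)d", s)
    return step3, ledger
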