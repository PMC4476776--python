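"""ICES statistical rectangles.

The ICES reporting grid tiles 36°N-85.5°N, 44°W-68.5°E with cells of 0.5°
latitude by 1° longitude.  Rows are numbered from 36°N ("01" = 36-36.5°N);
columns are lettered in 10°-of-longitude blocks starting at 44°W — A0-A3
cover 44°W-40°W, then B0-B9, C0-C9, ... with the letter I skipped, so that
F0 is 0-1°E and M8 ends at the 68.5°E boundary.  Cells are half-open in
both axes: a point on a southern/western edge belongs to that cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_LETTERS = "BCDEFGHJKLM"  # 10-degree blocks from 40W eastwards; I omitted

LAT_MIN, LAT_MAX = 36.0, 85.5
LON_MIN, LON_MAX = -44.0, 68.5


@dataclass(frozen=True)
class ICESRectangle:
    """One statistical rectangle: code plus (lat_min, lat_max, lon_min, lon_max)."""

    code: str
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.lat_min, self.lat_max, self.lon_min, self.lon_max)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.lat_min + self.lat_max) / 2,
                (self.lon_min + self.lon_max) / 2)


def ices_encode(lat: float, lon: float) -> ICESRectangle:
    """Rectangle containing (lat, lon); raises ValueError outside the domain."""
    if not (LAT_MIN <= lat < LAT_MAX) or not (LON_MIN <= lon < LON_MAX):
        raise ValueError(f"({lat}, {lon}) outside the ICES rectangle domain")
    row = int(math.floor((lat - LAT_MIN) / 0.5)) + 1
    col = int(math.floor(lon - LON_MIN))  # 1-degree column index from 44W
    if col < 4:
        letter, digit = "A", col
    else:
        letter = _LETTERS[(col - 4) // 10]
        digit = (col - 4) % 10
    return ices_decode(f"{row:02d}{letter}{digit}")


def ices_decode(code: str) -> ICESRectangle:
    """Bounds of a rectangle code such as '44G1'."""
    code = code.strip().upper()
    if len(code) != 4 or not code[:2].isdigit() or not code[3].isdigit():
        raise ValueError(f"malformed ICES rectangle code: {code!r}")
    row = int(code[:2])
    letter, digit = code[2], int(code[3])
    if row < 1 or row > 99:
        raise ValueError(f"row out of range in {code!r}")
    if letter == "A":
        if digit > 3:
            raise ValueError(f"column out of range in {code!r}")
        col = digit
    else:
        if letter not in _LETTERS:
            raise ValueError(f"unknown column letter in {code!r}")
        col = 4 + _LETTERS.index(letter) * 10 + digit
    lat_lo = LAT_MIN + (row - 1) * 0.5
    lon_lo = LON_MIN + col
    if lon_lo >= LON_MAX:
        raise ValueError(f"column out of range in {code!r}")
    return ICESRectangle(code, lat_lo, lat_lo + 0.5, lon_lo, min(lon_lo + 1.0, LON_MAX))
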