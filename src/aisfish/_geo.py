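"""Small geodesy helpers on WGS84 coordinates.

All distances are great-circle (spherical haversine); at the scale of a
single fishing region (tens of nautical miles) this is accurate to well
under 0.5%, which is ample for gap splitting and grid assignment.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_NM = 3440.065  # mean Earth radius in nautical miles
NM_PER_DEG_LAT = 60.0


def haversine_nm(lat1, lon1, lat2, lon2):
    """Great-circle distance in nautical miles. Accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_NM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
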