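"""Great-circle geometry on the IUGG mean-radius sphere."""
from __future__ import annotations

import numpy as np

__all__ = ["EARTH_RADIUS_KM", "haversine_km"]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points in decimal degrees.

    Broadcasts over array inputs.  Ellipsoidal corrections are below 0.5% at
    Gulf-of-Maine scales and are deliberately omitted.
    """
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
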