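"""Latitude-structured synthetic geography and monthly climate covariates."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ..geoclimate import CLIMATE_VARS, month_col
from .sequences import PopulationTruth


def gen_geoclimate(
    labels: PopulationTruth | Mapping[str, str],
    lat_ranges: Mapping[str, tuple[float, float]],
    climate_gradients: Mapping[str, float] | None = None,
    lon_ranges: Mapping[str, tuple[float, float]] | None = None,
    elev_ranges: Mapping[str, tuple[float, float]] | None = None,
    monthly_baselines: Mapping[str, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-accession geography plus 12 monthly values per climate
    variable, each linear in latitude with Gaussian noise.

    ``lat_ranges`` maps each lineage to its latitude band; latitude is
    uniform within the band, so disjoint bands separate lineages by
    latitude.  ``climate_gradients`` maps a variable name to its slope
    versus latitude (applied to all 12 months on top of the optional
    monthly baseline).  Elevation is uniform within the per-lineage range.
    """
    if isinstance(labels, PopulationTruth):
        labels = labels.lineage_labels
    gradients = dict(climate_gradients or {})
    for var, slope in gradients.items():
        if not np.isfinite(slope):
            raise ValueError(f"non-finite slope for {var!r}")
    for name, (lo, hi) in lat_ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
            raise ValueError(f"degenerate latitude range for lineage {name!r}")
    missing = set(labels.values()) - set(lat_ranges)
    if missing:
        raise ValueError(f"no latitude range for lineages {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    for acc in sorted(labels):
        lineage = labels[acc]
        lo, hi = lat_ranges[lineage]
        lat = float(rng.uniform(lo, hi))
        if lon_ranges is not None:
            llo, lhi = lon_ranges[lineage]
            lon = float(rng.uniform(llo, lhi))
        else:
            lon = float(rng.uniform(20.0, 45.0))
        if elev_ranges is not None:
            elo, ehi = elev_ranges[lineage]
            elev = float(rng.uniform(elo, ehi))
        else:
            elev = float(rng.uniform(0.0, 1500.0))
        row = {"accession": acc, "lineage": lineage, "lat": lat, "lon": lon,
               "elev": elev}
        for var in CLIMATE_VARS:
            slope = gradients.get(var, 0.0)
            base = (
                np.asarray(monthly_baselines[var], dtype=float)
                if monthly_baselines and var in monthly_baselines
                else np.zeros(12)
            )
            noise = (
                rng.normal(0.0, noise_sd, size=12)
                if noise_sd > 0
                else np.zeros(12)
            )
            values = base + slope * lat + noise
            for m in range(1, 13):
                row[month_col(var, m)] = float(values[m - 1])
        rows.append(row)
    return pd.DataFrame(rows)
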