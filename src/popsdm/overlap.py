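"""Niche-overlap statistics between suitability surfaces.

Both statistics compare two suitability rasters after normalizing each to a
probability surface over the shared finite cells:

    Schoener's D = 1 - 1/2 sum_i |p1_i - p2_i|
    Hellinger  I = 1 - 1/2 sum_i (sqrt(p1_i) - sqrt(p2_i))^2
                 = sum_i sqrt(p1_i * p2_i)      (Bhattacharyya identity)

Both range from 0 (completely discordant niches) to 1 (identical niches)
and are symmetric in their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid


def normalize_suitability(surface: RasterGrid,
                          region: RasterGrid | None = None) -> np.ndarray:
    """Flatten a suitability raster to a probability vector over the finite
    (and optionally region-masked) cells; sums to 1."""
    mask = surface.finite_mask
    if region is not None:
        if not surface.same_geometry(region):
            raise ValueError("surface and region geometry differ")
        mask = mask & (region.values == 1)
    s = surface.values[mask]
    total = np.nansum(s)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("suitability surface is all-zero over the region")
    return s / total


def _shared_probabilities(a: RasterGrid, b: RasterGrid,
                          region: RasterGrid | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_geometry(b):
        raise ValueError("overlap: geometry mismatch")
    mask = a.finite_mask & b.finite_mask
    if region is not None:
        if not a.same_geometry(region):
            raise ValueError("overlap: region geometry mismatch")
        mask &= region.values == 1
    sa, sb = a.values[mask], b.values[mask]
    ta, tb = sa.sum(), sb.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("overlap: a surface is all-zero over the shared cells")
    return sa / ta, sb / tb


def schoener_d(p1: np.ndarray, p2: np.ndarray) -> float:
    """D = 1 - 1/2 sum |p1 - p2| on two aligned probability vectors."""
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("probability vectors must share one cell set")
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_i(p1: np.ndarray, p2: np.ndarray, form: str = "hellinger") -> float:
    """Corrected Hellinger overlap I in [0, 1].

    ``form='hellinger'`` computes 1 - H^2/2; ``form='bhattacharyya'``
    computes sum sqrt(p1*p2) — mathematically identical, kept as an
    internal consistency check.
    """
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("probability vectors must share one cell set")
    if form == "hellinger":
        h2 = np.sum((np.sqrt(p1) - np.sqrt(p2)) ** 2)
        return float(1.0 - 0.5 * h2)
    if form == "bhattacharyya":
        return float(np.sum(np.sqrt(p1 * p2)))
    raise ValueError("form must be 'hellinger' or 'bhattacharyya'")


@dataclass
class OverlapResult:
    pair: str
    scenario: str
    D: float
    I: float


def overlap(a: RasterGrid, b: RasterGrid, region: RasterGrid | None = None,
            pair: str = "", scenario: str = "current") -> OverlapResult:
    """D and I between two suitability surfaces on their shared cells."""
    p1, p2 = _shared_probabilities(a, b, region)
    return OverlapResult(pair, scenario, schoener_d(p1, p2), hellinger_i(p1, p2))


def overlap_trajectory(surface_pairs: dict[str, tuple[RasterGrid, RasterGrid]],
                       region: RasterGrid | None = None,
                       pair: str = "") -> pd.DataFrame:
    """D and I per scenario for a {scenario: (surface_a, surface_b)} map,
    as a tidy table ordered by insertion."""
    rows = []
    for scenario, (a, b) in surface_pairs.items():
        r = overlap(a, b, region=region, pair=pair, scenario=scenario)
        rows.append({"pair": pair, "scenario": scenario, "Sch_D": r.D, "Cor_I": r.I})
    return pd.DataFrame(rows)
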