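"""Depth-bin occupancy and geographic range summaries per haplotype.

Coarse markers lump distinct species into one haplotype and therefore
inflate apparent bathymetric and geographic ranges; these summaries make
that effect measurable.  Depth occupancy places each specimen in a
half-open 100 m bin; haplotype ranges collect site/region sets, depth
extremes, and the maximum great-circle span among coordinates when
coordinates are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import SpecimenRecord
from .haplotypes import HaplotypeAssignment

logger = logging.getLogger("hapresolve")

EARTH_RADIUS_KM = 6371.0


def haversine_km(
    a: tuple[float, float], b: tuple[float, float]
) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    la1, lo1, la2, lo2 = map(math.radians, (*a, *b))
    s = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


@dataclass(frozen=True)
class OccupancyMatrix:
    """Specimen counts per (depth bin, haplotype).

    Rows are bin lower bounds in meters, half-open [lower, lower + width);
    columns are haplotype codes sorted by minimum observed depth (ties
    broken by code).  ``uncertain`` marks cells containing midpoint-derived
    or collector-questioned depths.
    """

    counts: pd.DataFrame  # rows: bin lower bound (int); cols: haplotype code
    uncertain: pd.DataFrame  # same shape, counts of uncertain placements
    bin_width: float
    n_missing_depth: int

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.index = [
            f"[{int(lo)},{int(lo + self.bin_width)})" for lo in self.counts.index
        ]
        out.index.name = "depth_bin_m"
        return out


def depth_occupancy(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
    bin_width: float = 100.0,
) -> OccupancyMatrix:
    """Bin specimens by depth and cross-tabulate against haplotypes.

    Specimens with missing depth are skipped with a warning; total counts
    equal the number of specimens with a depth, whatever the bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    placed: list[tuple[float, int, bool]] = []
    n_missing = 0
    for s in specimens:
        if s.specimen_id not in assignment.labels:
            continue
        if s.depth.kind == "missing":
            n_missing += 1
            logger.warning("specimen %s has no depth; skipped", s.specimen_id)
            continue
        flagged = s.depth.kind == "range_midpoint" or s.depth.uncertain
        placed.append((s.depth.value_m, assignment.labels[s.specimen_id], flagged))
    if not placed:
        raise ValueError("no specimens with depth to bin")
    bins = sorted({math.floor(d / bin_width) * bin_width for d, _, _ in placed})
    min_depth: dict[int, float] = {}
    for d, code, _ in placed:
        min_depth[code] = min(min_depth.get(code, math.inf), d)
    cols = sorted(min_depth, key=lambda c: (min_depth[c], c))
    counts = pd.DataFrame(0, index=bins, columns=cols, dtype=int)
    uncertain = pd.DataFrame(0, index=bins, columns=cols, dtype=int)
    for d, code, flagged in placed:
        row = math.floor(d / bin_width) * bin_width
        counts.loc[row, code] += 1
        if flagged:
            uncertain.loc[row, code] += 1
    return OccupancyMatrix(
        counts=counts, uncertain=uncertain,
        bin_width=bin_width, n_missing_depth=n_missing,
    )


@dataclass(frozen=True)
class HaplotypeRange:
    """Observed range of one haplotype: sites, regions, depths, geo span.

    ``geo_span_km`` is the maximum pairwise great-circle distance among
    occurrence sites with coordinates, and is None (undefined, not zero)
    when fewer than two sites have coordinates.
    """

    code: int
    sites: frozenset[str]
    regions: frozenset[str]
    depth_min: float | None
    depth_max: float | None
    geo_span_km: float | None
    n_specimens: int

    def to_dict(self) -> dict:
        return {
            "haplotype": self.code,
            "sites": sorted(self.sites),
            "regions": sorted(self.regions),
            "depth_min_m": self.depth_min,
            "depth_max_m": self.depth_max,
            "geo_span_km": self.geo_span_km,
            "n_specimens": self.n_specimens,
        }


def range_summary(
    assignment: HaplotypeAssignment,
    specimens: Sequence[SpecimenRecord],
) -> list[HaplotypeRange]:
    """Per-haplotype site/region sets, depth extremes, and geographic span."""
    members: dict[int, list[SpecimenRecord]] = {}
    for s in specimens:
        code = assignment.labels.get(s.specimen_id)
        if code is not None:
            members.setdefault(code, []).append(s)
    out = []
    for code in sorted(members):
        group = members[code]
        depths = [s.depth.value_m for s in group if s.depth.kind != "missing"]
        coords: dict[str, tuple[float, float]] = {
            s.site: (s.lat, s.lon)
            for s in group
            if s.lat is not None and s.lon is not None
        }
        span = None
        if len(coords) >= 2:
            pts = list(coords.values())
            span = max(
                haversine_km(pts[i], pts[j])
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            )
        out.append(
            HaplotypeRange(
                code=code,
                sites=frozenset(s.site for s in group),
                regions=frozenset(s.region for s in group),
                depth_min=min(depths) if depths else None,
                depth_max=max(depths) if depths else None,
                geo_span_km=span,
                n_specimens=len(group),
            )
        )
    return out
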