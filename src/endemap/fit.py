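"""Species-to-area fit index against candidate areas of endemism.

For a species and a candidate AoE, both expressed as occupied one-degree grid
cells, the fit is (a + b) / c where a is the percentage of the species' cells
inside the area, b the percentage of the area's cells the species occupies,
and c = 200 (the sum of the two maxima), giving an index in [0, 1]. An area's
score averages the indices of its qualifying species - those with more than
90% of their distribution inside it (the threshold is exposed because it is
an explicitly arbitrary restriction rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .core_data import PresenceAbsenceMatrix


@dataclass(frozen=True)
class FitComponents:
    taxon_id: str
    a: float  # % of species distribution inside the AoE
    b: float  # % of AoE area occupied by the species
    c: float = 200.0

    @property
    def index(self) -> float:
        return (self.a + self.b) / self.c


@dataclass
class AoEFitReport:
    aoe_id: str
    qualifying_taxa: list[str]
    components: list[FitComponents]
    mean_index: float
    n_exclusive: int
    n_cells: int


@dataclass
class FitAnalysis:
    reports: list[AoEFitReport]
    unassigned_taxa: list[str]  # taxa qualifying for no candidate area
    pooled_mean_index: float  # mean over all qualifying (species, AoE) pairs
    mean_of_aoe_means: float


def species_fit(species_cells: set[int], aoe_cells: set[int], taxon_id: str = "") -> FitComponents:
    """Fit components for one species against one area (same grid)."""
    if not aoe_cells:
        raise ValueError("degenerate area: empty AoE cell set")
    if not species_cells:
        raise ValueError("empty species cell set")
    inter = len(species_cells & aoe_cells)
    a = 100.0 * inter / len(species_cells)
    b = 100.0 * inter / len(aoe_cells)
    return FitComponents(taxon_id, a, b)


def rasterize_polygon_to_cells(polygon, pam: PresenceAbsenceMatrix, all_cells: bool = True) -> set[int]:
    """Cells whose centroid lies inside *polygon*.

    With *all_cells* (default) every grid cell is considered; otherwise only
    the occupied cells of the matrix.
    """
    grid = pam.grid
    if all_cells:
        idx = np.arange(grid.n_cells)
    else:
        idx = np.asarray(pam.cells)
    lon, lat = grid.cell_centroid(idx)
    inside = shapely.contains_xy(polygon, lon, lat)
    return set(idx[inside].tolist())


def aoe_fit_report(
    pam: PresenceAbsenceMatrix,
    aoe_polygons: dict,
    qualify_threshold: float = 90.0,
) -> FitAnalysis:
    """Fit reports for every candidate area polygon.

    Qualifying taxa have a > *qualify_threshold* (percent of their occupied
    cells inside the area); ``n_exclusive`` counts those fully inside
    (a = 100). Taxa qualifying for no area are listed separately. Both mean
    conventions are reported: the mean of per-area means and the pooled mean
    over all qualifying pairs.
    """
    species_cells = {t: pam.taxon_cells(t) for t in pam.taxa}
    reports: list[AoEFitReport] = []
    qualified_anywhere: set[str] = set()
    pooled: list[float] = []
    for aoe_id, poly in aoe_polygons.items():
        cells = rasterize_polygon_to_cells(poly, pam)
        if not cells:
            warnings.warn(f"area {aoe_id!r} rasterizes to zero cells; skipped")
            continue
        comps = []
        for t in pam.taxa:
            fc = species_fit(species_cells[t], cells, taxon_id=t)
            if fc.a > qualify_threshold:
                comps.append(fc)
        qualifying = [fc.taxon_id for fc in comps]
        qualified_anywhere.update(qualifying)
        mean_index = float(np.mean([fc.index for fc in comps])) if comps else float("nan")
        pooled.extend(fc.index for fc in comps)
        reports.append(
            AoEFitReport(
                aoe_id=str(aoe_id), qualifying_taxa=qualifying, components=comps,
                mean_index=mean_index,
                n_exclusive=sum(1 for fc in comps if fc.a == 100.0),
                n_cells=len(cells),
            )
        )
    unassigned = [t for t in pam.taxa if t not in qualified_anywhere]
    aoe_means = [r.mean_index for r in reports if not np.isnan(r.mean_index)]
    return FitAnalysis(
        reports=reports,
        unassigned_taxa=unassigned,
        pooled_mean_index=float(np.mean(pooled)) if pooled else float("nan"),
        mean_of_aoe_means=float(np.mean(aoe_means)) if aoe_means else float("nan"),
    )
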