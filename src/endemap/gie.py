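"""Geographical Interpolation of Endemism (GIE).

Species are binned into 11 range-size categories by the distance from their
range centroid to their farthest record. Within each category a kernel density
surface is interpolated over the species centroids (quartic kernel, bandwidth
tied to the category's upper bound), rescaled to [0, 1], and the per-category
layers are summed into a consensus endemism surface. Peaks of the consensus
mark areas of endemism (AoEs): places where the centroids of several
similar-ranged species stack up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .core_data import TaxonRangeSummary
from .raster import KernelSurface, RasterGeometry, quartic_kernel_surface

logger = logging.getLogger(__name__)

#: Upper bounds (km) of the 11 range-size categories; category 1 is [0, 100],
#: category i>1 is (bound[i-1], bound[i]].
CATEGORY_UPPER_KM = [100, 200, 400, 600, 800, 1000, 1200, 1400, 1600, 2000, 2150]


@dataclass(frozen=True)
class RangeCategory:
    index: int  # 1..11
    lower_km: float
    upper_km: float


def range_categories() -> list[RangeCategory]:
    lows = [0] + CATEGORY_UPPER_KM[:-1]
    return [
        RangeCategory(i + 1, float(lo), float(hi))
        for i, (lo, hi) in enumerate(zip(lows, CATEGORY_UPPER_KM))
    ]


def assign_category(summary: TaxonRangeSummary) -> RangeCategory:
    """Category whose (lower, upper] interval contains the taxon's range size.

    Ranges beyond the last bound (2150 km) are clamped into category 11 with a
    log message; the category system was designed for ranges up to that size.
    """
    d = summary.max_dist_km
    cats = range_categories()
    if d > cats[-1].upper_km:
        logger.warning(
            "range of %s (%.0f km) exceeds %d km; clamped to category 11",
            summary.taxon_id, d, int(cats[-1].upper_km),
        )
        return cats[-1]
    for c in cats:
        if d <= c.upper_km:
            return c
    return cats[-1]  # unreachable


@dataclass
class EndemismArea:
    id: int
    pixels: np.ndarray  # boolean mask on the consensus geometry
    polygon: object
    peak_index: float
    supporting_taxa: list[str]

    @property
    def n_synendemics(self) -> int:
        return len(self.supporting_taxa)


@dataclass
class GieResult:
    per_category: dict[int, KernelSurface]
    consensus: KernelSurface
    metadata: dict = field(default_factory=dict)


def gie_consensus(
    summaries: list[TaxonRangeSummary],
    geometry: RasterGeometry,
    bandwidth_for_category=None,
    assembly: str = "sum",
) -> GieResult:
    """Per-category standardized kernel surfaces and their consensus.

    *bandwidth_for_category* maps a :class:`RangeCategory` to a bandwidth in km
    (default: the category's upper bound). *assembly* is ``"sum"`` (default) or
    ``"max"`` over the standardized layers.
    """
    if not summaries:
        raise ValueError("no taxa")
    if assembly not in ("sum", "max"):
        raise ValueError("assembly must be 'sum' or 'max'")
    bw = bandwidth_for_category or (lambda c: c.upper_km)

    groups: dict[int, list[TaxonRangeSummary]] = {}
    cat_by_index = {c.index: c for c in range_categories()}
    for s in summaries:
        groups.setdefault(assign_category(s).index, []).append(s)

    per_category: dict[int, KernelSurface] = {}
    consensus = np.zeros((geometry.ny, geometry.nx))
    for ci in sorted(groups):
        members = groups[ci]
        surf = quartic_kernel_surface(
            [s.centroid[0] for s in members],
            [s.centroid[1] for s in members],
            bandwidth_km=float(bw(cat_by_index[ci])),
            geometry=geometry,
        )
        m = surf.max()
        vals = surf.values / m if m > 0 else surf.values
        per_category[ci] = KernelSurface(geometry, vals)
        if assembly == "sum":
            consensus += vals
        else:
            consensus = np.maximum(consensus, vals)

    meta = {
        "kernel": "quartic",
        "bandwidth_km_by_category": {ci: float(bw(cat_by_index[ci])) for ci in per_category},
        "assembly": assembly,
        "n_taxa": len(summaries),
    }
    return GieResult(per_category, KernelSurface(geometry, consensus), metadata=meta)


def delineate_aoes(
    consensus: KernelSurface,
    summaries: list[TaxonRangeSummary] | None = None,
    threshold_frac: float = 0.3,
    method: str = "watershed",
    min_separation_deg: float = 2.0,
    supporting_rule: str = "endemic",
    records_by_taxon: dict | None = None,
) -> list[EndemismArea]:
    """Delineate areas of endemism from the consensus surface.

    The default ``method="watershed"`` finds local maxima of the consensus that
    rise above ``background + threshold_frac * (global max - background)``
    (background = the surface median, the level set by widespread species),
    splits the surface into their watershed basins so that neighbouring areas
    separate at saddles, and keeps, within each basin, the connected pixels
    above ``background + threshold_frac * (peak - background)``. Peaks closer
    than *min_separation_deg* merge. ``method="global"`` is the plain rule:
    8-connected components of pixels >= ``threshold_frac * global max``.

    Supporting (synendemic) taxa per area, by *supporting_rule*:

    - ``"endemic"`` (default): range centroid inside the area and range radius
      (max_dist_km) no larger than the area's equivalent-circle radius - a
      species whose range dwarfs the area cannot be endemic to it;
    - ``"centroid"``: centroid inside, regardless of range size;
    - ``"record"``: any record inside (requires *records_by_taxon*:
      taxon -> (n, 2) lon/lat array).

    Areas are ordered by decreasing peak index. A flat-zero surface yields no
    areas.
    """
    v = consensus.values
    vmax = consensus.max()
    if vmax <= 0:
        return []
    g = consensus.geometry

    comps: list[np.ndarray] = []
    if method == "global":
        mask = v >= threshold_frac * vmax
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        comps = [labels == lab for lab in range(1, n + 1)]
    elif method == "watershed":
        from skimage.feature import peak_local_max
        from skimage.segmentation import watershed

        background = float(np.median(v))
        floor = background + threshold_frac * (vmax - background)
        min_px = max(1, int(round(min_separation_deg / g.pixel_size)))
        peaks = peak_local_max(
            v, min_distance=min_px, threshold_abs=floor, exclude_border=False
        )
        if len(peaks) == 0:
            return []
        markers = np.zeros_like(v, dtype=int)
        for i, (r, c) in enumerate(peaks):
            markers[r, c] = i + 1
        basins = watershed(-v, markers)
        for i, (r, c) in enumerate(peaks):
            cut = background + threshold_frac * (float(v[r, c]) - background)
            mask = (basins == i + 1) & (v >= cut)
            labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
            comps.append(labels == labels[r, c])
    else:
        raise ValueError("method must be 'watershed' or 'global'")

    px_area_km2 = np.broadcast_to(g.pixel_area_km2(), v.shape)
    areas = []
    for comp in comps:
        peak = float(v[comp].max())
        poly = _pixels_to_polygon(comp, g)
        eq_radius_km = float(np.sqrt(px_area_km2[comp].sum() / np.pi))
        taxa = []
        if supporting_rule in ("endemic", "centroid") and summaries is not None:
            for s in summaries:
                if not _point_in_mask(s.centroid[0], s.centroid[1], comp, g):
                    continue
                if supporting_rule == "endemic" and s.max_dist_km > eq_radius_km:
                    continue
                taxa.append(s.taxon_id)
        elif supporting_rule == "record":
            if records_by_taxon is None:
                raise ValueError("records_by_taxon required for supporting_rule='record'")
            for t, pts in records_by_taxon.items():
                pts = np.asarray(pts)
                if any(_point_in_mask(x, y, comp, g) for x, y in pts):
                    taxa.append(t)
        areas.append(EndemismArea(0, comp, poly, peak, sorted(taxa)))
    areas.sort(key=lambda a: -a.peak_index)
    for i, a in enumerate(areas):
        a.id = i + 1
    return areas


def _point_in_mask(lon, lat, mask, g: RasterGeometry) -> bool:
    col = int((lon - g.lon_min) / g.pixel_size)
    row = int((g.lat_max - lat) / g.pixel_size)
    if 0 <= row < g.ny and 0 <= col < g.nx:
        return bool(mask[row, col])
    return False


def _pixels_to_polygon(mask, g: RasterGeometry):
    rows, cols = np.nonzero(mask)
    boxes = [
        box(
            g.lon_min + c * g.pixel_size,
            g.lat_max - (r + 1) * g.pixel_size,
            g.lon_min + (c + 1) * g.pixel_size,
            g.lat_max - r * g.pixel_size,
        )
        for r, c in zip(rows, cols)
    ]
    return unary_union(boxes)


def surface_correlation(s1: KernelSurface, s2: KernelSurface) -> float:
    """Pixel-to-pixel Pearson correlation between two surfaces (same geometry)."""
    if s1.geometry != s2.geometry:
        raise ValueError("surfaces must share a raster geometry")
    a = s1.values.ravel()
    b = s2.values.ravel()
    if a.size < 3:
        raise ValueError("need at least 3 pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant surface")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.corrcoef(a, b)[0, 1])
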