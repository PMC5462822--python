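"""Raster geometry, kernel surfaces and text-raster I/O.

A :class:`RasterGeometry` is a pixel grid over a lon/lat extent, finer than the
analysis grid, on which kernel-index surfaces (endemism consensus, sampling
effort, kriged ordination scores) live. Surfaces are plain float arrays ordered
north-to-south, matching the ESRI ASCII grid layout used for export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_data import EARTH_RADIUS_KM, haversine_km

KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0  # 111.194926...


@dataclass(frozen=True)
class RasterGeometry:
    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    pixel_size: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def nx(self) -> int:
        return math.ceil((self.lon_max - self.lon_min) / self.pixel_size - 1e-9)

    @property
    def ny(self) -> int:
        return math.ceil((self.lat_max - self.lat_min) / self.pixel_size - 1e-9)

    def lons(self) -> np.ndarray:
        """Pixel-centre longitudes, west to east."""
        return self.lon_min + (np.arange(self.nx) + 0.5) * self.pixel_size

    def lats(self) -> np.ndarray:
        """Pixel-centre latitudes, north to south (row 0 is northernmost)."""
        return self.lat_max - (np.arange(self.ny) + 0.5) * self.pixel_size

    def pixel_area_km2(self) -> np.ndarray:
        """Per-row pixel area in km^2 (cos-latitude corrected), shape (ny, 1)."""
        a = (self.pixel_size * KM_PER_DEG) ** 2 * np.cos(np.radians(self.lats()))
        return a[:, None]


@dataclass
class KernelSurface:
    """A kernel-index raster: non-negative, finite values on a RasterGeometry."""

    geometry: RasterGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.ny, self.geometry.nx):
            raise ValueError("values shape does not match geometry")
        if not np.isfinite(self.values).all():
            raise ValueError("surface contains non-finite values")

    def max(self) -> float:
        return float(self.values.max())

    def copy_with(self, values: np.ndarray) -> "KernelSurface":
        return KernelSurface(self.geometry, values)


def quartic_kernel_surface(
    lons, lats, bandwidth_km: float, geometry: RasterGeometry, weights=None
) -> KernelSurface:
    """Quartic (biweight) kernel density over points, per km^2.

    Each point contributes K(d) = 3/(pi h^2) (1 - (d/h)^2)^2 for d < h, which
    integrates to one over the plane, so the pixel-sum times pixel area of a
    single-point surface is ~1. Distances are haversine km.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth_km must be positive")
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 0:
        raise ValueError("need at least one point")
    w = np.ones_like(lons) if weights is None else np.asarray(weights, dtype=float)

    glons = geometry.lons()
    glats = geometry.lats()
    out = np.zeros((geometry.ny, geometry.nx))
    norm = 3.0 / (math.pi * bandwidth_km**2)
    h_deg_lat = bandwidth_km / KM_PER_DEG
    for x0, y0, wi in zip(lons, lats, w):
        # restrict to the compact-support window to keep this linear in points
        coslat = max(math.cos(math.radians(y0)), 1e-6)
        h_deg_lon = h_deg_lat / coslat
        i0 = np.searchsorted(-glats, -(y0 + h_deg_lat))
        i1 = np.searchsorted(-glats, -(y0 - h_deg_lat))
        j0 = np.searchsorted(glons, x0 - h_deg_lon)
        j1 = np.searchsorted(glons, x0 + h_deg_lon)
        if i0 >= i1 or j0 >= j1:
            continue
        d = haversine_km(glons[None, j0:j1], glats[i0:i1, None], x0, y0)
        u = d / bandwidth_km
        k = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        out[i0:i1, j0:j1] += wi * norm * k
    return KernelSurface(geometry, out)


def write_esri_ascii(surface: KernelSurface, path, nodata: float = -9999.0) -> None:
    g = surface.geometry
    with open(path, "w") as fh:
        fh.write(f"ncols {g.nx}\nnrows {g.ny}\n")
        fh.write(f"xllcorner {g.lon_min}\nyllcorner {g.lat_min}\n")
        fh.write(f"cellsize {g.pixel_size}\nNODATA_value {nodata}\n")
        np.savetxt(fh, surface.values, fmt="%.6g")


def read_esri_ascii(path) -> KernelSurface:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cs = header["cellsize"]
    geom = RasterGeometry(
        lon_min=header["xllcorner"],
        lat_min=header["yllcorner"],
        lon_max=header["xllcorner"] + ncols * cs,
        lat_max=header["yllcorner"] + nrows * cs,
        pixel_size=cs,
    )
    return KernelSurface(geom, values.reshape(nrows, ncols))
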