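"""Occurrence I/O, grid geometry, presence/absence matrices and range summaries.

All coordinates are decimal degrees on WGS84. Metric distances are great-circle
(haversine) kilometres with Earth radius 6371.0 km; near the equator, where
these analyses operate, a degree grid is close to equal-area and no projection
is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

DEFAULT_COLUMNS = {
    "taxon": "taxon",
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
}


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced occurrence of a taxon."""

    taxon_id: str
    lon: float
    lat: float
    source_row: int = -1

    def __post_init__(self):
        if not self.taxon_id:
            raise ValueError("taxon_id must be non-empty")
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"coordinates out of range: ({self.lon}, {self.lat})")


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Cells are half-open ``[west, east) x (south, north]`` so that a point on a
    shared cell boundary belongs to exactly one cell. Cell indices are row-major
    from the north-west corner (row 0 is the northernmost band).
    """

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cell_size: float

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate extent")

    @property
    def n_cols(self) -> int:
        return math.ceil((self.lon_max - self.lon_min) / self.cell_size - 1e-9)

    @property
    def n_rows(self) -> int:
        return math.ceil((self.lat_max - self.lat_min) / self.cell_size - 1e-9)

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def cell_index(self, lon, lat):
        """Vectorised point -> cell index; -1 for points outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        # (south, north]: x = (lat_max - lat)/size lies in [r, r+1) exactly when
        # lat is in row r, so plain floor realises the convention.
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        idx = row * self.n_cols + col
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        return np.where(bad, -1, idx)

    def cell_centroid(self, idx):
        """Vectorised cell index -> (lon, lat) centre."""
        idx = np.asarray(idx, dtype=int)
        row, col = np.divmod(idx, self.n_cols)
        lon = self.lon_min + (col + 0.5) * self.cell_size
        lat = self.lat_max - (row + 0.5) * self.cell_size
        return lon, lat


@dataclass
class PresenceAbsenceMatrix:
    """Binary cell x taxon incidence on a :class:`GridSpec`.

    ``cells`` lists only occupied cell indices; ``record_counts`` keeps the raw
    record tally per cell (the sampling-effort signal), while ``matrix``
    collapses duplicates to presence.
    """

    grid: GridSpec
    taxa: list[str]
    cells: np.ndarray
    matrix: np.ndarray
    record_counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.shape != (len(self.cells), len(self.taxa)):
            raise ValueError("matrix shape does not match cells x taxa")
        if len(self.cells) and not (self.matrix.sum(axis=1) > 0).all():
            raise ValueError("retained cells must have at least one presence")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def cell_centroids(self) -> np.ndarray:
        lon, lat = self.grid.cell_centroid(self.cells)
        return np.column_stack([lon, lat])

    def taxon_cells(self, taxon_id: str) -> set[int]:
        j = self.taxa.index(taxon_id)
        return set(np.asarray(self.cells)[self.matrix[:, j] > 0].tolist())


@dataclass(frozen=True)
class TaxonRangeSummary:
    taxon_id: str
    centroid: tuple[float, float]
    max_dist_km: float
    n_records: int


@dataclass
class ReadResult:
    records: list[OccurrenceRecord]
    rejections: pd.DataFrame  # columns: row, reason


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km (R = 6371.0); broadcasts over arrays."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_points_km(p1, p2) -> float:
    """Distance between two (lon, lat) pairs in km."""
    return float(haversine_km(p1[0], p1[1], p2[0], p2[1]))


def read_occurrences(path, column_map: dict | None = None, sep: str | None = None) -> ReadResult:
    """Read occurrence records from delimited text.

    Expects columns for taxon, longitude and latitude; default names follow
    Darwin Core (``taxon``, ``decimalLongitude``, ``decimalLatitude``) and can
    be overridden with *column_map* (keys ``taxon``/``lon``/``lat``).
    Invalid rows are not fatal: they are returned in the rejection report with
    a reason and the 0-based data row index.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot parse occurrence file {path}: {exc}") from exc
    missing = [c for c in (cols["taxon"], cols["lon"], cols["lat"]) if c not in df.columns]
    if missing:
        raise KeyError(f"missing mandatory column(s): {missing}; present: {list(df.columns)}")

    records: list[OccurrenceRecord] = []
    rejected: list[tuple[int, str]] = []
    taxa = df[cols["taxon"]]
    lons = pd.to_numeric(df[cols["lon"]], errors="coerce")
    lats = pd.to_numeric(df[cols["lat"]], errors="coerce")
    for i in range(len(df)):
        t = taxa.iloc[i]
        if pd.isna(t) or str(t).strip() == "":
            rejected.append((i, "empty taxon"))
            continue
        lo, la = lons.iloc[i], lats.iloc[i]
        if pd.isna(lo) or pd.isna(la):
            rejected.append((i, "non-numeric coordinate"))
            continue
        if not (-180.0 <= lo <= 180.0) or not (-90.0 <= la <= 90.0):
            rejected.append((i, "out of range"))
            continue
        records.append(OccurrenceRecord(str(t), float(lo), float(la), source_row=i))
    rej = pd.DataFrame(rejected, columns=["row", "reason"])
    return ReadResult(records=records, rejections=rej)


def records_from_dataframe(df: pd.DataFrame, column_map: dict | None = None) -> list[OccurrenceRecord]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    return [
        OccurrenceRecord(str(t), float(lo), float(la), source_row=i)
        for i, (t, lo, la) in enumerate(
            zip(df[cols["taxon"]], df[cols["lon"]], df[cols["lat"]])
        )
    ]


def build_presence_matrix(records, grid: GridSpec) -> PresenceAbsenceMatrix:
    """Grid records into a binary cell x taxon matrix.

    Multiple records of a taxon in one cell collapse to one presence; the raw
    per-cell record count is preserved. Records outside the grid extent are
    dropped and reported under ``meta['n_outside']``.
    """
    if not records:
        raise ValueError("no data: empty record list")
    lon = np.array([r.lon for r in records])
    lat = np.array([r.lat for r in records])
    idx = np.asarray(GridSpec.cell_index(grid, lon, lat))
    inside = idx >= 0
    n_outside = int((~inside).sum())
    if not inside.any():
        raise ValueError("no data: all records fall outside the grid extent")
    idx = idx[inside]
    taxa_all = np.array([r.taxon_id for r in records])[inside]

    taxa = sorted(set(taxa_all.tolist()))
    taxon_pos = {t: j for j, t in enumerate(taxa)}
    cells = np.unique(idx)
    cell_pos = {c: i for i, c in enumerate(cells.tolist())}

    mat = np.zeros((len(cells), len(taxa)), dtype=np.uint8)
    counts = np.zeros(len(cells), dtype=np.int64)
    for c, t in zip(idx.tolist(), taxa_all.tolist()):
        i = cell_pos[c]
        mat[i, taxon_pos[t]] = 1
        counts[i] += 1
    return PresenceAbsenceMatrix(
        grid=grid, taxa=taxa, cells=cells, matrix=mat, record_counts=counts,
        meta={"n_outside": n_outside},
    )


def filter_cells_by_records(pam: PresenceAbsenceMatrix, min_records: int = 10) -> PresenceAbsenceMatrix:
    """Drop cells with fewer than *min_records* records.

    Sparsely collected cells inflate dissimilarities downstream, so cells below
    the record threshold are removed; taxa left with no presence are dropped
    and listed in ``meta['dropped_taxa']``.
    """
    keep = pam.record_counts >= min_records
    if not keep.any():
        raise ValueError("no cells survive filter")
    mat = pam.matrix[keep]
    col_keep = mat.sum(axis=0) > 0
    dropped = [t for t, k in zip(pam.taxa, col_keep) if not k]
    meta = dict(pam.meta)
    meta["dropped_taxa"] = dropped
    return PresenceAbsenceMatrix(
        grid=pam.grid,
        taxa=[t for t, k in zip(pam.taxa, col_keep) if k],
        cells=pam.cells[keep],
        matrix=mat[:, col_keep],
        record_counts=pam.record_counts[keep],
        meta=meta,
    )


def taxon_range_summary(records) -> list[TaxonRangeSummary]:
    """Per-taxon range centroid and distance to the farthest record.

    The centroid is the unweighted mean of the record coordinates; the range
    statistic is the haversine distance from that centroid to the farthest
    record, the quantity the range-size categories are defined on.
    """
    by_taxon: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        by_taxon.setdefault(r.taxon_id, []).append(r)
    out = []
    for t in sorted(by_taxon):
        rs = by_taxon[t]
        lon = np.array([r.lon for r in rs])
        lat = np.array([r.lat for r in rs])
        c = (float(lon.mean()), float(lat.mean()))
        d = haversine_km(c[0], c[1], lon, lat)
        out.append(TaxonRangeSummary(t, c, float(np.max(d)), len(rs)))
    return out


# ---------------------------------------------------------------------------
# exports

def pam_to_wide_csv(pam: PresenceAbsenceMatrix, path) -> None:
    """Wide CSV: one row per occupied cell with centroid, counts and taxa 0/1."""
    lon, lat = pam.grid.cell_centroid(pam.cells)
    df = pd.DataFrame(pam.matrix, columns=pam.taxa)
    df.insert(0, "record_count", pam.record_counts)
    df.insert(0, "lat", lat)
    df.insert(0, "lon", lon)
    df.insert(0, "cell", pam.cells)
    df.to_csv(path, index=False)


def _cell_labels(pam: PresenceAbsenceMatrix) -> list[str]:
    return [f"cell_{c}" for c in np.asarray(pam.cells).tolist()]


def pam_to_nexus(pam: PresenceAbsenceMatrix, path, outgroup: str | None = None) -> None:
    """NEXUS binary matrix with cells as taxa (interop with parsimony tools)."""
    labels = _cell_labels(pam)
    rows = ["".join(str(int(v)) for v in row) for row in pam.matrix]
    if outgroup is not None:
        labels = [outgroup] + labels
        rows = ["0" * pam.n_taxa] + rows
    width = max(len(s) for s in labels) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(labels)} NCHAR={pam.n_taxa};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n  MATRIX\n')
        for lab, row in zip(labels, rows):
            fh.write(f"    {lab.ljust(width)}{row}\n")
        fh.write("  ;\nEND;\n")


def pam_to_tnt(pam: PresenceAbsenceMatrix, path, outgroup: str = "ROOT") -> None:
    """TNT xread block; the all-absent outgroup row comes first (TNT roots on it)."""
    labels = [outgroup] + _cell_labels(pam)
    rows = ["0" * pam.n_taxa] + ["".join(str(int(v)) for v in row) for row in pam.matrix]
    with open(path, "w") as fh:
        fh.write("xread\n")
        fh.write(f"{pam.n_taxa} {len(labels)}\n")
        for lab, row in zip(labels, rows):
            fh.write(f"{lab} {row}\n")
        fh.write(";\n")
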