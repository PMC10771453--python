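"""Resistance landscapes with a fenced highway and permeable culverts.

Rasters hold movement resistance in [0, 1] (0 = fully permeable, 1 =
impassable) at a fixed 0.6-m cell — the width of the smallest culvert in
the study area, so every culvert spans an integer number of columns.  The
highway is an east-west band of resistance-1 cells (exclusionary fencing
makes it otherwise impassable); culverts are low-resistance corridors
through the band (0.05 inside, 0.25 on the mouth aprons, reflecting their
attractiveness as burrow surrogates).

Conventions: row 0 is the northernmost row; cells are addressed (row, col)
0-based; the world-to-grid mapping is half-open on cell edges.  Scenario
construction is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResistanceRaster",
    "CulvertSpec",
    "ScenarioConfig",
    "PlotRegion",
    "rescale_resistance",
    "build_scenario",
    "culvert_cells",
    "plot_regions",
    "read_ascii_grid",
    "write_ascii_grid",
]

CELL_M = 0.6
ROAD_RESISTANCE = 1.0
CULVERT_INTERIOR_RESISTANCE = 0.05
CULVERT_APRON_RESISTANCE = 0.25

#: the ten valid design scenarios: (n_culverts, width_m, placement)
VALID_SCENARIOS = tuple(
    [(n, w, "single") for n in (7, 14, 28) for w in (0.61, 1.83)]
    + [(n, w, "paired") for n in (7, 14) for w in (0.61, 1.83)]
)


@dataclass
class ResistanceRaster:
    """A resistance grid plus its georeferencing and highway band.

    ``values`` is (nrows, ncols) float32 in [0, 1]; ``x_origin`` is the west
    edge and ``y_top`` the north edge (projected metres); ``band_y`` is the
    (y_min, y_max) extent of the highway band, or ``None``.
    """

    values: np.ndarray
    cell: float = CELL_M
    x_origin: float = 0.0
    y_top: float = 0.0
    band_y: tuple | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("resistance values must lie in [0, 1]")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def y_bottom(self) -> float:
        return self.y_top - self.nrows * self.cell

    @property
    def x_right(self) -> float:
        return self.x_origin + self.ncols * self.cell

    def world_to_cell(self, x: float, y: float) -> tuple:
        col = int(math.floor((x - self.x_origin) / self.cell))
        row = int(math.floor((self.y_top - y) / self.cell))
        return row, col

    def rows_for_y(self, y_min: float, y_max: float) -> tuple:
        """Half-open row range [r0, r1) covering world interval [y_min, y_max)."""
        r0 = int(round((self.y_top - y_max) / self.cell))
        r1 = int(round((self.y_top - y_min) / self.cell))
        return max(r0, 0), min(r1, self.nrows)

    def cols_for_x(self, x_min: float, x_max: float) -> tuple:
        c0 = int(round((x_min - self.x_origin) / self.cell))
        c1 = int(round((x_max - self.x_origin) / self.cell))
        return max(c0, 0), min(c1, self.ncols)

    @property
    def band_rows(self) -> tuple | None:
        if self.band_y is None:
            return None
        return self.rows_for_y(*self.band_y)

    @property
    def band_y_center(self) -> float:
        if self.band_y is None:
            raise ValueError("raster has no highway band")
        return 0.5 * (self.band_y[0] + self.band_y[1])


@dataclass(frozen=True)
class CulvertSpec:
    """One culvert corridor through the highway band."""

    center_x: float
    width_m: float
    interior_resistance: float = CULVERT_INTERIOR_RESISTANCE
    apron_resistance: float = CULVERT_APRON_RESISTANCE
    apron_depth_m: float = 3.0

    def __post_init__(self):
        if self.width_m <= 0:
            raise ValueError("culvert width must be positive")
        if not self.interior_resistance < self.apron_resistance < ROAD_RESISTANCE:
            raise ValueError("need interior < apron < road resistance")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named culvert-design scenario on the fenced highway.

    The highway length defaults to 17.5 km, which makes all three culvert
    densities consistent with their stated spacings (7 -> 2.5 km,
    14 -> 1.25 km, 28 -> 625 m).  ``n_culverts`` counts *locations*; paired
    placement puts two culvert footprints (``pair_offset_m`` apart,
    centre-to-centre) at each location.
    """

    n_culverts: int
    width_m: float
    placement: str = "single"
    pair_offset_m: float = 10.0
    highway_length_km: float = 17.5
    band_depth_m: float = 30.0
    apron_depth_m: float = 3.0
    base_resistance: float = 0.2
    height_m: float = 1800.0
    cell: float = CELL_M
    validate_design: bool = True

    def __post_init__(self):
        if self.placement not in ("single", "paired"):
            raise ValueError("placement must be 'single' or 'paired'")
        if self.validate_design and (self.n_culverts, self.width_m, self.placement) not in VALID_SCENARIOS:
            raise ValueError(
                f"({self.n_culverts}, {self.width_m}, {self.placement}) is not one of the "
                f"ten design scenarios; pass validate_design=False for a custom design"
            )

    @property
    def label(self) -> str:
        return f"{self.n_culverts}x{self.width_m:g}m-{self.placement}"

    @property
    def spacing_m(self) -> float:
        """Centre-to-centre spacing between culvert locations."""
        return self.highway_length_km * 1000.0 / self.n_culverts

    def culvert_centers(self) -> list:
        """World x of every culvert footprint centre, evenly spaced."""
        L = self.highway_length_km * 1000.0
        locs = [(i + 0.5) * L / self.n_culverts for i in range(self.n_culverts)]
        if self.placement == "single":
            return locs
        half = self.pair_offset_m / 2.0
        return [c + s for c in locs for s in (-half, half)]


def rescale_resistance(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale a raw connectivity/resistance grid into [0, 1].

    0 means permeable, 1 impassable.  A grid already inside [0, 1] is
    returned unchanged (idempotent on the canonical range); a constant grid
    has no defined rescale and raises.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("raw grid contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if lo >= 0 and hi <= 1:
        return raw.copy()
    if hi == lo:
        raise ValueError("constant grid: min-max rescale undefined")
    return (raw - lo) / (hi - lo)


def build_scenario(config: ScenarioConfig, base: ResistanceRaster | None = None):
    """Render a culvert scenario into a resistance raster.

    If ``base`` is None a flat synthetic landscape of
    ``config.base_resistance`` is built (stand-in for the external
    landscape-connectivity model, which is not redistributable).  The
    highway band is centred vertically.  Returns ``(raster, culverts)``.

    Raises if culvert footprints (including pair members) overlap.
    """
    cell = config.cell
    if base is None:
        ncols = int(round(config.highway_length_km * 1000.0 / cell))
        nrows = int(round(config.height_m / cell))
        values = np.full((nrows, ncols), config.base_resistance, dtype=np.float32)
        raster = ResistanceRaster(values, cell=cell, x_origin=0.0, y_top=config.height_m)
    else:
        raster = ResistanceRaster(base.values.copy(), base.cell, base.x_origin, base.y_top)
        cell = raster.cell

    y_mid = (raster.y_top + raster.y_bottom) / 2.0
    band_y = (y_mid - config.band_depth_m / 2.0, y_mid + config.band_depth_m / 2.0)
    raster.band_y = band_y
    r0, r1 = raster.rows_for_y(*band_y)
    raster.values[r0:r1, :] = ROAD_RESISTANCE

    centers = config.culvert_centers()
    culverts = [
        CulvertSpec(cx, config.width_m, apron_depth_m=config.apron_depth_m)
        for cx in centers
    ]

    # overlap check on column footprints
    spans = []
    for c in culverts:
        cols = _culvert_cols(c, raster)
        spans.append(cols)
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("culvert footprints overlap")

    ar = int(round(config.apron_depth_m / cell))
    for c in culverts:
        c0, c1 = _culvert_cols(c, raster)
        # aprons first, then interior (interior wins where they meet)
        raster.values[max(r0 - ar, 0):r0, c0:c1] = c.apron_resistance
        raster.values[r1:min(r1 + ar, raster.nrows), c0:c1] = c.apron_resistance
        raster.values[r0:r1, c0:c1] = c.interior_resistance
    return raster, culverts


def _odd_column_count(width_m: float, cell: float) -> int:
    """Culvert width in columns: width / cell rounded to the nearest odd count."""
    n = max(1, round(width_m / cell))
    if n % 2 == 0:
        n = n + 1 if (width_m / cell) >= n else n - 1
    return max(1, n)


def _culvert_cols(spec: CulvertSpec, raster: ResistanceRaster) -> tuple:
    n = _odd_column_count(spec.width_m, raster.cell)
    ccol = int(math.floor((spec.center_x - raster.x_origin) / raster.cell))
    c0 = ccol - n // 2
    c1 = ccol + n // 2 + 1
    if c0 < 0 or c1 > raster.ncols:
        raise ValueError(f"culvert at x={spec.center_x} outside raster extent")
    return c0, c1


def culvert_cells(spec: CulvertSpec, raster: ResistanceRaster) -> np.ndarray:
    """(row, col) indices of the culvert interior spanning the highway band."""
    if raster.band_y is None:
        raise ValueError("raster has no highway band")
    r0, r1 = raster.band_rows
    c0, c1 = _culvert_cols(spec, raster)
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return np.column_stack([rows.ravel(), cols.ravel()])


def culvert_id_grid(raster: ResistanceRaster, culverts) -> np.ndarray:
    """Int32 grid: culvert index at interior cells, -1 elsewhere."""
    grid = np.full(raster.values.shape, -1, dtype=np.int32)
    for i, c in enumerate(culverts):
        cells = culvert_cells(c, raster)
        grid[cells[:, 0], cells[:, 1]] = i
    return grid


@dataclass(frozen=True)
class PlotRegion:
    """Semicircular capture/release plot on one side of the highway.

    ``anchor`` is the (x, y) point on the band edge nearest the culvert;
    the semicircle opens away from the highway.
    """

    anchor: tuple
    side: str
    radius_m: float = 800.0

    def __post_init__(self):
        if self.side not in ("north", "south"):
            raise ValueError("side must be 'north' or 'south'")

    def contains(self, x: float, y: float) -> bool:
        ax, ay = self.anchor
        if self.side == "north" and y < ay:
            return False
        if self.side == "south" and y > ay:
            return False
        return (x - ax) ** 2 + (y - ay) ** 2 <= self.radius_m**2


def plot_regions(culverts, raster: ResistanceRaster, radius_m: float = 800.0) -> list:
    """Two semicircular plots (north and south) per culvert anchor.

    Anchors sit on the band edges so footprints are entirely off the
    highway; pair members share a location, so paired culverts are first
    collapsed to unique locations (within the pair offset).
    """
    if raster.band_y is None:
        raise ValueError("raster has no highway band")
    y_lo, y_hi = raster.band_y
    xs = sorted(c.center_x for c in culverts)
    anchors = []
    for x in xs:
        if anchors and abs(x - anchors[-1]) < 20.0:  # collapse pair members
            anchors[-1] = (anchors[-1] + x) / 2.0
        else:
            anchors.append(x)
    regions = []
    for ax in anchors:
        regions.append(PlotRegion((ax, y_hi), "north", radius_m))
        regions.append(PlotRegion((ax, y_lo), "south", radius_m))
    return regions


# ---------------------------------------------------------------------------
# raster I/O (Esri ASCII grid)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: ResistanceRaster, path) -> None:
    """Write an Esri ASCII grid (text)."""
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x_origin}\n"
        f"yllcorner {raster.y_bottom}\n"
        f"cellsize {raster.cell}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.4g")


def read_ascii_grid(path) -> ResistanceRaster:
    with open(path) as fh:
        hdr = {}
        while len(hdr) < 6:
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=np.float32)
    values = np.atleast_2d(values)
    cell = hdr["cellsize"]
    return ResistanceRaster(
        values,
        cell=cell,
        x_origin=hdr["xllcorner"],
        y_top=hdr["yllcorner"] + values.shape[0] * cell,
    )


def culverts_to_csv(culverts, path) -> None:
    pd.DataFrame(
        {
            "culvert_id": range(len(culverts)),
            "center_x": [c.center_x for c in culverts],
            "width_m": [c.width_m for c in culverts],
            "interior_resistance": [c.interior_resistance for c in culverts],
            "apron_resistance": [c.apron_resistance for c in culverts],
        }
    ).to_csv(path, index=False)


def culverts_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        CulvertSpec(r.center_x, r.width_m, r.interior_resistance, r.apron_resistance)
        for r in df.itertuples()
    ]
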