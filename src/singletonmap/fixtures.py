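"""Deterministic, programmatically generated fixtures.

Everything here is synthetic: a stylized Africa-like habitat raster at the
87 x 83 deme resolution used by the continental simulations, a small 20 x 20
demo raster for fast examples and tests, a synthetic set of 146 accession
coordinates inside the Sahel prior box, and a small demo genotype matrix.
The Africa-like raster is a coarse hand-parameterized coastline polygon with
latitude-band vegetation classes - it is a plausible stand-in, not a
digitized map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expansion import HABITAT_CODES, DemeGrid
from .haplotypes import HaplotypeMatrix

__all__ = [
    "africa_like_grid",
    "demo_grid",
    "synthetic_accessions",
    "demo_matrix",
    "make_fixtures",
    "FixtureBundle",
]

# Coarse Africa-like coastline polygon, (lon, lat) vertices.  Stylized.
_AFRICA_OUTLINE = [
    (-17.0, 14.5), (-16.5, 21.0), (-13.0, 27.5), (-9.5, 31.5), (-5.0, 35.5),
    (3.0, 36.8), (10.0, 37.2), (11.5, 33.5), (19.0, 32.0), (28.0, 31.0),
    (32.5, 31.0), (34.0, 28.0), (36.5, 22.0), (38.5, 18.0), (43.0, 11.5),
    (48.0, 11.0), (51.0, 12.0), (51.0, 10.5), (47.5, 4.5), (41.0, -2.0),
    (40.5, -11.0), (36.0, -18.0), (35.0, -24.0), (32.5, -29.0), (27.5, -34.0),
    (20.0, -34.8), (18.0, -32.0), (15.5, -27.0), (12.0, -18.0), (13.5, -11.0),
    (9.5, -2.0), (8.5, 4.0), (3.0, 6.3), (-4.0, 5.2), (-8.0, 4.3),
    (-13.0, 7.5), (-17.0, 14.5),
]


def _rasterize_outline(grid_lons, grid_lats) -> np.ndarray:
    from matplotlib.path import Path as MplPath

    poly = MplPath(np.asarray(_AFRICA_OUTLINE))
    GX, GY = np.meshgrid(grid_lons, grid_lats)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    return poly.contains_points(pts).reshape(GX.shape)


def africa_like_grid(nrows: int = 87, ncols: int = 83) -> DemeGrid:
    """Stylized Africa-like land/sea + vegetation raster.

    Extent roughly lon [-19, 55], lat [-36, 41] at ~0.89 deg cells.
    Vegetation classes are simple latitude bands: extreme desert (Sahara
    band), semi-desert (Sahel and a southern band), rain forest (equatorial
    west/central Africa), other land elsewhere.
    """
    xll, yll = -19.0, -36.0
    cellsize = 74.0 / ncols  # ~0.89 deg; 87 rows span ~77.6 deg of latitude
    lons = xll + (np.arange(ncols) + 0.5) * cellsize
    lats = yll + (nrows - 1 - np.arange(nrows) + 0.5) * cellsize
    land = _rasterize_outline(lons, lats)
    hab = np.where(land, HABITAT_CODES["other"], HABITAT_CODES["sea"]).astype(
        np.int8
    )
    LON, LAT = np.meshgrid(lons, lats)
    sahara = land & (LAT > 18.0) & (LAT < 30.0)
    sahel = land & (LAT > 12.0) & (LAT <= 18.0)
    kalahari = land & (LAT > -28.0) & (LAT < -19.0)
    forest = land & (LAT > -6.0) & (LAT < 6.5) & (LON > 7.0) & (LON < 31.0)
    hab[sahel | kalahari] = HABITAT_CODES["semi-desert"]
    hab[sahara] = HABITAT_CODES["extreme-desert"]
    hab[forest] = HABITAT_CODES["rain-forest"]
    cap = np.where(hab > 0, 100.0, 0.0)
    return DemeGrid(cap, xll, yll, cellsize, hab)


def demo_grid(size: int = 20) -> DemeGrid:
    """Small demo raster: land interior with a one-cell sea border and a
    vegetation stripe, extent lon/lat [0, size] at 1-degree cells."""
    hab = np.zeros((size, size), dtype=np.int8)
    hab[1:-1, 1:-1] = HABITAT_CODES["other"]
    stripe = slice(size // 2 - 1, size // 2 + 1)
    hab[stripe, 1:-1] = np.where(
        hab[stripe, 1:-1] > 0, HABITAT_CODES["semi-desert"], 0
    )
    cap = np.where(hab > 0, 100.0, 0.0)
    return DemeGrid(cap, 0.0, 0.0, 1.0, hab)


def synthetic_accessions(
    rng: np.random.Generator,
    n: int = 146,
    grid: DemeGrid | None = None,
) -> pd.DataFrame:
    """Synthetic accession coordinates inside the Sahel prior box
    (lon [-16, 40], lat [5, 30]), restricted to habitable cells."""
    if grid is None:
        grid = africa_like_grid()
    out = []
    while len(out) < n:
        lon = rng.uniform(-16.0, 40.0)
        lat = rng.uniform(5.0, 30.0)
        try:
            r, c = grid.cell_of(lon, lat)
        except ValueError:
            continue
        if grid.is_habitable(r, c):
            out.append((f"acc{len(out):03d}", lon, lat))
    return pd.DataFrame(out, columns=["id", "lon", "lat"])


def demo_matrix(rng: np.random.Generator, n: int = 10, L: int = 50) -> HaplotypeMatrix:
    """Small random haplotype matrix with a sprinkling of missing calls."""
    freq = rng.uniform(0.02, 0.5, size=L)
    alleles = (rng.random((n, L)) < freq[None, :]).astype(np.int8)
    alleles[rng.random((n, L)) < 0.05] = -1
    return HaplotypeMatrix(alleles)


@dataclass
class FixtureBundle:
    africa_raster: Path
    demo_raster: Path
    accessions: Path
    demo_geno: Path


def make_fixtures(out_dir, seed: int = 0) -> FixtureBundle:
    """Write all fixtures deterministically from a seed."""
    from .io import write_esri_ascii, write_geno

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    africa = africa_like_grid()
    africa_path = out_dir / "africa_like_habitat.asc"
    write_esri_ascii(
        africa.habitat.astype(float), africa_path,
        africa.xllcorner, africa.yllcorner, africa.cellsize, nodata=-9999,
    )
    demo = demo_grid()
    demo_path = out_dir / "demo_habitat.asc"
    write_esri_ascii(
        demo.habitat.astype(float), demo_path,
        demo.xllcorner, demo.yllcorner, demo.cellsize, nodata=-9999,
    )
    acc = synthetic_accessions(rng, grid=africa)
    acc_path = out_dir / "synthetic_accessions.csv"
    acc.to_csv(acc_path, index=False)
    geno_path = out_dir / "demo.geno"
    write_geno(demo_matrix(rng), geno_path)
    return FixtureBundle(africa_path, demo_path, acc_path, geno_path)


def grid_from_habitat_raster(arr: np.ndarray, header: dict) -> DemeGrid:
    """Build a DemeGrid from a habitat-class ESRI ASCII raster."""
    hab = np.where(np.isnan(arr), 0, arr).astype(np.int8)
    cap = np.where(hab > 0, 100.0, 0.0)
    return DemeGrid(
        cap, header["xllcorner"], header["yllcorner"], header["cellsize"], hab
    )
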