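"""Minimal single-band raster container with ESRI ASCII grid I/O.

Elevation grids are stored with row 0 at the northern edge (the ESRI ASCII
convention) on a regular projected grid in local meters.  The container
carries the geographic anchor (reference lon/lat of the local frame) so
that nests or fixes given in lon/lat can be placed on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Dem:
    """Digital elevation model on a regular grid of square cells.

    Parameters
    ----------
    z
        Elevation in meters, shape (nrows, ncols), row 0 = north.
    cell_size
        Cell edge length in meters (> 0).
    xll, yll
        Local-meter coordinates of the lower-left corner of the grid.
    ref_lon, ref_lat
        Geographic anchor of the local frame (see :mod:`soarscape.geo`).
    """

    z: np.ndarray
    cell_size: float
    xll: float = 0.0
    yll: float = 0.0
    ref_lon: float = 18.5
    ref_lat: float = -32.1
    crs_tag: str = field(default="local-equirectangular-m")

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("elevation grid contains non-finite values")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape

    @property
    def nrows(self) -> int:
        return self.z.shape[0]

    @property
    def ncols(self) -> int:
        return self.z.shape[1]

    def x_centers(self) -> np.ndarray:
        """East coordinates of cell centers (length ncols)."""
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """North coordinates of cell centers (length nrows), row order (north first)."""
        top = self.yll + self.nrows * self.cell_size
        return top - (np.arange(self.nrows) + 0.5) * self.cell_size

    def contains(self, x, y) -> np.ndarray:
        """Whether local-meter points fall inside the grid extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.xll)
            & (x <= self.xll + self.ncols * self.cell_size)
            & (y >= self.yll)
            & (y <= self.yll + self.nrows * self.cell_size)
        )

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear elevation at local-meter points (clamped at the border)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cx = (x - self.xll) / self.cell_size - 0.5
        ry = (y - self.yll) / self.cell_size - 0.5  # rows from the south
        cx = np.clip(cx, 0.0, self.ncols - 1.0)
        ry = np.clip(ry, 0.0, self.nrows - 1.0)
        c0 = np.floor(cx).astype(int)
        r0 = np.floor(ry).astype(int)
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        fc = cx - c0
        fr = ry - r0
        zs = np.flipud(self.z)  # row 0 = south for the interpolation
        top = zs[r1, c0] * (1 - fc) + zs[r1, c1] * fc
        bot = zs[r0, c0] * (1 - fc) + zs[r0, c1] * fc
        return bot * (1 - fr) + top * fr

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing local-meter points (row 0 = north)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.clip(((x - self.xll) / self.cell_size).astype(int), 0, self.ncols - 1)
        row_s = np.clip(((y - self.yll) / self.cell_size).astype(int), 0, self.nrows - 1)
        return self.nrows - 1 - row_s, col

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (text)."""
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll!r}\n"
            f"yllcorner {self.yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.z, fmt="%.4f")

    @classmethod
    def read_ascii(cls, path, ref_lon: float = 18.5, ref_lat: float = -32.1) -> "Dem":
        """Read an ESRI ASCII grid written by :meth:`write_ascii`."""
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            z = np.loadtxt(fh)
        z = np.atleast_2d(z)
        return cls(
            z=z,
            cell_size=header["cellsize"],
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            ref_lon=ref_lon,
            ref_lat=ref_lat,
        )
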