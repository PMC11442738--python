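"""Raster grid geometry shared by the synthetic scenes and zonal extraction.

The scene coordinate frame is a simple local metric frame: x increases
eastward with column index, y increases southward with row index, and the
origin sits at the top-left corner of pixel (0, 0). Pixel centers are at
((col + 0.5) * pixel_size, (row + 0.5) * pixel_size). All rasters in a
scene share one grid; reprojection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: sentinel used when rasters are written to disk
NODATA = -9999.0


@dataclass(frozen=True)
class RasterGrid:
    """Shape and resolution of a scene's shared pixel grid.

    Parameters
    ----------
    rows, cols:
        Grid dimensions in pixels; must be positive.
    pixel_size_m:
        Side length of a square pixel in meters. Defaults to 70 m, the
        resolution of the ECOSTRESS thermal products this package emulates
        (0.49 ha per pixel).
    """

    rows: int
    cols: int
    pixel_size_m: float = 70.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.rows}x{self.cols}")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size_m**2 / 10_000.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in scene coordinates."""
        return (0.0, 0.0, self.cols * self.pixel_size_m, self.rows * self.pixel_size_m)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of every pixel center, row-major."""
        s = self.pixel_size_m
        xs = (np.arange(self.cols) + 0.5) * s
        ys = (np.arange(self.rows) + 0.5) * s
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()
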