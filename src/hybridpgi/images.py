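"""Pixelized 2D intensity maps on the beam-axis plane (z = 0).

Default field-of-view sizes follow the analysis conventions: the Compton
(PGI) FoV is 500 x 500 mm^2 in 1200 x 1200 pixels, the PET FoV is
300 x 300 mm^2 in 700 x 700 pixels.  ``values`` is indexed ``[iy, ix]``;
negative pixel values are permitted (the analytical inversion produces
side-lobes) and are only clipped at the range-metrics boundary.

Images serialize to a plain-text matrix format with '#'-prefixed header
lines carrying the extent and pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Image2D", "GridSpec", "pgi_grid", "pet_grid", "rebin"]


@dataclass(frozen=True)
class GridSpec:
    extent: tuple  # (x_min, x_max, y_min, y_max), mm
    nx: int
    ny: int

    def __post_init__(self):
        x0, x1, y0, y1 = self.extent
        if not (x0 < x1 and y0 < y1):
            raise ValueError("extent must be ordered")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("pixel counts must be positive")

    @property
    def pixel_size(self) -> tuple:
        x0, x1, y0, y1 = self.extent
        return ((x1 - x0) / self.nx, (y1 - y0) / self.ny)

    @property
    def x_centers(self) -> np.ndarray:
        x0, x1, _, _ = self.extent
        dx = (x1 - x0) / self.nx
        return x0 + dx * (np.arange(self.nx) + 0.5)

    @property
    def y_centers(self) -> np.ndarray:
        _, _, y0, y1 = self.extent
        dy = (y1 - y0) / self.ny
        return y0 + dy * (np.arange(self.ny) + 0.5)

    def empty(self) -> "Image2D":
        return Image2D(self, np.zeros((self.ny, self.nx)))


def pgi_grid(nx: int = 1200, ny: int = 1200,
             half_size: float = 250.0) -> GridSpec:
    """Default Compton FoV: 500 x 500 mm^2, 1200 x 1200 px."""
    return GridSpec((-half_size, half_size, -half_size, half_size), nx, ny)


def pet_grid(nx: int = 700, ny: int = 700,
             half_size: float = 150.0) -> GridSpec:
    """Default PET FoV: 300 x 300 mm^2, 700 x 700 px."""
    return GridSpec((-half_size, half_size, -half_size, half_size), nx, ny)


@dataclass
class Image2D:
    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})")

    @property
    def x_centers(self) -> np.ndarray:
        return self.grid.x_centers

    @property
    def y_centers(self) -> np.ndarray:
        return self.grid.y_centers

    def argmax_xy(self) -> tuple:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.x_centers[ix]), float(self.y_centers[iy])

    def copy_with(self, values: np.ndarray) -> "Image2D":
        return Image2D(self.grid, values)

    def same_grid(self, other: "Image2D") -> bool:
        return (self.grid.extent == other.grid.extent
                and self.grid.nx == other.grid.nx
                and self.grid.ny == other.grid.ny)


def rebin(image: Image2D, factor: int) -> Image2D:
    """Integer block-sum rebinning (pixel counts must divide by factor)."""
    ny, nx = image.values.shape
    if nx % factor or ny % factor:
        raise ValueError("pixel counts must be divisible by the rebin factor")
    v = image.values.reshape(ny // factor, factor, nx // factor, factor)
    g = GridSpec(image.grid.extent, nx // factor, ny // factor)
    return Image2D(g, v.sum(axis=(1, 3)))


def write_image(path, image: Image2D, meta: dict | None = None) -> None:
    x0, x1, y0, y1 = image.grid.extent
    header = [
        "hybridpgi image v1",
        f"extent_mm {x0} {x1} {y0} {y1}",
        f"pixels {image.grid.nx} {image.grid.ny}",
    ]
    for k, v in (meta or {}).items():
        header.append(f"{k} {v}")
    np.savetxt(path, image.values, header="\n".join(header))


def read_image(path) -> Image2D:
    extent = None
    nx = ny = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] == "extent_mm":
                extent = tuple(float(p) for p in parts[1:5])
            elif parts and parts[0] == "pixels":
                nx, ny = int(parts[1]), int(parts[2])
    if extent is None or nx is None:
        raise ValueError(f"{path}: missing image header")
    values = np.loadtxt(path)
    return Image2D(GridSpec(extent, nx, ny), values.reshape(ny, nx))
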