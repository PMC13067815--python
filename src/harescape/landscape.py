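"""Raster stack handling, buffer extraction, and terrain ruggedness.

Layers live on a shared planar 30-m grid (row 0 = northernmost row; x grows
east, y grows north). Cover type is categorical {open, conifer, deciduous,
mixed}; the remaining layers are continuous. Rasters are read and written as
plain gridded text with a small JSON header so a stack round-trips without
GIS dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve

COVER_CLASSES = ("open", "conifer", "deciduous", "mixed")
CONTINUOUS_LAYERS = ("canopy", "tree_density", "elevation", "vrm")


@dataclass
class LandscapeStack:
    """Co-registered named 2-D arrays on one grid.

    ``origin`` is the (x, y) of the *center* of the top-left cell;
    ``cell_size`` in meters.
    """

    grids: dict[str, np.ndarray]
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 30.0
    crs: str = "planar-meters"

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree in shape: {shapes}")
        if "canopy" in self.grids:
            c = self.grids["canopy"]
            if c.min() < 0 or c.max() > 100:
                raise ValueError("canopy outside [0, 100]")
        for name, g in self.grids.items():
            if np.isnan(np.asarray(g, dtype=float)).any():
                raise ValueError(f"NaN in layer {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) spanned by cell centers."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, x0 + (nc - 1) * self.cell_size,
                y0 - (nr - 1) * self.cell_size, y0)

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(round((x - x0) / self.cell_size))
        row = int(round((y0 - y) / self.cell_size))
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + np.arange(nc) * self.cell_size
        ys = y0 - np.arange(nr) * self.cell_size
        return xs, ys


@dataclass
class BufferSummary:
    """Per-layer summaries at a point: class proportions + continuous means."""

    cover_props: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)

    def as_covariates(self) -> dict[str, float]:
        out = {f"prop_{k}": v for k, v in self.cover_props.items()}
        out.update(self.means)
        return out


def _horn_normals(elev: np.ndarray, cell: float) -> tuple[np.ndarray, ...]:
    """Unit terrain-normal components (x, y, z) via Horn 3x3 gradients."""
    z = np.pad(np.asarray(elev, dtype=float), 1, mode="edge")
    # linear extrapolation at the borders keeps planes exactly planar
    z[0, :] = 2 * z[1, :] - z[2, :]
    z[-1, :] = 2 * z[-2, :] - z[-3, :]
    z[:, 0] = 2 * z[:, 1] - z[:, 2]
    z[:, -1] = 2 * z[:, -2] - z[:, -3]
    # Horn kernel: weights 1,2,1 along the orthogonal axis
    dz_dx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8.0 * cell)
    dz_dy = (
        (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
        - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
    ) / (8.0 * cell)
    slope = np.arctan(np.hypot(dz_dx, dz_dy))
    aspect = np.arctan2(dz_dy, -dz_dx)
    sin_s = np.sin(slope)
    # flat cells: sin(slope)=0 -> normal (0,0,1) regardless of aspect
    return sin_s * np.sin(aspect), sin_s * np.cos(aspect), np.cos(slope)


def compute_vrm(elevation: np.ndarray, window: int = 3,
                cell_size: float = 30.0) -> np.ndarray:
    """Vector ruggedness measure (Sappington): 1 - |R|/n over a moving window.

    Terrain unit normals from Horn slope/aspect are summed in the window;
    the normalized resultant length measures how parallel they are. 0 for
    flat or uniformly inclined terrain, toward 1 for broken terrain. Edge
    cells use the shrunken window that fits.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    elevation = np.asarray(elevation, dtype=float)
    if min(elevation.shape) < window:
        raise ValueError("elevation grid smaller than window")
    nx, ny, nz = _horn_normals(elevation, cell_size)
    kernel = np.ones((window, window))
    ones = np.ones_like(elevation)
    n = convolve(ones, kernel, mode="constant", cval=0.0)
    sx = convolve(nx, kernel, mode="constant", cval=0.0)
    sy = convolve(ny, kernel, mode="constant", cval=0.0)
    sz = convolve(nz, kernel, mode="constant", cval=0.0)
    resultant = np.sqrt(sx**2 + sy**2 + sz**2)
    return np.clip(1.0 - resultant / n, 0.0, 1.0)


def extract_buffer(stack: LandscapeStack, point: tuple[float, float],
                   radius: float) -> BufferSummary:
    """Summaries over cells whose centers lie within ``radius`` of ``point``.

    Categorical cover becomes class proportions (summing to 1); continuous
    layers become means. A radius smaller than half a cell reduces to the
    containing cell.
    """
    x, y = point
    xmin, xmax, ymin, ymax = stack.extent()
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    xs, ys = stack.cell_centers()
    dx2 = (xs - x) ** 2
    dy2 = (ys - y) ** 2
    mask = dy2[:, None] + dx2[None, :] <= radius**2
    if not mask.any():  # radius below half cell size: use containing cell
        r, c = stack.rowcol(x, y)
        mask = np.zeros(stack.shape, dtype=bool)
        mask[r, c] = True
    out = BufferSummary()
    if "cover_class" in stack.grids:
        cover = stack.grids["cover_class"][mask]
        for code, name in enumerate(COVER_CLASSES):
            out.cover_props[name] = float(np.mean(cover == code))
    for name in stack.grids:
        if name == "cover_class":
            continue
        out.means[name] = float(stack.grids[name][mask].mean())
    return out


def buffered_layers(stack: LandscapeStack, radius: float) -> dict[str, np.ndarray]:
    """Buffer summaries precomputed at every cell center, as rasters.

    Equivalent to :func:`extract_buffer` evaluated at each cell center (same
    cell-center-in-circle membership rule), via convolution with the disc
    footprint. Used by simulation and step-covariate assembly, where per-point
    extraction would be quadratic.
    """
    cs = stack.cell_size
    r_cells = int(np.floor(radius / cs))
    off = np.arange(-r_cells, r_cells + 1)
    disc = (off[:, None] ** 2 + off[None, :] ** 2) * cs**2 <= radius**2
    if not disc.any():
        disc = np.ones((1, 1), dtype=bool)
    k = disc.astype(float)
    k /= k.sum()
    out: dict[str, np.ndarray] = {}
    for name, g in stack.grids.items():
        if name == "cover_class":
            for code, cname in enumerate(COVER_CLASSES):
                out[f"prop_{cname}"] = convolve(
                    (g == code).astype(float), k, mode="nearest")
        else:
            out[name] = convolve(np.asarray(g, dtype=float), k, mode="nearest")
    return out


def distance_to_lines(points: np.ndarray, lines) -> np.ndarray:
    """Planar Euclidean distance from each (x, y) point to a line network.

    ``lines`` is any shapely geometry (LineString / MultiLineString /
    collection).
    """
    from shapely.geometry import Point
    from shapely.ops import unary_union

    geom = unary_union(lines) if isinstance(lines, (list, tuple)) else lines
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([geom.distance(Point(p)) for p in pts])


# ---------------------------------------------------------------------------
# plain-text raster IO

def save_stack(stack: LandscapeStack, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    header = {"origin": list(stack.origin), "cell_size": stack.cell_size,
              "crs": stack.crs, "layers": sorted(stack.grids)}
    (d / "stack.json").write_text(json.dumps(header, indent=1))
    for name, g in stack.grids.items():
        fmt = "%d" if name == "cover_class" else "%.6g"
        np.savetxt(d / f"{name}.txt", g, fmt=fmt)


def load_stack(directory) -> LandscapeStack:
    d = Path(directory)
    header = json.loads((d / "stack.json").read_text())
    grids = {}
    for name in header["layers"]:
        arr = np.loadtxt(d / f"{name}.txt")
        if name == "cover_class":
            arr = arr.astype(int)
        grids[name] = arr
    return LandscapeStack(grids=grids, origin=tuple(header["origin"]),
                          cell_size=header["cell_size"], crs=header["crs"])
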