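"""2D neuron sheets with cortical coordinates and per-neuron metadata.

A sheet is a population of one neuron class placed uniformly at random over
a cortical rectangle (``sx`` x ``sy`` micrometres) at a given density
(neurons per mm^2).  A linear retinotopy maps cortical position to visual
position through the magnification factor (micrometres of cortex per degree
of visual field), with the sheet centre anchored at the visual-field
centre.  Orientation preference is assigned by bilinear sampling of an
orientation map; phase preference is drawn from a configured distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import DistributionSpec, sample_distribution

__all__ = [
    "SheetSpec",
    "Sheet",
    "RecorderSpec",
    "OrientationMap",
    "build_sheet",
    "cortical_to_visual",
    "visual_to_cortical",
    "select_random_n",
    "assign_orientation_map",
    "generate_orientation_map",
    "read_orientation_map",
    "write_orientation_map",
]


@dataclass(frozen=True)
class RecorderSpec:
    """A population selector + the variables it records."""

    selector: str = "RCRandomN"
    num_of_cells: int = 0
    variables: tuple[str, ...] = ("spikes",)

    def __post_init__(self) -> None:
        if self.num_of_cells < 0:
            raise ValueError("num_of_cells must be >= 0")
        allowed = {"spikes", "v", "gsyn_exc", "gsyn_inh"}
        bad = set(self.variables) - allowed
        if bad:
            raise ValueError(f"unknown recorded variable(s): {sorted(bad)}")


@dataclass(frozen=True)
class BackgroundNoiseSpec:
    """Two independent Poisson sources per neuron (exc and inh)."""

    exc_firing_rate: float = 0.0   # spikes/s
    exc_weight: float = 0.0        # uS
    inh_firing_rate: float = 0.0
    inh_weight: float = 0.0


@dataclass(frozen=True)
class SheetSpec:
    name: str
    sx: float                       # um
    sy: float                       # um
    density: float                  # neurons / mm^2
    magnification_factor: float     # um / deg
    cell_model: str = "IF_cond_exp"
    cell_params: Mapping[str, float] = field(default_factory=dict)
    initial_values: Mapping[str, DistributionSpec] = field(default_factory=dict)
    background_noise: BackgroundNoiseSpec = field(default_factory=BackgroundNoiseSpec)
    recorders: Mapping[str, RecorderSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.sx, self.sy, self.magnification_factor) <= 0:
            raise ValueError("sx, sy, magnification_factor must be > 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")


@dataclass
class Sheet:
    """A built sheet: positions (um, centred on 0), metadata, initial state."""

    spec: SheetSpec
    positions: np.ndarray                      # (N, 2) um
    metadata: dict[str, np.ndarray] = field(default_factory=dict)
    initial_state: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def visual_positions(self) -> np.ndarray:
        """(N, 2) visual positions in degrees (linear retinotopy)."""
        return self.positions / self.spec.magnification_factor


def build_sheet(spec: SheetSpec, rng: np.random.Generator) -> Sheet:
    """Place ``round(density * area_mm2)`` neurons uniformly; sample initial
    state variables from their declared distributions."""
    area_mm2 = (spec.sx / 1000.0) * (spec.sy / 1000.0)
    n = int(round(spec.density * area_mm2))
    positions = np.column_stack([
        rng.uniform(-spec.sx / 2.0, spec.sx / 2.0, size=n),
        rng.uniform(-spec.sy / 2.0, spec.sy / 2.0, size=n),
    ]) if n else np.empty((0, 2))
    initial = {
        name: np.asarray(sample_distribution(dist, rng, size=n), dtype=float)
        for name, dist in spec.initial_values.items()
    }
    return Sheet(spec, positions, initial_state=initial)


def cortical_to_visual(pos_um: Sequence[float] | np.ndarray, mf: float) -> np.ndarray:
    """um -> deg, componentwise division by the magnification factor."""
    if mf <= 0:
        raise ValueError("magnification factor must be > 0")
    return np.asarray(pos_um, dtype=float) / mf


def visual_to_cortical(pos_deg: Sequence[float] | np.ndarray, mf: float) -> np.ndarray:
    if mf <= 0:
        raise ValueError("magnification factor must be > 0")
    return np.asarray(pos_deg, dtype=float) * mf


def select_random_n(sheet: Sheet, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct neuron indices, uniform without replacement."""
    if n > sheet.size:
        raise ValueError(f"cannot select {n} cells from a {sheet.size}-neuron sheet")
    return rng.choice(sheet.size, size=n, replace=False)


# ---------------------------------------------------------------------------
# Orientation maps
# ---------------------------------------------------------------------------

@dataclass
class OrientationMap:
    """Preferred orientations in [0, pi) on a regular grid in visual degrees.

    ``grid[i, j]`` is the angle at visual position
    ``(x0 + j*deg_per_cell, y0 + i*deg_per_cell)``.
    """

    grid: np.ndarray
    deg_per_cell: float
    origin: tuple[float, float] = (0.0, 0.0)  # visual deg of grid[0, 0]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0) or np.any(self.grid >= np.pi):
            raise ValueError("orientation map values must lie in [0, pi)")
        if self.deg_per_cell <= 0:
            raise ValueError("deg_per_cell must be > 0")

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) covered by grid nodes, in degrees."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * self.deg_per_cell,
                y0, y0 + (ny - 1) * self.deg_per_cell)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear sample at visual positions; angles via the doubled-angle
        complex representation so interpolation respects the pi period."""
        gx = (np.asarray(x, float) - self.origin[0]) / self.deg_per_cell
        gy = (np.asarray(y, float) - self.origin[1]) / self.deg_per_cell
        ny, nx = self.grid.shape
        if np.any(gx < -1e-9) or np.any(gx > nx - 1 + 1e-9) \
                or np.any(gy < -1e-9) or np.any(gy > ny - 1 + 1e-9):
            raise ValueError("sample position outside orientation-map extent")
        gx = np.clip(gx, 0, nx - 1)
        gy = np.clip(gy, 0, ny - 1)
        j0 = np.minimum(gx.astype(int), nx - 2) if nx > 1 else np.zeros_like(gx, int)
        i0 = np.minimum(gy.astype(int), ny - 2) if ny > 1 else np.zeros_like(gy, int)
        fx = gx - j0
        fy = gy - i0
        z = np.exp(2j * self.grid)
        j1 = np.minimum(j0 + 1, nx - 1)
        i1 = np.minimum(i0 + 1, ny - 1)
        zi = ((1 - fx) * (1 - fy) * z[i0, j0] + fx * (1 - fy) * z[i0, j1]
              + (1 - fx) * fy * z[i1, j0] + fx * fy * z[i1, j1])
        ang = np.angle(zi) / 2.0
        return np.mod(ang, np.pi)


def assign_orientation_map(sheet: Sheet, ormap: OrientationMap,
                           phase_dist: DistributionSpec | None = None,
                           rng: np.random.Generator | None = None) -> Sheet:
    """Attach per-neuron ``orientation`` (map sample at the neuron's visual
    position) and ``phase`` (drawn from ``phase_dist``) metadata."""
    vp = sheet.visual_positions()
    sheet.metadata["orientation"] = ormap.sample(vp[:, 0], vp[:, 1])
    if phase_dist is not None:
        if rng is None:
            raise ValueError("rng required to sample phases")
        sheet.metadata["phase"] = np.asarray(
            sample_distribution(phase_dist, rng, size=sheet.size), dtype=float
        )
    return sheet


def generate_orientation_map(n: int, spatial_period: float, k_components: int,
                             rng: np.random.Generator,
                             deg_per_cell: float = 0.05,
                             centred: bool = True,
                             band: float = 0.5) -> OrientationMap:
    """Synthesize a smooth pseudo orientation map on an ``n`` x ``n`` grid.

    Superposition of ``k_components`` plane waves whose wave vectors are
    drawn uniformly from the annulus around magnitude
    ``2*pi/spatial_period`` (relative width ``band``) with uniformly random
    directions and phases; the preferred orientation is half the argument
    of the complex sum, shifted into [0, pi).  The construction is
    isotropic, so orientations are uniformly distributed; the magnitude
    spread makes spatial correlations decay over a few periods.
    """
    if k_components < 2:
        raise ValueError("need at least 2 wave components")
    if spatial_period <= 0:
        raise ValueError("spatial_period must be > 0")
    coords = np.arange(n) * deg_per_cell
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    k0 = 2.0 * np.pi / spatial_period
    kmags = rng.uniform(k0 * (1 - band / 2), k0 * (1 + band / 2), size=k_components)
    angles = rng.uniform(0, 2 * np.pi, size=k_components)
    phases = rng.uniform(0, 2 * np.pi, size=k_components)
    z = np.zeros((n, n), dtype=complex)
    for km, a, ph in zip(kmags, angles, phases):
        z += np.exp(1j * (km * (np.cos(a) * x + np.sin(a) * y) + ph))
    ormap = np.mod(0.5 * np.angle(z) + np.pi / 2.0, np.pi)
    extent = (n - 1) * deg_per_cell
    origin = (-extent / 2.0, -extent / 2.0) if centred else (0.0, 0.0)
    return OrientationMap(ormap, deg_per_cell, origin)


def write_orientation_map(ormap: OrientationMap, path: str | Path) -> None:
    """Plain-text format: header ``ncols nrows deg_per_cell x0 y0`` then the
    row-major angle grid."""
    ny, nx = ormap.grid.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{nx} {ny} {ormap.deg_per_cell!r} "
                 f"{ormap.origin[0]!r} {ormap.origin[1]!r}\n")
        for row in ormap.grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_orientation_map(path: str | Path) -> OrientationMap:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 5:
            raise ValueError(f"{path}: malformed orientation-map header")
        nx, ny = int(header[0]), int(header[1])
        deg_per_cell = float(header[2])
        origin = (float(header[3]), float(header[4]))
        grid = np.loadtxt(fh, ndmin=2)
    if grid.shape != (ny, nx):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header")
    return OrientationMap(grid, deg_per_cell, origin)
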