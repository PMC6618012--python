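"""Simplified 2D mesophyll unit cell geometry and structured meshing.

The model domain is a half unit cell of a palisade mesophyll cell seen in
cross-section: a stack of layers from the intercellular airspace inward
(cell wall, outer cytosol, chloroplast stroma, inner cytosol) bounded by
the tonoplast, with a cytosol gap between neighbouring chloroplasts.  The
lateral coordinate x runs from the chloroplast mid-plane (x = 0) to the
mid-gap plane (x = W/2); both are symmetry (no-flux) planes.  The depth
coordinate y runs from the outer cell-wall surface (y = 0, facing the
airspace) inward to the tonoplast.  All lengths are SI metres.

(Photo)respired CO2 is released in one of three cytosolic regions
(`Scenario`): the inner cytosol between chloroplast and tonoplast, the
cytosol gaps between neighbouring chloroplasts, or the outer cytosol
between plasma membrane and chloroplast envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "LeafAnatomy",
    "Scenario",
    "CellGeometry",
    "Mesh",
    "AreaScaling",
    "build_unit_cell",
    "generate_mesh",
    "area_scaling",
]

# layer labels used throughout the solver
WALL = "wall"
CYT_OUTER = "cyt_outer"
STROMA = "stroma"
CYT_GAP = "cyt_gap"
CYT_INNER = "cyt_inner"

LAYERS = (WALL, CYT_OUTER, STROMA, CYT_GAP, CYT_INNER)

#: layers that belong to the cytosol (share the cytosol diffusivity)
CYTOSOL_LAYERS = frozenset({CYT_OUTER, CYT_GAP, CYT_INNER})


class Scenario(str, Enum):
    """Location of (photo)respiratory CO2 release within the cytosol."""

    INNER = "inner"
    GAPS = "gaps"
    OUTER = "outer"


@dataclass(frozen=True)
class LeafAnatomy:
    """Measured mesophyll microstructure parameters.

    Parameters
    ----------
    twall : float
        Cell-wall thickness (m).
    tcyt : float
        Outer cytosol layer thickness (m).
    tstr : float
        Chloroplast stroma thickness (m).
    sc_sm : float
        Ratio of exposed chloroplast to exposed mesophyll surface area
        (0 < sc_sm <= 1); sets the lateral fraction of the unit cell
        covered by chloroplast.
    sm_s : float
        Ratio of exposed mesophyll surface to leaf surface area (>= 1).
    tcyt_inner : float, optional
        Inner cytosol thickness (m); defaults to ``tcyt``.
    lchl : float, optional
        Lateral chloroplast half-width (m); only enters through the gap
        width ``lchl * (1/sc_sm - 1)``.
    """

    twall: float = 120e-9
    tcyt: float = 250e-9
    tstr: float = 2.5e-6
    sc_sm: float = 0.90
    sm_s: float = 16.0
    tcyt_inner: float | None = None
    lchl: float = 5e-6

    def __post_init__(self) -> None:
        if self.tcyt_inner is None:
            object.__setattr__(self, "tcyt_inner", self.tcyt)
        for name in ("twall", "tcyt", "tstr", "tcyt_inner", "lchl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"anatomy length {name!r} must be > 0")
        if not 0 < self.sc_sm <= 1:
            raise ValueError("sc_sm must lie in (0, 1]")
        if self.sm_s < 1:
            raise ValueError("sm_s must be >= 1")


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle [x0, x1] x [y0, y1]."""

    x0: float
    x1: float
    y0: float
    y1: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass(frozen=True)
class CellGeometry:
    """Unit-cell layout: layer boxes, membrane interfaces, source region.

    ``layers`` maps layer labels to boxes; boxes tile the domain
    [0, half_width] x [0, depth].  Membrane interfaces (plasma membrane,
    chloroplast envelope) are recorded as the y (or x) coordinate of the
    shared box edge plus its extent; the solver attaches permeabilities.
    """

    anatomy: LeafAnatomy
    scenario: Scenario
    half_width: float
    depth: float
    chl_half_width: float
    layers: dict[str, Box] = field(repr=False)
    # y-positions of horizontal membrane interfaces
    y_plasma_membrane: float = 0.0
    y_env_outer: float = 0.0
    y_env_inner: float = 0.0

    @property
    def y_breaks(self) -> list[float]:
        """Sorted distinct y coordinates of all layer boundaries."""
        ys = {0.0, self.depth}
        for b in self.layers.values():
            ys.update((b.y0, b.y1))
        return sorted(ys)

    @property
    def x_breaks(self) -> list[float]:
        xs = {0.0, self.half_width}
        for b in self.layers.values():
            xs.update((b.x0, b.x1))
        return sorted(xs)

    @property
    def source_layer(self) -> str:
        return {
            Scenario.INNER: CYT_INNER,
            Scenario.GAPS: CYT_GAP,
            Scenario.OUTER: CYT_OUTER,
        }[self.scenario]

    def layer_at(self, x: float, y: float) -> str:
        """Layer label at an interior point (boundaries resolve inward)."""
        if not (0 <= x <= self.half_width and 0 <= y <= self.depth):
            raise ValueError(f"point ({x}, {y}) outside the unit cell")
        if y < self.y_plasma_membrane:
            return WALL
        if y < self.y_env_outer:
            return CYT_OUTER
        if y < self.y_env_inner:
            return STROMA if x < self.chl_half_width else CYT_GAP
        return CYT_INNER


def build_unit_cell(anatomy: LeafAnatomy, scenario: Scenario | str) -> CellGeometry:
    """Construct the half unit cell for a release scenario.

    The depth ordering from the airspace inward is wall, plasma membrane,
    outer cytosol, chloroplast envelope, stroma, envelope, inner cytosol,
    tonoplast (no-flux).  The chloroplast spans x in [0, sc_sm * W/2];
    the cytosol gap fills the remaining lateral span over the stroma
    depth range.

    Raises
    ------
    ValueError
        If ``scenario`` is ``gaps`` while ``sc_sm == 1`` (the gap region
        is empty and cannot act as a CO2 source).
    """
    scenario = Scenario(scenario)
    a = anatomy
    chl_half = a.lchl
    half_width = a.lchl / a.sc_sm
    gap_w = half_width - chl_half
    if scenario is Scenario.GAPS and gap_w <= 0:
        raise ValueError("scenario 'gaps' needs sc_sm < 1: gap region is empty")

    y0 = 0.0
    y1 = a.twall
    y2 = y1 + a.tcyt
    y3 = y2 + a.tstr
    y4 = y3 + a.tcyt_inner

    layers = {
        WALL: Box(0.0, half_width, y0, y1),
        CYT_OUTER: Box(0.0, half_width, y1, y2),
        STROMA: Box(0.0, chl_half, y2, y3),
        CYT_GAP: Box(chl_half, half_width, y2, y3),
        CYT_INNER: Box(0.0, half_width, y3, y4),
    }
    return CellGeometry(
        anatomy=a,
        scenario=scenario,
        half_width=half_width,
        depth=y4,
        chl_half_width=chl_half,
        layers=layers,
        y_plasma_membrane=y1,
        y_env_outer=y2,
        y_env_inner=y3,
    )


@dataclass(frozen=True)
class Mesh:
    """Structured, boundary-fitted rectangular mesh over the unit cell.

    Cell (i, j) spans ``x_edges[i]:x_edges[i+1]`` by
    ``y_edges[j]:y_edges[j+1]``; ``layer[i, j]`` holds the layer label
    index into :data:`LAYERS`.  The unit cell has unit extent in the
    third (out-of-plane) direction, so cell "volumes" are areas (m^2)
    per metre of depth.
    """

    geometry: CellGeometry
    x_edges: np.ndarray
    y_edges: np.ndarray
    layer: np.ndarray  # (nx, ny) int codes into LAYERS

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def volumes(self) -> np.ndarray:
        """Cell areas (m^2), shape (nx, ny)."""
        return np.outer(self.dx, self.dy)

    def layer_mask(self, name: str) -> np.ndarray:
        return self.layer == LAYERS.index(name)

    @property
    def source_mask(self) -> np.ndarray:
        return self.layer_mask(self.geometry.source_layer)

    def rows_in_layer(self, name: str) -> int:
        """Number of mesh rows (columns for the gap) across a layer's
        thin dimension."""
        mask = self.layer_mask(name)
        if name == CYT_GAP:
            return int(mask.any(axis=1).sum())  # columns in x
        return int(mask.any(axis=0).sum())  # rows in y


def _subdivide(breaks: list[float], n: int, axis_name: str) -> np.ndarray:
    """Distribute ``n`` cells over the segments between ``breaks``.

    Each segment receives cells in proportion to its length; a segment
    whose proportional share falls below one cell cannot be resolved and
    raises, naming the offending segment extent.
    """
    breaks_arr = np.asarray(breaks, dtype=float)
    seg = np.diff(breaks_arr)
    seg = seg[seg > 0]
    starts = breaks_arr[:-1][np.diff(breaks_arr) > 0]
    total = seg.sum()
    counts = np.floor(n * seg / total + 1e-9).astype(int)
    if (counts == 0).any():
        i = int(np.argmin(counts))
        raise ValueError(
            f"{axis_name} resolution {n} too coarse: layer segment at "
            f"{starts[i]:.3g} m of thickness {seg[i]:.3g} m is thinner than "
            f"one uniform cell ({total / n:.3g} m); increase {axis_name}"
        )
    # hand out the remainder to the largest segments
    rem = n - counts.sum()
    order = np.argsort(-seg)
    for k in range(max(rem, 0)):
        counts[order[k % len(seg)]] += 1
    k = 0
    while rem < 0:  # rounding overshoot: trim the largest segments
        if counts[order[k % len(seg)]] > 1:
            counts[order[k % len(seg)]] -= 1
            rem += 1
        k += 1
    edges = [breaks_arr[0]]
    pos = breaks_arr[0]
    j = 0
    for b0, b1 in zip(breaks_arr[:-1], breaks_arr[1:]):
        if b1 - b0 <= 0:
            continue
        c = counts[j]
        j += 1
        edges.extend(np.linspace(b0, b1, c + 1)[1:])
        pos = b1
    return np.asarray(edges)


def generate_mesh(geometry: CellGeometry, resolution: tuple[int, int] = (12, 40)) -> Mesh:
    """Mesh the unit cell with ``resolution = (nx, ny)`` cells.

    Mesh lines always include every layer boundary and membrane
    interface, so each cell lies wholly inside one layer and interfaces
    coincide with cell faces.

    Raises
    ------
    ValueError
        If ``nx`` or ``ny`` is below 4, or too coarse to give every
        layer at least one cell across its thickness.
    """
    nx, ny = resolution
    if nx < 4 or ny < 4:
        raise ValueError("resolution must be at least (4, 4)")
    x_edges = _subdivide(geometry.x_breaks, nx, "nx")
    y_edges = _subdivide(geometry.y_breaks, ny, "ny")

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    layer = np.empty((len(xc), len(yc)), dtype=int)
    g = geometry
    for j, y in enumerate(yc):
        if y < g.y_plasma_membrane:
            layer[:, j] = LAYERS.index(WALL)
        elif y < g.y_env_outer:
            layer[:, j] = LAYERS.index(CYT_OUTER)
        elif y < g.y_env_inner:
            inside = xc < g.chl_half_width
            layer[inside, j] = LAYERS.index(STROMA)
            layer[~inside, j] = LAYERS.index(CYT_GAP)
        else:
            layer[:, j] = LAYERS.index(CYT_INNER)
    return Mesh(geometry=g, x_edges=x_edges, y_edges=y_edges, layer=layer)


@dataclass(frozen=True)
class AreaScaling:
    """Conversion factors between per-leaf-area, per-mesophyll-area and
    volumetric stroma rates.

    Rates measured per unit leaf area (the gas-exchange convention)
    divide by Sm/S to become per unit exposed mesophyll area, and
    further by the stroma volume per mesophyll area (tstr * Sc/Sm) to
    become volumetric stroma rates.
    """

    sm_s: float
    stroma_volume_per_mesophyll_area: float  # m

    def leaf_to_mesophyll(self, rate: float) -> float:
        return rate / self.sm_s

    def mesophyll_to_leaf(self, rate: float) -> float:
        return rate * self.sm_s

    def leaf_to_stroma_volumetric(self, rate: float) -> float:
        """umol m^-2(leaf) s^-1 -> umol m^-3(stroma) s^-1."""
        return rate / self.sm_s / self.stroma_volume_per_mesophyll_area

    def stroma_volumetric_to_leaf(self, rate: float) -> float:
        return rate * self.sm_s * self.stroma_volume_per_mesophyll_area


def area_scaling(anatomy: LeafAnatomy) -> AreaScaling:
    """Area/volume scaling factors implied by the anatomy."""
    return AreaScaling(
        sm_s=anatomy.sm_s,
        stroma_volume_per_mesophyll_area=anatomy.tstr * anatomy.sc_sm,
    )
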