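"""Adhesive micropattern fields χ(r).

The micropattern is a static scalar field that is 0 on the adhesive
(fibronectin-coated) region and 1 outside it, with a smooth logistic
transition of width w_χ across the boundary.  Patterns are described by
shapely polygons; the standard geometries are

* ``two_state`` — two square basins (38×38 μm) joined by a narrow bridge
  (10 μm tall × 35 μm long), total bounding box 111×38 μm;
* ``rectangle`` — a single 111×38 μm rectangle;
* ``free2d``    — a fully adhesive plane (χ ≡ 0);
* ``composite`` — an arbitrary union of simple polygons from config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .fields import Grid, ScalarField2D
from .params import ParameterError

#: default basin edge, bridge height (y) and bridge length (x), μm
BASIN_SIZE = 38.0
BRIDGE_HEIGHT = 10.0
BRIDGE_LENGTH = 35.0


@dataclass
class PatternSpec:
    """Geometry specification of an adhesive micropattern."""

    kind: str = "two_state"   # two_state | rectangle | free2d | composite
    basin_size: float = BASIN_SIZE        # μm, square basin edge
    bridge_height: float = BRIDGE_HEIGHT  # μm (the narrow dimension)
    bridge_length: float = BRIDGE_LENGTH  # μm (along x)
    rect_width: float = 2 * BASIN_SIZE + BRIDGE_LENGTH   # 111 μm
    rect_height: float = BASIN_SIZE                      # 38 μm
    polygons: list = field(default_factory=list)  # [[(x,y), ...], ...] for composite
    smoothing: float = 1.2    # w_χ, μm (λ/4 for the default interface width)

    def __post_init__(self) -> None:
        kinds = {"two_state", "rectangle", "free2d", "composite"}
        if self.kind not in kinds:
            raise ParameterError(f"unknown pattern kind {self.kind!r}")
        if self.smoothing <= 0:
            raise ParameterError("smoothing width must be positive")
        if self.kind == "composite":
            if not self.polygons:
                raise ParameterError("composite pattern needs polygons")
            for verts in self.polygons:
                if not Polygon(verts).is_valid:
                    raise ParameterError(
                        "composite polygons must be simple (non-self-"
                        "intersecting)")

    def geometry(self) -> Polygon | None:
        """Shapely geometry of the adhesive region (None for free2d)."""
        if self.kind == "free2d":
            return None
        if self.kind == "two_state":
            b, hb, lb = self.basin_size, self.bridge_height, self.bridge_length
            half = lb / 2.0 + b
            left = box(-half, -b / 2.0, -lb / 2.0, b / 2.0)
            right = box(lb / 2.0, -b / 2.0, half, b / 2.0)
            bridge = box(-lb / 2.0, -hb / 2.0, lb / 2.0, hb / 2.0)
            return unary_union([left, bridge, right])
        if self.kind == "rectangle":
            return box(-self.rect_width / 2.0, -self.rect_height / 2.0,
                       self.rect_width / 2.0, self.rect_height / 2.0)
        return unary_union([Polygon(v) for v in self.polygons])

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the adhesive region, μm."""
        geom = self.geometry()
        if geom is None:
            return (-np.inf, -np.inf, np.inf, np.inf)
        return geom.bounds

    def basin_areas(self) -> tuple[float, float]:
        """Areas (μm²) of the left (x<0) and right (x>0) basins.

        Used as the weights of the area-normalized occupancy statistic.
        The bridge, defined as the region between the basin inner edges,
        is assigned to neither basin.
        """
        geom = self.geometry()
        if geom is None:
            raise ParameterError("free2d pattern has no basins")
        xmin, ymin, xmax, ymax = geom.bounds
        if self.kind == "two_state":
            cut = self.bridge_length / 2.0
        elif self.kind == "composite":
            cut = self.bridge_length / 2.0
        else:
            cut = 0.0
        pad = 1.0
        left = geom.intersection(box(xmin - pad, ymin - pad, -cut, ymax + pad))
        right = geom.intersection(box(cut, ymin - pad, xmax + pad, ymax + pad))
        return float(left.area), float(right.area)


def default_grid(spec: PatternSpec, dx: float, pad: float = 10.0) -> Grid:
    """Symmetric grid covering the pattern with ≥pad μm of margin."""
    if spec.kind == "free2d":
        # unconfined: a generous square working domain
        return Grid.centered(120.0, 120.0, dx)
    xmin, ymin, xmax, ymax = spec.bounding_box()
    ex = 2.0 * max(abs(xmin), abs(xmax)) + 2.0 * pad
    ey = 2.0 * max(abs(ymin), abs(ymax)) + 2.0 * pad
    return Grid.centered(ex, ey, dx)


def build_pattern(spec: PatternSpec, grid: Grid) -> ScalarField2D:
    """Construct χ on the grid: 0 inside, 1 outside, logistic in the signed
    distance to the pattern boundary, χ = 1/(1 + e^{−d/w_χ})."""
    geom = spec.geometry()
    if geom is None:
        return ScalarField2D(np.zeros(grid.shape), grid)
    xmin, ymin, xmax, ymax = geom.bounds
    gx0, gy0 = grid.origin
    gx1 = gx0 + (grid.nx - 1) * grid.dx
    gy1 = gy0 + (grid.ny - 1) * grid.dx
    if xmin < gx0 or ymin < gy0 or xmax > gx1 or ymax > gy1:
        raise ParameterError("pattern does not fit inside the grid")
    X, Y = grid.meshgrid()
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    dist = shapely.distance(geom.boundary, pts)
    inside = shapely.contains(geom, pts)
    signed = np.where(inside, -dist, dist).reshape(grid.shape)
    chi = 1.0 / (1.0 + np.exp(np.clip(-signed / spec.smoothing, -60, 60)))
    return ScalarField2D(chi, grid)
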