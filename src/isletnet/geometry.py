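"""Planar geometry shared by the whole pipeline.

Every islet is described by a rim polygon (the hand- or simulator-drawn
boundary around the endocrine cell mass) and a set of typed cell positions
in micrometres.  All downstream stages — staging, proximity networks, the
randomization null model, the outer-ring and half-islet analyses — reduce
to a handful of geometric primitives defined here:

* signed Euclidean distance of a point to the rim (negative inside,
  positive outside, zero on the boundary),
* Minkowski dilation of the enclosed region by a disc ("enlarge by m"),
* membership of the outer ring of endocrine cells,
* splitting an islet into two halves through the rim centroid,
* polygon area.

Coordinates are continuous μm in a y-down image frame (pixel row index
times the pixel size); nothing here enforces that, it is a documented
convention.  Distances between cells are nucleus-centre to nucleus-centre;
cells carry no radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "CELL_TYPES",
    "ENDOCRINE_TYPES",
    "IMMUNE_TYPES",
    "InvalidGeometryError",
    "RimPolygon",
    "CellRecord",
    "IsletMap",
    "signed_distance_to_rim",
    "dilate_rim",
    "outer_ring",
    "split_halves",
    "islet_area",
]

#: Closed vocabulary of cell types.
CELL_TYPES = ("alpha", "beta", "T", "macrophage", "myeloid")
ENDOCRINE_TYPES = frozenset({"alpha", "beta"})
IMMUNE_TYPES = frozenset({"T", "macrophage", "myeloid"})

#: Number of segments per quarter circle used when buffering polygons.
#: At the margins used in this pipeline (≤ 60 μm) the round-join chord
#: error is 60·(1 − cos(π/64)) ≈ 0.07 μm, well under half an image pixel.
BUFFER_QUAD_SEGS = 16


class InvalidGeometryError(ValueError):
    """Raised for degenerate or self-intersecting rim polygons."""


@dataclass(frozen=True)
class RimPolygon:
    """Closed, simple boundary polygon of an islet, vertices in μm.

    The first and last vertex are treated as joined; the vertex list must
    describe a simple (non-self-intersecting) polygon with positive area.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidGeometryError("rim needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(verts)):
            raise InvalidGeometryError("rim vertices must be finite")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts)
        if not poly.is_valid:
            raise InvalidGeometryError("rim polygon is self-intersecting")
        if poly.area <= 0.0:
            raise InvalidGeometryError("rim polygon has zero area")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        """The shapely polygon backing this rim."""
        return self._polygon  # type: ignore[attr-defined]

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @classmethod
    def from_polygon(cls, poly: Polygon) -> "RimPolygon":
        return cls(np.asarray(poly.exterior.coords[:-1], dtype=float))


@dataclass(frozen=True)
class CellRecord:
    """One cell: opaque id, type from the closed vocabulary, position in μm."""

    cell_id: str
    cell_type: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("cell coordinates must be finite")


@dataclass
class IsletMap:
    """One islet: rim polygon, typed cell positions, tissue-edge flag.

    ``tissue_edge_flag`` marks islets at the edge of the tissue section,
    which are excluded from polarity analyses because part of their
    surroundings is missing.
    """

    islet_id: str
    mouse_id: str
    rim: RimPolygon
    cells: list[CellRecord]
    tissue_edge_flag: bool = False
    _pos_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate cell_ids in islet {self.islet_id!r}")

    def cells_of_type(self, *types: str) -> list[CellRecord]:
        wanted = set(types)
        return [c for c in self.cells if c.cell_type in wanted]

    def positions(self, *types: str) -> np.ndarray:
        """(n, 2) array of positions of the given types, in cell order."""
        key = tuple(sorted(types))
        if key not in self._pos_cache:
            sel = self.cells_of_type(*types)
            arr = np.array([(c.x, c.y) for c in sel], dtype=float).reshape(-1, 2)
            self._pos_cache[key] = arr
        return self._pos_cache[key]

    def ids_of_type(self, *types: str) -> list[str]:
        return [c.cell_id for c in self.cells_of_type(*types)]

    def signed_distances(self, *types: str) -> np.ndarray:
        """Signed rim distances for all cells of the given types."""
        return signed_distance_to_rim(self.positions(*types), self.rim)


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def signed_distance_to_rim(point, rim: RimPolygon) -> float | np.ndarray:
    """Signed Euclidean distance from point(s) to the rim boundary.

    Negative inside the polygon, positive outside, exactly 0 on the
    boundary.  The sign convention makes "enlarged by m" read as
    ``signed_distance <= m``.  Accepts a single ``(x, y)`` pair or an
    ``(n, 2)`` array; returns a scalar or an ``(n,)`` array accordingly.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = pts.reshape(-1, 2)
    poly = rim.polygon
    geoms = shapely.points(pts)
    dist = shapely.distance(geoms, poly.exterior)
    inside = shapely.covers(poly, geoms)
    signed = np.where(inside, -dist, dist)
    return float(signed[0]) if scalar else signed


def dilate_rim(rim: RimPolygon, margin: float) -> RimPolygon:
    """Minkowski dilation of the enclosed region by a disc of radius margin.

    A point p lies inside the dilated rim iff
    ``signed_distance_to_rim(p, rim) <= margin``.  Round joins are used so
    the offset region is the true disc dilation up to a sub-pixel chord
    error.
    """
    if margin < 0:
        raise ValueError("dilation margin must be >= 0")
    if margin == 0:
        return rim
    buffered = rim.polygon.buffer(margin, quad_segs=BUFFER_QUAD_SEGS)
    return RimPolygon.from_polygon(buffered)


def islet_area(rim: RimPolygon) -> float:
    """Enclosed (shoelace) area of the rim polygon in μm², always positive."""
    return float(rim.polygon.area)


def outer_ring(islet: IsletMap, band: float = 20.0) -> set[str]:
    """Endocrine cells within ``band`` μm of the rim, on either side.

    Returns the cell_ids of α- and β-cells with ``|signed_distance| <=
    band``.  Immune cells are never filtered here; their membership rule
    (inside the rim or within the immune margin) lives in the network
    builder.  The default 20 μm band equalizes the opportunity of
    peripheral endocrine cells to meet peri-islet immune cells.
    """
    if band <= 0:
        raise ValueError("band must be > 0")
    ids = islet.ids_of_type(*ENDOCRINE_TYPES)
    if not ids:
        return set()
    d = islet.signed_distances(*ENDOCRINE_TYPES)
    return {cid for cid, di in zip(ids, d) if abs(di) <= band}


def split_halves(
    islet: IsletMap, axis: str = "vertical", band: float = 20.0
) -> tuple[set[str], set[str]]:
    """Partition the islet's cells into two halves through the rim centroid.

    ``axis="vertical"`` splits along a vertical plane (cells compared by
    x); ``"horizontal"`` splits along a horizontal plane (compared by y).
    Considered cells are all endocrine cells plus immune cells within
    ``band`` μm of the rim.  Cells exactly on the plane go to the first
    (left / lower) half — a deterministic tie-break.  Returns
    ``(left_or_lower_ids, right_or_upper_ids)``; every considered cell is
    in exactly one half.
    """
    if axis not in ("vertical", "horizontal"):
        raise ValueError("axis must be 'vertical' or 'horizontal'")
    if not islet.cells:
        raise ValueError("islet has no cells")
    cx, cy = islet.rim.centroid
    pivot = cx if axis == "vertical" else cy

    considered: list[CellRecord] = list(islet.cells_of_type(*ENDOCRINE_TYPES))
    imm = islet.cells_of_type(*IMMUNE_TYPES)
    if imm:
        d = islet.signed_distances(*IMMUNE_TYPES)
        considered += [c for c, di in zip(imm, d) if di <= band]

    first: set[str] = set()
    second: set[str] = set()
    for c in considered:
        coord = c.x if axis == "vertical" else c.y
        (first if coord <= pivot else second).add(c.cell_id)
    return first, second


class OffsetCurveCache:
    """Level sets of signed rim distance (offset curves), with caching.

    The level set at signed distance d is the boundary of the rim region
    dilated (d > 0) or eroded (d < 0) by |d|; sampling a point uniformly
    by arc length on it realizes "a random position at rim distance d".
    Curves are cached per distance value, which pays off whenever the
    same distances recur (e.g. draws from a fixed pool).
    """

    def __init__(self, rim: RimPolygon):
        self._poly = rim.polygon
        self._cache: dict = {}

    def _curve(self, d: float):
        if d in self._cache:
            return self._cache[d]
        if d == 0.0:
            lines = [self._poly.exterior]
        else:
            region = self._poly.buffer(d, quad_segs=BUFFER_QUAD_SEGS)
            if region.is_empty:
                self._cache[d] = None
                return None
            boundary = region.boundary
            if boundary.geom_type == "LineString":
                lines = [boundary]
            else:
                lines = list(boundary.geoms)
        lengths = np.array([ln.length for ln in lines])
        entry = (lines, np.cumsum(lengths), float(lengths.sum()))
        self._cache[d] = entry
        return entry

    def feasible(self, d: float) -> bool:
        return self._curve(d) is not None

    def sample_point(self, d: float, u: float) -> tuple[float, float]:
        """Point at fraction ``u`` of total arc length along the level set."""
        entry = self._curve(d)
        if entry is None:
            raise ValueError(f"level set at distance {d} is empty")
        lines, cum, total = entry
        s = u * total
        idx = int(np.searchsorted(cum, s, side="right"))
        idx = min(idx, len(lines) - 1)
        offset = s - (cum[idx - 1] if idx else 0.0)
        p = lines[idx].interpolate(offset)
        return (p.x, p.y)
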