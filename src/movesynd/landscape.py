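"""Habitat landscapes, triangulated meshes, and datalogger attributes.

The landscape is a planar mosaic of habitat polygons in projected metres,
classified into three classes: forest (1), matrix (2) and open area (3).
The mesh is a conforming right-triangle triangulation built on the tensor
grid spanned by the polygon vertex coordinates, so habitat boundaries are
honoured exactly for rectilinear (axis-aligned) mosaics -- the only kind
the synthetic generator produces.  Each datalogger carries the eight
attributes used by the movement statistics: habitat-cover fractions and
Shannon diversity in a 200 m buffer, distance to the nearest forest, and
fruit counts of the three food genera.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.ops import unary_union

FOREST, MATRIX, OPEN = 1, 2, 3
HABITAT_NAMES = {FOREST: "forest", MATRIX: "matrix", OPEN: "open"}
HABITAT_CODES = {v: k for k, v in HABITAT_NAMES.items()}

#: attribute columns of a datalogger, in the order of statistics S1-S8
LOGGER_ATTRIBUTES = ["FC", "OA", "MA", "HE", "NN", "PI", "SO", "CE"]


class GeometryError(ValueError):
    """Raised for invalid or unsupported landscape geometry."""


# ---------------------------------------------------------------------------
# habitat polygons


@dataclass
class HabitatPolygonSet:
    """A tiling of a rectangular extent by habitat-classified polygons.

    Parameters
    ----------
    polygons
        List of ``(shapely.Polygon, habitat_class)`` pairs; classes are
        1 = forest, 2 = matrix, 3 = open.  Polygons must tile the extent:
        no overlap of positive area, no gaps.
    extent
        ``(xmin, ymin, xmax, ymax)`` in metres.
    """

    polygons: list[tuple[Polygon, int]]
    extent: tuple[float, float, float, float]
    _class_unions: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise GeometryError("degenerate extent")
        area_sum = 0.0
        for i, (poly, h) in enumerate(self.polygons):
            if h not in HABITAT_NAMES:
                raise GeometryError(f"polygon {i}: unknown habitat class {h}")
            if not poly.is_valid:
                raise GeometryError(f"polygon {i} (habitat {h}) is invalid: {shapely.is_valid_reason(poly)}")
            area_sum += poly.area
        extent_area = (xmax - xmin) * (ymax - ymin)
        if abs(area_sum - extent_area) > 1e-6 * extent_area:
            raise GeometryError(
                f"polygons do not tile the extent: total polygon area {area_sum:.6g} "
                f"vs extent area {extent_area:.6g}"
            )

    @property
    def extent_area(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)

    def class_union(self, h: int):
        """Union of all polygons of habitat class ``h`` (cached)."""
        if h not in self._class_unions:
            geoms = [p for p, hh in self.polygons if hh == h]
            self._class_unions[h] = unary_union(geoms) if geoms else Polygon()
        return self._class_unions[h]

    def class_areas(self) -> dict[int, float]:
        out = {FOREST: 0.0, MATRIX: 0.0, OPEN: 0.0}
        for poly, h in self.polygons:
            out[h] += poly.area
        return out

    def habitat_at(self, x: float, y: float) -> int:
        pt = Point(x, y)
        for h in (FOREST, MATRIX, OPEN):
            u = self.class_union(h)
            if not u.is_empty and u.covers(pt):
                return h
        raise GeometryError(f"point ({x}, {y}) is not covered by any habitat polygon")

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"habitat": HABITAT_NAMES[h]},
                "geometry": mapping(poly),
            }
            for poly, h in self.polygons
        ]
        doc = {
            "type": "FeatureCollection",
            "extent": list(self.extent),
            "features": features,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path) -> "HabitatPolygonSet":
        with open(path) as fh:
            doc = json.load(fh)
        polys = []
        for feat in doc["features"]:
            geom = shape(feat["geometry"])
            h = HABITAT_CODES[feat["properties"]["habitat"]]
            if geom.geom_type == "MultiPolygon":
                polys.extend((g, h) for g in geom.geoms)
            else:
                polys.append((geom, h))
        if "extent" in doc:
            extent = tuple(doc["extent"])
        else:
            xmin, ymin, xmax, ymax = unary_union([p for p, _ in polys]).bounds
            extent = (xmin, ymin, xmax, ymax)
        return cls(polys, extent)


# ---------------------------------------------------------------------------
# mesh


@dataclass
class Mesh:
    """Conforming triangulation with per-triangle habitat classes.

    ``vertices`` is ``(n_v, 2)`` float, ``triangles`` ``(n_t, 3)`` int,
    ``habitat`` ``(n_t,)`` int in {1, 2, 3}, ``areas`` ``(n_t,)`` float (m^2).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    habitat: np.ndarray
    areas: np.ndarray
    extent: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.habitat = np.asarray(self.habitat, dtype=np.int64)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.areas <= 0):
            raise GeometryError("mesh contains a degenerate (zero-area) triangle")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def habitat_area(self, h: int) -> float:
        return float(self.areas[self.habitat == h].sum())

    def vertex_habitat(self) -> np.ndarray:
        """Majority habitat class of the triangles around each vertex.

        Ties are broken toward the smaller class code; only used for
        reporting, never inside the solver (which is triangle-based).
        """
        counts = np.zeros((self.n_vertices, 4))
        for t, h in zip(self.triangles, self.habitat):
            counts[t, h] += 1
        out = counts[:, 1:].argmax(axis=1) + 1
        return out

    def nearest_vertex(self, x: float, y: float) -> int:
        d2 = (self.vertices[:, 0] - x) ** 2 + (self.vertices[:, 1] - y) ** 2
        return int(np.argmin(d2))

    def vertex_rings(self) -> list[set]:
        """One-ring neighbour sets per vertex (computed once, cached)."""
        cached = getattr(self, "_rings", None)
        if cached is not None:
            return cached
        rings: list[set] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            rings[a].update((b, c))
            rings[b].update((a, c))
            rings[c].update((a, b))
        self._rings = rings
        return rings

    # -- OFF-style text export ----------------------------------------------

    def to_off(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_vertices} {self.n_triangles} 0\n")
            for x, y in self.vertices:
                fh.write(f"{x:.6f} {y:.6f} 0.0\n")
            for (a, b, c), h in zip(self.triangles, self.habitat):
                fh.write(f"3 {a} {b} {c} {h}\n")

    @classmethod
    def from_off(cls, path) -> "Mesh":
        with open(path) as fh:
            header = fh.readline().strip()
            if header != "OFF":
                raise GeometryError(f"not an OFF file: header {header!r}")
            nv, nt, _ = (int(s) for s in fh.readline().split())
            verts = np.array([[float(v) for v in fh.readline().split()[:2]] for _ in range(nv)])
            tris = np.empty((nt, 3), dtype=np.int64)
            hab = np.empty(nt, dtype=np.int64)
            for i in range(nt):
                parts = fh.readline().split()
                tris[i] = [int(p) for p in parts[1:4]]
                hab[i] = int(parts[4])
        areas = _triangle_areas(verts, tris)
        return cls(verts, tris, hab, areas)


def _triangle_areas(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p0, p1, p2 = verts[tris[:, 0]], verts[tris[:, 1]], verts[tris[:, 2]]
    return 0.5 * np.abs(
        (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
        - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
    )


def _axis_aligned_breaklines(habitat: HabitatPolygonSet):
    """Collect x/y breaklines; reject non-rectilinear polygon edges."""
    xs, ys = set(), set()
    for i, (poly, h) in enumerate(habitat.polygons):
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            coords = np.asarray(ring.coords)
            dx = np.diff(coords[:, 0])
            dy = np.diff(coords[:, 1])
            if np.any((np.abs(dx) > 1e-9) & (np.abs(dy) > 1e-9)):
                raise GeometryError(
                    f"polygon {i} (habitat {HABITAT_NAMES[h]}) has a non-axis-aligned edge; "
                    "the grid mesher supports rectilinear habitat mosaics only"
                )
            xs.update(np.round(coords[:, 0], 9))
            ys.update(np.round(coords[:, 1], 9))
    xmin, ymin, xmax, ymax = habitat.extent
    xs.update((xmin, xmax))
    ys.update((ymin, ymax))
    return np.array(sorted(xs)), np.array(sorted(ys))


def _refine_breaklines(breaks: np.ndarray, pitch: float) -> np.ndarray:
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((b - a) / pitch - 1e-12)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def build_mesh(habitat: HabitatPolygonSet, max_triangle_area: float) -> Mesh:
    """Triangulate a rectilinear habitat mosaic.

    The tensor grid spanned by all polygon vertex coordinates (refined until
    every cell's half-area is at most ``max_triangle_area``) is split into
    right triangles with a consistent diagonal.  Because habitat boundaries
    lie on grid lines, no triangle straddles a boundary and the triangulation
    is conforming by construction.

    Raises
    ------
    GeometryError
        If a polygon has non-axis-aligned edges, the polygons do not tile
        the extent, or habitat areas are not conserved to 0.1 %.
    """
    if max_triangle_area <= 0:
        raise GeometryError("max_triangle_area must be positive")
    bx, by = _axis_aligned_breaklines(habitat)
    pitch = np.sqrt(2.0 * max_triangle_area)
    xs = _refine_breaklines(bx, pitch)
    ys = _refine_breaklines(by, pitch)
    nx, ny = len(xs) - 1, len(ys) - 1

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    v00, v10 = vid(ii, jj), vid(ii + 1, jj)
    v11, v01 = vid(ii + 1, jj + 1), vid(ii, jj + 1)
    tris = np.empty((2 * len(ii), 3), dtype=np.int64)
    tris[0::2] = np.column_stack([v00, v10, v11])
    tris[1::2] = np.column_stack([v00, v11, v01])

    # classify cells by centroid; exact for boundary-aligned grids
    cx = 0.5 * (xs[ii] + xs[ii + 1])
    cy = 0.5 * (ys[jj] + ys[jj + 1])
    cell_h = np.zeros(len(ii), dtype=np.int64)
    for h in (FOREST, MATRIX, OPEN):
        u = habitat.class_union(h)
        if u.is_empty:
            continue
        inside = shapely.contains_xy(u, cx, cy)
        cell_h[inside & (cell_h == 0)] = h
    if np.any(cell_h == 0):
        k = int(np.flatnonzero(cell_h == 0)[0])
        raise GeometryError(
            f"cell centred at ({cx[k]:.3f}, {cy[k]:.3f}) is not covered by any habitat polygon"
        )
    hab = np.repeat(cell_h, 2)
    areas = _triangle_areas(verts, tris)

    mesh = Mesh(verts, tris, hab, areas, extent=habitat.extent)
    for h, target in habitat.class_areas().items():
        got = mesh.habitat_area(h)
        if target > 0 and abs(got - target) > 1e-3 * habitat.extent_area:
            raise GeometryError(
                f"habitat {HABITAT_NAMES[h]} area not conserved by meshing: "
                f"{got:.6g} vs {target:.6g} (boundary not honoured by the grid)"
            )
    return mesh


# ---------------------------------------------------------------------------
# scalar landscape metrics


def shannon_diversity(proportions) -> float:
    """Shannon diversity -sum(p ln p) in nats, with 0 ln 0 = 0.

    ``proportions`` must be nonnegative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def logger_attributes(
    location,
    habitat: HabitatPolygonSet,
    buffer_radius: float = 200.0,
) -> dict[str, float]:
    """Landscape attributes of a datalogger location.

    Returns FC/OA/MA (habitat-cover fractions of the 200 m buffer clipped to
    the extent), HE (Shannon diversity of the three fractions, nats) and NN
    (distance in metres to the nearest forest edge; 0 inside forest).
    """
    x, y = location
    xmin, ymin, xmax, ymax = habitat.extent
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise GeometryError(f"logger location ({x}, {y}) outside landscape extent")
    buf = Point(x, y).buffer(buffer_radius, quad_segs=64)
    clipped = buf.intersection(box(xmin, ymin, xmax, ymax))
    if clipped.is_empty or clipped.area <= 0:
        raise GeometryError("buffer entirely outside landscape extent")
    fracs = {}
    for h in (FOREST, MATRIX, OPEN):
        u = habitat.class_union(h)
        fracs[h] = 0.0 if u.is_empty else clipped.intersection(u).area / clipped.area
    total = fracs[FOREST] + fracs[MATRIX] + fracs[OPEN]
    fracs = {h: v / total for h, v in fracs.items()}  # absorb clipping slivers
    forest = habitat.class_union(FOREST)
    if not forest.is_empty and forest.covers(Point(x, y)):
        nn = 0.0
    elif forest.is_empty:
        nn = float("inf")
    else:
        nn = Point(x, y).distance(forest)
    he = shannon_diversity([fracs[FOREST], fracs[MATRIX], fracs[OPEN]])
    return {"FC": fracs[FOREST], "OA": fracs[OPEN], "MA": fracs[MATRIX], "HE": he, "NN": nn}


def fruit_abundance(per_branch_counts, branch_counts) -> float:
    """Estimated fruit count: mean fruits per branch times total branches.

    ``per_branch_counts`` are the 10 per-tree fruit counts; ``branch_counts``
    the branch tallies of the 4 perpendicular transects.
    """
    pb = np.asarray(per_branch_counts, dtype=float)
    br = np.asarray(branch_counts, dtype=float)
    if pb.shape != (10,):
        raise ValueError(f"expected 10 per-branch counts, got {pb.shape}")
    if br.shape != (4,):
        raise ValueError(f"expected 4 transect branch counts, got {br.shape}")
    if np.any(pb < 0) or np.any(br < 0):
        raise ValueError("counts must be nonnegative")
    return float(pb.mean() * br.sum())


# ---------------------------------------------------------------------------
# dataloggers


@dataclass
class Datalogger:
    """A fixed receiver with a disc detection region and landscape attributes.

    ``detect_radius_m`` is the field-calibrated radius; the region used by
    the observation model doubles its *area* by default (radius scaled by
    sqrt(2)), emulating small-scale movements around the receiver.
    """

    id: str
    x: float
    y: float
    detect_radius_m: float
    attributes: dict[str, float]
    area_doubling: str = "area"  # "area" (radius*sqrt(2)) or "radius" (2*radius)

    @property
    def effective_radius(self) -> float:
        if self.area_doubling == "area":
            return self.detect_radius_m * np.sqrt(2.0)
        if self.area_doubling == "radius":
            return self.detect_radius_m * 2.0
        raise ValueError(f"unknown area_doubling mode {self.area_doubling!r}")

    def region(self) -> Polygon:
        return Point(self.x, self.y).buffer(self.effective_radius, quad_segs=64)

    def validate(self) -> None:
        a = self.attributes
        s = a["FC"] + a["OA"] + a["MA"]
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"logger {self.id}: FC+OA+MA = {s}, expected 1")
        if a["HE"] < 0 or a["NN"] < 0:
            raise ValueError(f"logger {self.id}: HE and NN must be nonnegative")


def loggers_to_frame(loggers: list[Datalogger]) -> pd.DataFrame:
    rows = []
    for lg in loggers:
        row = {"id": lg.id, "x": lg.x, "y": lg.y, "detect_radius_m": lg.detect_radius_m}
        row.update({k: lg.attributes.get(k, np.nan) for k in LOGGER_ATTRIBUTES})
        rows.append(row)
    return pd.DataFrame(rows)


def write_loggers_csv(loggers: list[Datalogger], path) -> None:
    loggers_to_frame(loggers).to_csv(path, index=False)


def read_loggers_csv(path, area_doubling: str = "area") -> list[Datalogger]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        attrs = {k: float(r[k]) for k in LOGGER_ATTRIBUTES if k in df.columns}
        out.append(
            Datalogger(
                id=str(r["id"]),
                x=float(r["x"]),
                y=float(r["y"]),
                detect_radius_m=float(r["detect_radius_m"]),
                attributes=attrs,
                area_doubling=area_doubling,
            )
        )
    return out


def attach_attributes(
    loggers: list[Datalogger],
    habitat: HabitatPolygonSet,
    buffer_radius: float = 200.0,
) -> None:
    """Compute and store FC/OA/MA/HE/NN for each logger in place."""
    for lg in loggers:
        lg.attributes.update(logger_attributes((lg.x, lg.y), habitat, buffer_radius))
        try:
            lg.validate()
        except ValueError as err:  # pragma: no cover - defensive
            warnings.warn(str(err))
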