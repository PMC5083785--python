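"""Synthetic geometry generators.

Two discretizations are produced here:

* :func:`build_cell_domain` — a Lloyd-relaxed (centroidal) Voronoi
  tessellation of an elongated rectangular cell surface into polygonal
  compartments, the spatial substrate of the reaction–diffusion model.
  Basal is the ``x = 0`` edge, apical the ``x = length`` edge.
* :func:`build_shell_mesh` — a structured quadrilateral (optionally locally
  triangulated) mesh of a square wall patch with a circular central region
  of distinct material/loading, the substrate of the mechanical model.

All coordinates are in model length units; the wall-patch mesh is
conventionally read in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or ill-posed region definitions."""


class TopologyError(RuntimeError):
    """Raised when compartment adjacency is missing or inconsistent."""


# ---------------------------------------------------------------------------
# Cell compartment domain
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    """A polygonal compartment of the cell surface.

    ``neighbors`` holds ``(other_id, shared_edge_length, centroid_distance)``
    triples; shared-edge length over centroid distance is the geometric
    conductance used by the discrete Laplacian.
    """

    id: int
    polygon: np.ndarray          # (k, 2) vertices, CCW
    area: float
    centroid: tuple[float, float]
    neighbors: list[tuple[int, float, float]] = field(default_factory=list)
    is_boundary: bool = False
    is_basal_source: bool = False
    is_apical_sink: bool = False


@dataclass
class CellDomain2D:
    """Polygonal compartmentalization of a rectangular cell surface."""

    length: float
    width: float
    compartments: list[Compartment]
    basal_edge: str = "x=0"
    apical_edge: str = "x=length"

    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.compartments])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.compartments])

    @property
    def boundary_mask(self) -> np.ndarray:
        return np.array([c.is_boundary for c in self.compartments])

    @property
    def source_mask(self) -> np.ndarray:
        return np.array([c.is_basal_source for c in self.compartments])

    @property
    def sink_mask(self) -> np.ndarray:
        return np.array([c.is_apical_sink for c in self.compartments])

    def conductances(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return COO triplets ``(i, j, L_ij / d_ij)`` over directed neighbor pairs."""
        ii, jj, ww = [], [], []
        for c in self.compartments:
            if not c.neighbors:
                raise TopologyError(f"compartment {c.id} has no neighbors")
            for j, L, d in c.neighbors:
                ii.append(c.id)
                jj.append(j)
                ww.append(L / d)
        return np.array(ii), np.array(jj), np.array(ww)


def _clipped_voronoi_polygons(points: np.ndarray, length: float, width: float):
    """Voronoi cells of `points` clipped to the rectangle.

    Mirroring the generators across all four sides makes every cell of an
    interior generator finite and exactly clipped to the rectangle.
    """
    n = len(points)
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, length), (1, 0.0), (1, width)):
        m = points.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise TopologyError("unbounded Voronoi cell despite mirroring")
        polys.append(Polygon(vor.vertices[region]))
    ridge_pairs = [
        tuple(sorted(p))
        for p in vor.ridge_points
        if p[0] < n and p[1] < n
    ]
    return polys, set(ridge_pairs)


def _edge_lengths_on_sides(coords: np.ndarray, length: float, width: float,
                           tol: float = 1e-9) -> dict[str, float]:
    """Total polygon-edge length lying on each rectangle side."""
    out = {"x0": 0.0, "x1": 0.0, "y0": 0.0, "y1": 0.0}
    k = len(coords)
    for a in range(k):
        v1, v2 = coords[a], coords[(a + 1) % k]
        seg = float(np.hypot(*(v2 - v1)))
        if abs(v1[0]) < tol and abs(v2[0]) < tol:
            out["x0"] += seg
        elif abs(v1[0] - length) < tol and abs(v2[0] - length) < tol:
            out["x1"] += seg
        elif abs(v1[1]) < tol and abs(v2[1]) < tol:
            out["y0"] += seg
        elif abs(v1[1] - width) < tol and abs(v2[1] - width) < tol:
            out["y1"] += seg
    return out


def build_cell_domain(
    length: float,
    width: float,
    n_compartments: int,
    source_fraction: float = 0.05,
    sink_fraction: float = 0.05,
    seed: int = 0,
    lloyd_iterations: int = 40,
    symmetric: bool = True,
) -> CellDomain2D:
    """Generate a centroidal-Voronoi polygonal compartmentalization.

    Compartments whose centroid lies within ``source_fraction * length`` of the
    basal edge (x = 0) are flagged as auxin sources; the analogous apical strip
    is flagged as sink. Deterministic for a fixed ``seed``.

    With ``symmetric=True`` (default) the tessellation is exactly mirror
    symmetric about the lateral midline: compartments are generated on the
    lower half-strip and reflected, with shared-edge lengths and distances
    copied bitwise between mirror twins. A laterally unbiased discretization
    matters for the patterning dynamics — on an asymmetric tessellation the
    lateral position of an emerging ROP patch is selected by compartment-size
    noise rather than by the model. ``n_compartments`` must be even in this
    mode.
    """
    if length <= 0 or width <= 0:
        raise InvalidGeometryError("cell dimensions must be positive")
    if n_compartments < 4:
        raise InvalidGeometryError("need at least 4 compartments")
    if not (0 < source_fraction < 0.5 and 0 < sink_fraction < 0.5):
        raise InvalidGeometryError("source/sink fractions must lie in (0, 0.5)")
    if symmetric and n_compartments % 2:
        raise InvalidGeometryError("symmetric tessellation needs an even count")

    n_gen = n_compartments // 2 if symmetric else n_compartments
    gen_width = width / 2 if symmetric else width
    rng = np.random.default_rng(seed)
    pts = rng.uniform((0, 0), (length, gen_width), size=(n_gen, 2))
    for _ in range(lloyd_iterations):
        polys, _ = _clipped_voronoi_polygons(pts, length, gen_width)
        pts = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    polys, pairs = _clipped_voronoi_polygons(pts, length, gen_width)

    def make_comp(idx, poly_coords, area, cx, cy, on_outer):
        return Compartment(
            id=idx, polygon=poly_coords, area=area, centroid=(cx, cy),
            is_boundary=on_outer,
            is_basal_source=cx <= source_fraction * length,
            is_apical_sink=cx >= (1.0 - sink_fraction) * length,
        )

    midline = width / 2.0
    comps: list[Compartment] = []
    half_info = []
    for i, p in enumerate(polys):
        p = p.simplify(0)
        coords = np.asarray(p.exterior.coords)[:-1]
        if Polygon(coords).exterior.is_ccw is False:
            coords = coords[::-1]
        cx, cy = p.centroid.x, p.centroid.y
        sides = _edge_lengths_on_sides(coords, length, gen_width)
        if not symmetric:
            comps.append(make_comp(i, coords, p.area, cx, cy,
                                   sum(sides.values()) > 1e-9))
            continue
        # lower twin keeps its geometry; outer boundary excludes the midline
        mid_edge = sides["y1"]
        on_outer = (sides["x0"] + sides["x1"] + sides["y0"]) > 1e-9
        comps.append(make_comp(2 * i, coords, p.area, cx, cy, on_outer))
        mirrored = coords.copy()[::-1]
        mirrored[:, 1] = width - mirrored[:, 1]
        comps.append(make_comp(2 * i + 1, mirrored, p.area, cx, width - cy,
                               on_outer))
        half_info.append((i, mid_edge, cy))

    if symmetric:
        for i, j in sorted(pairs):
            L = polys[i].intersection(polys[j]).length
            if L <= 1e-9:
                continue
            d = float(np.hypot(comps[2 * i].centroid[0] - comps[2 * j].centroid[0],
                               comps[2 * i].centroid[1] - comps[2 * j].centroid[1]))
            for a, b in ((2 * i, 2 * j), (2 * i + 1, 2 * j + 1)):
                comps[a].neighbors.append((b, L, d))
                comps[b].neighbors.append((a, L, d))
        for i, mid_edge, cy in half_info:
            if mid_edge > 1e-9:
                d = 2.0 * (midline - cy)
                comps[2 * i].neighbors.append((2 * i + 1, mid_edge, d))
                comps[2 * i + 1].neighbors.append((2 * i, mid_edge, d))
    else:
        for i, j in sorted(pairs):
            shared = polys[i].intersection(polys[j])
            L = shared.length
            if L <= 1e-9:
                continue
            d = float(np.hypot(comps[i].centroid[0] - comps[j].centroid[0],
                               comps[i].centroid[1] - comps[j].centroid[1]))
            comps[i].neighbors.append((j, L, d))
            comps[j].neighbors.append((i, L, d))

    domain = CellDomain2D(length=length, width=width, compartments=comps)
    total = domain.areas.sum()
    if not np.isclose(total, length * width, rtol=1e-6):
        raise TopologyError(
            f"tessellation does not tile the rectangle: {total} != {length * width}"
        )
    return domain


def mark_boundary(domain: CellDomain2D,
                  edges: tuple[str, ...] = ("x0", "x1", "y0", "y1")) -> None:
    """Re-flag ``is_boundary`` for compartments touching the listed rectangle
    edges only (``x0``/``x1`` = basal/apical, ``y0``/``y1`` = lateral).

    Used for symmetry-reduced half domains, where the mirror plane is an
    interior line of the full cell rather than a membrane edge.
    """
    for c in domain.compartments:
        sides = _edge_lengths_on_sides(c.polygon, domain.length, domain.width)
        c.is_boundary = any(sides[e] > 1e-9 for e in edges)


# ---------------------------------------------------------------------------
# Wall-patch shell mesh
# ---------------------------------------------------------------------------

@dataclass
class ShellMesh:
    """Flat mid-surface mesh of the square wall patch.

    Nodes carry 3D coordinates (initially planar, z = 0). Elements are
    4-node quadrilaterals and/or 3-node triangles, each labelled ``inner``
    (centroid inside the circular central region) or ``outer``. Boundary
    nodes of the square are collected in ``fixed_node_set``.
    """

    nodes: np.ndarray                # (n_nodes, 3)
    quads: np.ndarray                # (n_quads, 4) int
    tris: np.ndarray                 # (n_tris, 3) int
    thickness: np.ndarray            # (n_elements,)
    region_label: np.ndarray         # (n_elements,) of {"inner", "outer"}
    fixed_node_set: np.ndarray       # node ids
    patch_center: tuple[float, float]
    patch_radius: float
    side: float = 0.0

    @property
    def n_elements(self) -> int:
        return len(self.quads) + len(self.tris)

    def element_nodes(self, e: int) -> np.ndarray:
        """Connectivity of element ``e`` (quads first, then triangles)."""
        if e < len(self.quads):
            return self.quads[e]
        return self.tris[e - len(self.quads)]

    @property
    def element_centroids(self) -> np.ndarray:
        cents = [self.nodes[self.element_nodes(e), :2].mean(axis=0)
                 for e in range(self.n_elements)]
        return np.array(cents)

    @property
    def element_areas(self) -> np.ndarray:
        out = np.empty(self.n_elements)
        for e in range(self.n_elements):
            xy = self.nodes[self.element_nodes(e), :2]
            x, y = xy[:, 0], xy[:, 1]
            out[e] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        return out

    @property
    def inner_mask(self) -> np.ndarray:
        return self.region_label == "inner"


def build_shell_mesh(
    side: float,
    thickness: float,
    patch_center: tuple[float, float],
    patch_radius: float,
    n_elements_per_side: int,
    conform: bool = False,
) -> ShellMesh:
    """Structured quad mesh of a ``side``×``side`` square with a circular
    inner region.

    With ``conform=True`` quads cut by the circle are split into four
    triangles at their centroid, sharpening the region boundary (mixed
    quad/tri mesh); otherwise a pure quad grid is used and elements are
    labelled by centroid position only.
    """
    if side <= 0 or thickness <= 0:
        raise InvalidGeometryError("side and thickness must be positive")
    if n_elements_per_side < 8:
        raise InvalidGeometryError("n_elements_per_side must be >= 8")
    cx, cy = patch_center
    if patch_radius < 0 or (
        patch_radius > 0
        and not (patch_radius <= cx <= side - patch_radius
                 and patch_radius <= cy <= side - patch_radius)
    ):
        raise InvalidGeometryError("circular patch must be contained in the square")

    n = n_elements_per_side
    h = side / n
    xs = np.linspace(0.0, side, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel(), np.zeros((n + 1) ** 2)])

    def nid(i, j):  # column i, row j
        return j * (n + 1) + i

    quads = []
    for j in range(n):
        for i in range(n):
            quads.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
    quads = np.array(quads, dtype=int)

    tris = np.empty((0, 3), dtype=int)
    if conform and patch_radius > 0:
        keep, split = [], []
        for q in quads:
            r = np.hypot(nodes[q, 0] - cx, nodes[q, 1] - cy)
            inside = r < patch_radius
            (split if 0 < inside.sum() < 4 else keep).append(q)
        new_nodes = list(nodes)
        new_tris = []
        for q in split:
            c = nodes[q].mean(axis=0)
            cidx = len(new_nodes)
            new_nodes.append(c)
            for a, b in zip(q, np.roll(q, -1)):
                new_tris.append([a, b, cidx])
        nodes = np.array(new_nodes)
        quads = np.array(keep, dtype=int)
        tris = np.array(new_tris, dtype=int)

    mesh = ShellMesh(
        nodes=nodes,
        quads=quads,
        tris=tris,
        thickness=np.full(len(quads) + len(tris), thickness),
        region_label=np.empty(len(quads) + len(tris), dtype=object),
        fixed_node_set=np.array([]),
        patch_center=patch_center,
        patch_radius=patch_radius,
        side=side,
    )
    cents = mesh.element_centroids
    r = np.hypot(cents[:, 0] - cx, cents[:, 1] - cy)
    mesh.region_label = np.where(r < patch_radius, "inner", "outer").astype(object)

    on_edge = (
        np.isclose(nodes[:, 0], 0.0) | np.isclose(nodes[:, 0], side)
        | np.isclose(nodes[:, 1], 0.0) | np.isclose(nodes[:, 1], side)
    )
    mesh.fixed_node_set = np.flatnonzero(on_edge)
    return mesh
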