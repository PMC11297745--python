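"""Rhizotron domain geometry and triangular mesh generation.

The measurement domain is a thin, water-filled tank (rhizotron) modelled as a
2D rectangle of the tank's inner width and the water height, with a uniform
out-of-plane thickness.  All coordinates are metres, x rightward and y upward
from the bottom-left corner of the tank.  Electrodes are points in the plane
(the physical wire protrusion is ignored); the mesh is a structured, graded
tensor-product triangulation whose node set contains every electrode position
exactly, with locally refined cell size around the electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RhizotronGeometry",
    "ElectrodeLayout",
    "TriMesh",
    "default_electrode_layout",
    "build_mesh",
    "total_volume",
]

#: inner tank width (m)
DEFAULT_WIDTH = 0.52
#: modelled height (m): tank height minus 3 cm freeboard down to the water level
DEFAULT_HEIGHT = 0.49
#: inner tank thickness (m)
DEFAULT_THICKNESS = 0.025
#: expected rooting zone used for spatially weighted survey design, (x0, y0, x1, y1) in m
DEFAULT_ROI = (0.085, 0.125, 0.435, 0.425)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode positions plus the designated central-batch subset.

    ``central_batch`` indexes the interior central column of electrodes that
    the reduced-scheme experiment removes from the survey.
    """

    positions: np.ndarray  # (n, 2) metres
    central_batch: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        # duplicate electrodes make the mesh and scheme ill-defined
        if len(np.unique(np.round(pos, 12), axis=0)) != len(pos):
            raise ValueError("duplicate electrode positions")
        object.__setattr__(self, "positions", pos)
        bad = [i for i in self.central_batch if not 0 <= i < len(pos)]
        if bad:
            raise ValueError(f"central_batch indices out of range: {bad}")

    def __len__(self) -> int:
        return len(self.positions)


def default_electrode_layout(
    width: float = DEFAULT_WIDTH,
    height: float = DEFAULT_HEIGHT,
    n_ring_bottom: int = 7,
    n_ring_side: int = 5,
    side_margin: float = 0.06,
    bottom_margin: float = 0.04,
    top_margin: float = 0.04,
    column_x: Sequence[float] = (0.16, 0.26, 0.36),
    column_y: Sequence[float] = (0.12, 0.20, 0.28, 0.36),
    central_columns: Sequence[int] = (0, 1, 2),
) -> ElectrodeLayout:
    """Construct the 36-electrode layout: a perimeter ring plus interior columns.

    The tank's published layout is a ring of electrodes around the rim and
    several interior columns; the exact coordinates are not tabulated, so the
    layout is parameterized and reconstructed here.  Defaults give 24 ring
    electrodes (7 bottom, 7 top, 5 per side) and 3 interior columns of 4,
    36 electrodes in total.  The interior columns (``central_columns``) form
    the "central batch" whose exclusion in the reduced-scheme comparison
    carves a low-sensitivity zone into the tank centre.
    """
    x0, x1 = side_margin, width - side_margin
    y0, y1 = bottom_margin, height - top_margin
    if not (0 < x0 < x1 < width and 0 < y0 < y1 < height):
        raise ValueError("electrode margins leave no interior span")
    pts: list[tuple[float, float]] = []
    xs = np.linspace(x0, x1, n_ring_bottom)
    pts += [(x, y0) for x in xs]                       # bottom row (with corners)
    pts += [(x, y1) for x in xs]                       # top row (with corners)
    ys = np.linspace(y0, y1, n_ring_side + 2)[1:-1]    # sides exclude corners
    pts += [(x0, y) for y in ys]
    pts += [(x1, y) for y in ys]
    central: list[int] = []
    for j, cx in enumerate(column_x):
        for cy in column_y:
            if j in central_columns:
                central.append(len(pts))
            pts.append((cx, cy))
    layout = ElectrodeLayout(np.array(pts, float), tuple(central))
    return layout


@dataclass(frozen=True)
class RhizotronGeometry:
    """Rectangular rhizotron cross-section with electrodes and rooting-zone ROI."""

    width: float = DEFAULT_WIDTH
    modelled_height: float = DEFAULT_HEIGHT
    thickness: float = DEFAULT_THICKNESS
    electrode_positions: np.ndarray = None  # type: ignore[assignment]
    central_batch: tuple[int, ...] = ()
    roi: tuple[float, float, float, float] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if min(self.width, self.modelled_height, self.thickness) <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.electrode_positions is None:
            layout = default_electrode_layout(self.width, self.modelled_height)
            object.__setattr__(self, "electrode_positions", layout.positions)
            object.__setattr__(self, "central_batch", layout.central_batch)
        else:
            layout = ElectrodeLayout(
                np.asarray(self.electrode_positions, float), tuple(self.central_batch)
            )
            object.__setattr__(self, "electrode_positions", layout.positions)
        pos = self.electrode_positions
        eps = 1e-12
        inside = (
            (pos[:, 0] >= -eps)
            & (pos[:, 0] <= self.width + eps)
            & (pos[:, 1] >= -eps)
            & (pos[:, 1] <= self.modelled_height + eps)
        )
        if not inside.all():
            raise ValueError("electrode positions outside the domain")
        rx0, ry0, rx1, ry1 = self.roi
        if not (0 <= rx0 < rx1 <= self.width and 0 <= ry0 < ry1 <= self.modelled_height):
            raise ValueError("roi not contained in the domain")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_positions)


@dataclass
class TriMesh:
    """Conforming triangle mesh of the rhizotron cross-section.

    ``cell_volumes`` are triangle areas times the uniform tank thickness, so
    volume-weighted integrals over cells are physical volumes in m³.
    """

    nodes: np.ndarray          # (n_nodes, 2)
    cells: np.ndarray          # (n_cells, 3) int, CCW
    thickness: float
    electrode_nodes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.cells = np.asarray(self.cells, np.int64)
        if self.cells.size == 0:
            raise ValueError("mesh has no cells")
        areas = self.cell_areas
        if np.any(areas <= 0):
            raise ValueError("mesh contains non-positive-area cells")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_areas(self) -> np.ndarray:
        p = self.nodes[self.cells]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    @property
    def cell_volumes(self) -> np.ndarray:
        return self.cell_areas * self.thickness

    @property
    def cell_centroids(self) -> np.ndarray:
        return self.nodes[self.cells].mean(axis=1)

    def cell_neighbors(self) -> np.ndarray:
        """Pairs (i, j) of cells sharing an edge, each pair once, i < j."""
        edges: dict[tuple[int, int], int] = {}
        pairs: list[tuple[int, int]] = []
        for ci, tri in enumerate(self.cells):
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                other = edges.pop(key, None)
                if other is None:
                    edges[key] = ci
                else:
                    pairs.append((min(other, ci), max(other, ci)))
        return np.array(sorted(pairs), np.int64)

    def write_off(self, path: str) -> None:
        """Export as an ASCII OFF unstructured mesh file (z = 0 plane)."""
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{self.n_nodes} {self.n_cells} 0\n")
            for x, y in self.nodes:
                fh.write(f"{x:.12g} {y:.12g} 0\n")
            for a, b, c in self.cells:
                fh.write(f"3 {a} {b} {c}\n")


def _grid_lines(
    length: float,
    anchors: np.ndarray,
    spacings: np.ndarray,
    base_cell: float,
    refinement_level: float,
) -> np.ndarray:
    """1D grid lines: uniform base grid, anchor (electrode) lines, and graded
    refinement lines at ``refinement_level`` times the anchor's neighbour
    spacing on either side of each anchor.  Anchor lines are kept exactly;
    other lines closer than a fraction of the local refinement offset are
    merged away."""
    n_base = max(2, int(round(length / base_cell)) + 1)
    base = np.linspace(0.0, length, n_base)
    fixed = np.unique(np.concatenate([[0.0, length], anchors]))
    refine = []
    for a, s in zip(anchors, spacings):
        d = refinement_level * s
        for off in (-d, d, -2 * d, 2 * d):
            v = a + off
            if 0 < v < length:
                refine.append(v)
    min_gap = 0.45 * refinement_level * spacings.min()
    lines = list(fixed)
    for v in sorted(set(np.concatenate([base, np.array(refine)]).tolist())):
        if np.min(np.abs(np.asarray(lines) - v)) > min_gap:
            lines.append(v)
    return np.array(sorted(lines))


def build_mesh(
    geometry: RhizotronGeometry,
    refinement_level: float = 0.25,
    base_cell: float = 0.02,
) -> TriMesh:
    """Triangulate the rhizotron with electrode positions as mesh nodes.

    A graded tensor-product grid is built whose x- and y-lines include every
    electrode coordinate plus refinement lines at ``refinement_level`` times
    each electrode's nearest-neighbour spacing; each grid quad is split into
    two triangles.  ``base_cell`` sets the background cell size away from
    electrodes.
    """
    if not 0 < refinement_level <= 1:
        raise ValueError("refinement_level must be in (0, 1]")
    pos = geometry.electrode_positions
    if len(pos) < 1:
        raise ValueError("geometry has no electrodes")
    # nearest-neighbour spacing per electrode
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    spacing = np.sqrt(d2.min(axis=1))
    xs = _grid_lines(geometry.width, pos[:, 0], spacing, base_cell, refinement_level)
    ys = _grid_lines(geometry.modelled_height, pos[:, 1], spacing, base_cell, refinement_level)
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i: int, j: int) -> int:
        return i * ny + j

    cells = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            # alternate the diagonal for an isotropic union-jack pattern
            if (i + j) % 2 == 0:
                cells += [(a, b, c), (a, c, d)]
            else:
                cells += [(a, b, d), (b, c, d)]
    cells = np.array(cells, np.int64)

    electrode_nodes: dict[int, int] = {}
    for k, (ex, ey) in enumerate(pos):
        i = int(np.argmin(np.abs(xs - ex)))
        j = int(np.argmin(np.abs(ys - ey)))
        if abs(xs[i] - ex) > 1e-9 or abs(ys[j] - ey) > 1e-9:
            raise RuntimeError(f"electrode {k} does not coincide with a grid node")
        electrode_nodes[k] = nid(i, j)
    return TriMesh(nodes, cells, geometry.thickness, electrode_nodes)


def subdivide(mesh: TriMesh) -> TriMesh:
    """Uniform 1-to-4 midpoint subdivision of every triangle.

    Cell k of the parent maps to children 4k..4k+3, so a per-cell field
    transfers exactly with ``np.repeat(values, 4)`` — useful for
    mesh-convergence checks with an identical material model.
    """
    nodes = [tuple(p) for p in mesh.nodes]
    midpoint: dict[tuple[int, int], int] = {}

    def mid(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in midpoint:
            midpoint[key] = len(nodes)
            nodes.append(tuple((mesh.nodes[a] + mesh.nodes[b]) / 2))
        return midpoint[key]

    cells = []
    for a, b, c in mesh.cells:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        cells += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
    return TriMesh(
        np.array(nodes), np.array(cells, np.int64), mesh.thickness, dict(mesh.electrode_nodes)
    )


def total_volume(mesh: TriMesh) -> float:
    """Total modelled volume Σ V_k in m³."""
    vols = mesh.cell_volumes
    if vols.size == 0:
        raise ValueError("mesh has no cells")
    return float(vols.sum())
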