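"""Unstructured triangulation of circular phantom domains.

Meshes are built from concentric rings of points (a near-hexagonal layout)
triangulated with Delaunay.  Because a disk is convex, the Delaunay
triangulation tiles the polygonal hull exactly; boundary nodes are the
outermost ring and lie on the circle.  Meshes for different diameters with
the same *relative* element size are similar, so a unit-disk template is
cached and rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import Delaunay


@dataclass(frozen=True, eq=False)
class Mesh:
    """Linear-triangle mesh of a disk.

    Attributes
    ----------
    node_coordinates : (n_nodes, 2) float array, mm
    triangle_connectivity : (n_tri, 3) int array
        Counter-clockwise node triples.
    boundary_node_flags : (n_nodes,) bool array
    characteristic_element_size : float, mm
    """

    node_coordinates: np.ndarray
    triangle_connectivity: np.ndarray
    boundary_node_flags: np.ndarray
    characteristic_element_size: float

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangle_connectivity.shape[0]

    def triangle_areas(self) -> np.ndarray:
        """Signed areas of all triangles (positive for CCW orientation)."""
        p = self.node_coordinates[self.triangle_connectivity]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def boundary_edges(self) -> np.ndarray:
        """(n_edges, 2) node pairs forming the boundary polygon."""
        tri = self.triangle_connectivity
        raw = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        key = np.sort(raw, axis=1)
        _, idx, counts = np.unique(
            key, axis=0, return_index=True, return_counts=True
        )
        # edges shared by a single triangle form the boundary polygon
        return raw[idx[counts == 1]]


@lru_cache(maxsize=16)
def _unit_disk_points(n_rings: int) -> tuple:
    """Ring layout on the unit disk; outer-ring count a multiple of 16."""
    pts = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = i / n_rings
        if i == n_rings:
            n_i = 16 * max(1, int(np.ceil(6 * i / 16)))
        else:
            n_i = 6 * i
        # stagger alternate rings for better-shaped triangles
        offset = (np.pi / n_i) * (i % 2)
        theta = offset + 2 * np.pi * np.arange(n_i) / n_i
        pts.extend(zip(r * np.cos(theta), r * np.sin(theta)))
    pts = np.asarray(pts, dtype=float)
    return pts, len(pts) - (16 * max(1, int(np.ceil(6 * n_rings / 16))))


@lru_cache(maxsize=16)
def _unit_disk_mesh(n_rings: int):
    pts, n_interior = _unit_disk_points(n_rings)
    tri = Delaunay(pts)
    simplices = tri.simplices.copy()
    # enforce CCW orientation
    p = pts[simplices]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = area2 < 0
    simplices[flip, 1], simplices[flip, 2] = (
        simplices[flip, 2].copy(),
        simplices[flip, 1].copy(),
    )
    flags = np.zeros(len(pts), dtype=bool)
    flags[n_interior:] = True
    return pts, simplices, flags


def build_circular_mesh(diameter: float, target_element_size: float) -> Mesh:
    """Triangulate a disk of the given diameter.

    Parameters
    ----------
    diameter : float, mm
        Phantom diameter, expected in [50, 150].
    target_element_size : float, mm
        Requested characteristic edge length; must be < diameter / 10.

    Returns
    -------
    Mesh
    """
    if not (50.0 <= diameter <= 150.0):
        raise ValueError("diameter must lie in [50, 150] mm")
    if target_element_size >= diameter / 10.0:
        raise ValueError("target_element_size must be < diameter/10")
    if target_element_size <= 0:
        raise ValueError("target_element_size must be positive")
    radius = diameter / 2.0
    n_rings = max(5, int(round(radius / target_element_size)))
    pts, simplices, flags = _unit_disk_mesh(n_rings)
    mesh = Mesh(
        node_coordinates=pts * radius,
        triangle_connectivity=simplices,
        boundary_node_flags=flags,
        characteristic_element_size=radius / n_rings,
    )
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise RuntimeError(f"degenerate triangle {bad} in mesh")
    return mesh


def save_mesh_txt(mesh: Mesh, path) -> None:
    """Write the mesh as a plain-text node/element list."""
    with open(path, "w") as fh:
        fh.write(f"# diffdot mesh  h={mesh.characteristic_element_size:.6g}\n")
        fh.write(f"{mesh.n_nodes} {mesh.n_triangles}\n")
        for (x, y), b in zip(mesh.node_coordinates, mesh.boundary_node_flags):
            fh.write(f"{x:.12g} {y:.12g} {int(b)}\n")
        for a, b, c in mesh.triangle_connectivity:
            fh.write(f"{a} {b} {c}\n")


def load_mesh_txt(path) -> Mesh:
    """Read a mesh written by :func:`save_mesh_txt`."""
    with open(path) as fh:
        header = fh.readline()
        h = float(header.strip().split("h=")[1]) if "h=" in header else 1.0
        n_nodes, n_tri = map(int, fh.readline().split())
        coords = np.empty((n_nodes, 2))
        flags = np.empty(n_nodes, dtype=bool)
        for i in range(n_nodes):
            x, y, b = fh.readline().split()
            coords[i] = (float(x), float(y))
            flags[i] = bool(int(b))
        tris = np.empty((n_tri, 3), dtype=int)
        for i in range(n_tri):
            tris[i] = [int(t) for t in fh.readline().split()]
    return Mesh(coords, tris, flags, h)
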