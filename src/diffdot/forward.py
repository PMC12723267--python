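"""Frequency-domain diffusion forward model on circular domains.

Solves ``(-div D grad + mu_a - i w/c) phi = S`` with Robin boundary
conditions by linear (P1) triangle finite elements and extracts boundary
amplitude/phase measurements for a 16-source / 15-detector layout in which
the detectors of each source are the remaining 15 of the 16 equidistant
boundary positions.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .mesh import Mesh
from .physics import PhysicsConstants, angular_frequency, diffusion_coefficient

N_SOURCES = 16
N_DETECTORS = 15


@dataclass
class PropertyField:
    """Nodal optical properties (mm^-1)."""

    mu_a_nodal: np.ndarray
    mu_s_prime_nodal: np.ndarray

    def __post_init__(self):
        self.mu_a_nodal = np.asarray(self.mu_a_nodal, dtype=float)
        self.mu_s_prime_nodal = np.asarray(self.mu_s_prime_nodal, dtype=float)
        if np.any(self.mu_a_nodal <= 0) or np.any(self.mu_s_prime_nodal <= 0):
            raise ValueError("optical properties must be strictly positive")
        if np.any(self.mu_s_prime_nodal < self.mu_a_nodal):
            raise ValueError(
                "diffusion approximation requires mu_s' >= mu_a everywhere"
            )

    @property
    def diffusion_nodal(self) -> np.ndarray:
        return diffusion_coefficient(self.mu_a_nodal, self.mu_s_prime_nodal)


@dataclass(frozen=True)
class ProbeLayout:
    """Positions of the 16 sources and their 15 detectors each.

    ``source_positions`` are the boundary contact points; the effective
    isotropic source is placed ``source_depth_offset`` (one transport mean
    free path by default) inside the domain at ``effective_source_positions``.
    Detector evaluation points sit fractionally inside the boundary polygon
    (``detector_radius_factor``) so that interpolation is well defined on the
    chordal mesh boundary.
    """

    source_angles: np.ndarray
    source_positions: np.ndarray
    effective_source_positions: np.ndarray
    detector_positions_per_source: np.ndarray
    source_depth_offset: float
    detector_radius_factor: float = 0.99

    @property
    def n_pairs(self) -> int:
        return self.detector_positions_per_source.shape[0] * (
            self.detector_positions_per_source.shape[1]
        )

    def detector_index_map(self) -> np.ndarray:
        """(16, 15) array: canonical boundary-position index of each detector."""
        out = np.empty((N_SOURCES, N_DETECTORS), dtype=int)
        for s in range(N_SOURCES):
            out[s] = [k for k in range(N_SOURCES) if k != s]
        return out


def place_probes(
    diameter: float,
    constants: PhysicsConstants = PhysicsConstants(),
    mu_s_prime_background: Optional[float] = None,
    source_depth_offset: Optional[float] = None,
    detector_radius_factor: float = 0.99,
) -> ProbeLayout:
    """Build the 16-source/15-detector layout for a circular phantom.

    The source depth defaults to one transport mean free path ``1/mu_s'``
    (1 mm when no background scattering is given).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter / 2.0
    if source_depth_offset is None:
        if mu_s_prime_background is not None:
            source_depth_offset = 1.0 / mu_s_prime_background
        else:
            source_depth_offset = 1.0
    angles = 2.0 * np.pi * np.arange(N_SOURCES) / N_SOURCES
    ring = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    source_positions = radius * ring
    effective = (radius - source_depth_offset) * ring
    det_radius = radius * detector_radius_factor
    detectors = np.empty((N_SOURCES, N_DETECTORS, 2))
    for s in range(N_SOURCES):
        others = [k for k in range(N_SOURCES) if k != s]
        detectors[s] = det_radius * ring[others]
    return ProbeLayout(
        source_angles=angles,
        source_positions=source_positions,
        effective_source_positions=effective,
        detector_positions_per_source=detectors,
        source_depth_offset=source_depth_offset,
        detector_radius_factor=detector_radius_factor,
    )


# ---------------------------------------------------------------------------
# point location / interpolation

_LOCATORS: "weakref.WeakKeyDictionary[Mesh, Delaunay]" = weakref.WeakKeyDictionary()


def _locator(mesh: Mesh) -> Delaunay:
    loc = _LOCATORS.get(mesh)
    if loc is None:
        loc = Delaunay(mesh.node_coordinates)
        _LOCATORS[mesh] = loc
    return loc


def interpolation_vectors(mesh: Mesh, points: np.ndarray):
    """Barycentric interpolation of nodal fields at arbitrary points.

    Returns ``(node_indices, weights)`` with shapes (m, 3); points slightly
    outside the chordal boundary are pulled toward the origin until they
    fall inside (raises if a point is genuinely outside the mesh).
    """
    loc = _locator(mesh)
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    simplex = loc.find_simplex(pts)
    for _ in range(60):
        outside = simplex < 0
        if not outside.any():
            break
        pts[outside] *= 0.999
        simplex[outside] = loc.find_simplex(pts[outside])
    if (simplex < 0).any():
        raise ValueError("point outside mesh")
    trans = loc.transform[simplex]
    bary = np.einsum("mij,mj->mi", trans[:, :2], pts - trans[:, 2])
    weights = np.concatenate([bary, 1.0 - bary.sum(axis=1, keepdims=True)], axis=1)
    nodes = loc.simplices[simplex]
    return nodes, weights


def interpolation_vector_sparse(mesh: Mesh, point) -> np.ndarray:
    """Dense length-n_nodes vector w with w.phi = phi(point)."""
    nodes, weights = interpolation_vectors(mesh, np.atleast_2d(point))
    w = np.zeros(mesh.n_nodes)
    w[nodes[0]] = weights[0]
    return w


def interpolate_nodal(mesh: Mesh, nodal: np.ndarray, points: np.ndarray) -> np.ndarray:
    nodes, weights = interpolation_vectors(mesh, points)
    return (nodal[nodes] * weights).sum(axis=1)


# ---------------------------------------------------------------------------
# assembly

@dataclass
class ElementData:
    """Per-element geometric factors reused by assembly and sensitivities."""

    nodes: np.ndarray          # (n_tri, 3)
    areas: np.ndarray          # (n_tri,)
    stiffness_unit: np.ndarray  # (n_tri, 3, 3)  integral grad.grad (D=1)
    mass_unit: np.ndarray       # (n_tri, 3, 3)  integral phi_i phi_j
    boundary_edges: np.ndarray  # (n_edge, 2)
    edge_mass: np.ndarray       # (n_edge, 2, 2) integral over edge


def element_data(mesh: Mesh) -> ElementData:
    tri = mesh.triangle_connectivity
    p = mesh.node_coordinates[tri]  # (n_tri, 3, 2)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    area2 = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    if np.any(area2 <= 0):
        bad = int(np.argmin(area2))
        raise RuntimeError(f"degenerate triangle {bad}")
    areas = 0.5 * area2
    # P1 gradients: grad_i = rot90(opposite edge) / (2 A)
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    grads = np.stack(
        [
            np.stack([-e0[:, 1], e0[:, 0]], axis=1),
            np.stack([-e1[:, 1], e1[:, 0]], axis=1),
            np.stack([-e2[:, 1], e2[:, 0]], axis=1),
        ],
        axis=1,
    ) / area2[:, None, None]
    stiffness = np.einsum("tik,tjk->tij", grads, grads) * areas[:, None, None]
    m = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    mass = areas[:, None, None] * m
    edges = mesh.boundary_edges()
    pe = mesh.node_coordinates[edges]
    lengths = np.linalg.norm(pe[:, 1] - pe[:, 0], axis=1)
    em = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
    edge_mass = lengths[:, None, None] * em
    return ElementData(tri, areas, stiffness, mass, edges, edge_mass)


def _scatter(n_nodes, nodes, local):
    """Assemble (n_tri, k, k) local matrices into a CSR sparse matrix."""
    k = nodes.shape[1]
    rows = np.repeat(nodes, k, axis=1).ravel()
    cols = np.tile(nodes, (1, k)).ravel()
    return sp.coo_matrix(
        (local.ravel(), (rows, cols)), shape=(n_nodes, n_nodes)
    ).tocsr()


@dataclass
class FEMSystem:
    """Discrete frequency-domain diffusion system ``A phi = b``."""

    system_matrix: sp.spmatrix
    source_vectors: np.ndarray  # (n_sources, n_nodes) complex
    angular_frequency: float
    mesh: Mesh = None
    elements: ElementData = None
    layout: ProbeLayout = None
    _factor: object = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.system_matrix.shape[0]

    def factorize(self):
        if self._factor is None:
            self._factor = spla.splu(self.system_matrix.tocsc())
        return self._factor


@dataclass
class OpticalField:
    """Complex photon density at the mesh nodes for one source."""

    nodal_photon_density: np.ndarray
    mesh: Mesh = None


def assemble_mua_d(
    mesh: Mesh,
    mu_a_nodal: np.ndarray,
    d_nodal: np.ndarray,
    frequency_mhz: float,
    constants: PhysicsConstants = PhysicsConstants(),
    layout: Optional[ProbeLayout] = None,
    elements: Optional[ElementData] = None,
) -> FEMSystem:
    """Assemble the P1 finite-element system for all 16 sources.

    Takes nodal absorption and diffusion coefficient directly (the
    parameterization used by the inverse solver).  The element coefficients
    are the means of the three nodal values, which makes discrete
    sensitivities with respect to nodal parameters exact (each node
    contributes 1/3 of its element matrices).
    """
    if len(mu_a_nodal) != mesh.n_nodes:
        raise ValueError("property field does not match mesh")
    if elements is None:
        elements = element_data(mesh)
    omega = angular_frequency(frequency_mhz)
    c = constants.light_speed_medium
    d_elem = d_nodal[elements.nodes].mean(axis=1)
    mua_elem = mu_a_nodal[elements.nodes].mean(axis=1)
    coef = mua_elem - 1j * omega / c
    local = (
        d_elem[:, None, None] * elements.stiffness_unit
        + coef[:, None, None] * elements.mass_unit
    )
    a = _scatter(mesh.n_nodes, elements.nodes, local).astype(complex)
    robin = _scatter(
        mesh.n_nodes,
        elements.boundary_edges,
        elements.edge_mass / (2.0 * constants.robin_coefficient),
    )
    a = a + robin.astype(complex)
    if layout is None:
        diameter = 2.0 * np.linalg.norm(mesh.node_coordinates, axis=1).max()
        mu_s_med = 1.0 / (3.0 * float(np.median(d_nodal))) - float(
            np.median(mu_a_nodal)
        )
        layout = place_probes(
            diameter, constants, mu_s_prime_background=max(mu_s_med, 0.5)
        )
    sources = np.zeros((N_SOURCES, mesh.n_nodes), dtype=complex)
    nodes, weights = interpolation_vectors(mesh, layout.effective_source_positions)
    for s in range(N_SOURCES):
        sources[s, nodes[s]] += weights[s]
    return FEMSystem(
        system_matrix=a,
        source_vectors=sources,
        angular_frequency=omega,
        mesh=mesh,
        elements=elements,
        layout=layout,
    )


def assemble_system(
    mesh: Mesh,
    props: PropertyField,
    frequency_mhz: float,
    constants: PhysicsConstants = PhysicsConstants(),
    layout: Optional[ProbeLayout] = None,
    elements: Optional[ElementData] = None,
) -> FEMSystem:
    """Assemble the system from a (mu_a, mu_s') property field."""
    return assemble_mua_d(
        mesh,
        props.mu_a_nodal,
        props.diffusion_nodal,
        frequency_mhz,
        constants,
        layout,
        elements,
    )


def solve_forward(system: FEMSystem, source_index: int) -> OpticalField:
    """Solve for one source; the sparse LU factor is shared across sources."""
    if not 0 <= source_index < system.source_vectors.shape[0]:
        raise IndexError("source index out of range")
    lu = system.factorize()
    phi = lu.solve(system.source_vectors[source_index])
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("forward solve produced non-finite photon density")
    return OpticalField(nodal_photon_density=phi, mesh=system.mesh)


def solve_all(system: FEMSystem) -> list:
    lu = system.factorize()
    sols = lu.solve(system.source_vectors.T)
    return [OpticalField(sols[:, s], system.mesh) for s in range(sols.shape[1])]


@dataclass
class MeasurementSet:
    """Boundary observations: 16x15 amplitude and phase arrays."""

    amplitude: np.ndarray
    phase: np.ndarray
    frequency_mhz: float

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)

    def stacked(self) -> np.ndarray:
        """(16, 15, 2) array: log-amplitude is *not* applied here."""
        return np.stack([self.amplitude, self.phase], axis=-1)


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Map phases to the principal interval (-pi, pi]."""
    wrapped = np.mod(-phase + np.pi, 2.0 * np.pi)
    return np.pi - wrapped


def measure(fields, layout: ProbeLayout, frequency_mhz: float = 0.0) -> MeasurementSet:
    """Interpolate complex photon density at every detector.

    ``fields`` is a sequence of 16 :class:`OpticalField`, one per source,
    in source order.
    """
    if len(fields) != N_SOURCES:
        raise ValueError("one field per source is required")
    amplitude = np.empty((N_SOURCES, N_DETECTORS))
    phase = np.empty((N_SOURCES, N_DETECTORS))
    for s, fld in enumerate(fields):
        vals = interpolate_nodal(
            fld.mesh,
            fld.nodal_photon_density,
            layout.detector_positions_per_source[s],
        )
        amplitude[s] = np.abs(vals)
        phase[s] = wrap_phase(np.angle(vals))
    if np.any(amplitude <= 0):
        raise RuntimeError("non-positive measured amplitude")
    return MeasurementSet(amplitude=amplitude, phase=phase, frequency_mhz=frequency_mhz)


def interpolate_to_grid(
    mesh: Mesh,
    nodal: np.ndarray,
    diameter: float,
    n: int = 64,
    fill: float = 0.0,
) -> np.ndarray:
    """Sample a nodal field at the centres of an n x n grid over the
    bounding square; pixels outside the disk receive ``fill``."""
    radius = diameter / 2.0
    pitch = diameter / n
    centers = -radius + pitch * (np.arange(n) + 0.5)
    xx, yy = np.meshgrid(centers, centers, indexing="xy")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    rr = np.hypot(pts[:, 0], pts[:, 1])
    inside = rr <= radius
    out = np.full(n * n, float(fill))
    if inside.any():
        out[inside] = interpolate_nodal(mesh, nodal, pts[inside])
    return out.reshape(n, n)
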