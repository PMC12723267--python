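"""Synthetic circular tissue phantoms and their simulated boundary data.

The generator draws circular phantoms with 0-2 embedded inclusion disks.
Default parameter ranges describe near-infrared breast-tissue imaging at
frequency-domain modulation: diameters 60-150 mm, background absorption
0.005-0.03 mm^-1, reduced scattering 0.5-3 mm^-1, modulation 10-100 MHz,
inclusion contrasts 1.5-8x background and radii 2-30 mm.  The population is
1% homogeneous, 44% single-inclusion and 55% double-inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from . import forward
from .forward import (
    MeasurementSet,
    PropertyField,
    ProbeLayout,
    assemble_system,
    measure,
    place_probes,
    solve_all,
)
from .mesh import Mesh, build_circular_mesh
from .physics import PhysicsConstants

GRID = 64

#: default sampling ranges (min, max)
DEFAULT_RANGES = {
    "diameter": (60.0, 150.0),
    "frequency": (10.0, 100.0),
    "mu_a": (0.005, 0.03),
    "mu_s_prime": (0.5, 3.0),
    "contrast": (1.5, 8.0),
    "inclusion_radius": (2.0, 30.0),
}

#: homogeneous / one-inclusion / two-inclusion category probabilities
CATEGORY_PROBS = (0.01, 0.44, 0.55)


@dataclass(frozen=True)
class Inclusion:
    """A circular inhomogeneity: contrasts multiply the background values."""

    center: tuple
    radius: float
    contrast_a: float
    contrast_s: float


@dataclass(frozen=True)
class Phantom:
    diameter: float
    background_mu_a: float
    background_mu_s_prime: float
    frequency_mhz: float
    inclusions: tuple = ()

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def properties_at(self, points: np.ndarray):
        """(mu_a, mu_s') arrays at arbitrary (m, 2) points."""
        pts = np.atleast_2d(points)
        mu_a = np.full(len(pts), self.background_mu_a)
        mu_s = np.full(len(pts), self.background_mu_s_prime)
        for inc in self.inclusions:
            d = np.hypot(pts[:, 0] - inc.center[0], pts[:, 1] - inc.center[1])
            inside = d <= inc.radius
            mu_a[inside] = self.background_mu_a * inc.contrast_a
            mu_s[inside] = self.background_mu_s_prime * inc.contrast_s
        return mu_a, mu_s

    def homogeneous(self) -> "Phantom":
        return replace(self, inclusions=())


def sample_phantom(rng, ranges: Optional[dict] = None) -> Phantom:
    """Draw one phantom from the dataset recipe.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.  The
    inclusion count is drawn from :data:`CATEGORY_PROBS`; inclusion
    geometry is rejection-sampled until every disk lies inside the phantom
    and the two disks (if present) do not overlap.
    """
    rng = np.random.default_rng(rng)
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    diameter = rng.uniform(*r["diameter"])
    phantom = Phantom(
        diameter=diameter,
        background_mu_a=rng.uniform(*r["mu_a"]),
        background_mu_s_prime=rng.uniform(*r["mu_s_prime"]),
        frequency_mhz=rng.uniform(*r["frequency"]),
    )
    n_incl = rng.choice(3, p=CATEGORY_PROBS)
    margin = 0.02 * phantom.radius  # keep inclusions off the very boundary
    # rejection sampling with full-set restarts: an unlucky large first
    # inclusion in a small phantom could otherwise block the second one
    for _ in range(1000):
        incs: List[Inclusion] = []
        for _ in range(20 * max(n_incl, 1)):
            if len(incs) == n_incl:
                break
            radius = rng.uniform(*r["inclusion_radius"])
            if radius >= phantom.radius - margin:
                continue
            # uniform over the admissible center disk
            rho = (phantom.radius - radius - margin) * np.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = Inclusion(
                center=(rho * np.cos(theta), rho * np.sin(theta)),
                radius=radius,
                contrast_a=rng.uniform(*r["contrast"]),
                contrast_s=rng.uniform(*r["contrast"]),
            )
            if any(
                np.hypot(
                    cand.center[0] - o.center[0], cand.center[1] - o.center[1]
                )
                < cand.radius + o.radius
                for o in incs
            ):
                continue
            incs.append(cand)
        if len(incs) == n_incl:
            return replace(phantom, inclusions=tuple(incs))
    raise RuntimeError("inclusion rejection sampling did not converge")


@dataclass
class PropertyImage:
    """64x64x2 ground-truth / reconstruction grid of (mu_a, mu_s')."""

    values: np.ndarray          # (64, 64, 2), mm^-1
    pixel_pitch: float          # mm
    domain_mask: np.ndarray     # (64, 64) bool, True inside the phantom disk

    @property
    def mu_a(self) -> np.ndarray:
        return self.values[..., 0]

    @property
    def mu_s_prime(self) -> np.ndarray:
        return self.values[..., 1]


def _pixel_centers(diameter: float, n: int = GRID):
    pitch = diameter / n
    c = -diameter / 2.0 + pitch * (np.arange(n) + 0.5)
    xx, yy = np.meshgrid(c, c, indexing="xy")
    return np.stack([xx.ravel(), yy.ravel()], axis=1), pitch


def rasterize(phantom: Phantom, n: int = GRID) -> PropertyImage:
    """Rasterize a phantom by pixel-center membership tests.

    Pixels outside the phantom disk carry the background value (not zero)
    so that image metrics are not dominated by the mask; the mask itself is
    returned for optional masked analyses.
    """
    pts, pitch = _pixel_centers(phantom.diameter, n)
    mu_a, mu_s = phantom.properties_at(pts)
    rr = np.hypot(pts[:, 0], pts[:, 1])
    mask = (rr <= phantom.radius).reshape(n, n)
    values = np.stack([mu_a.reshape(n, n), mu_s.reshape(n, n)], axis=-1)
    return PropertyImage(values=values, pixel_pitch=pitch, domain_mask=mask)


def nodal_properties(phantom: Phantom, mesh: Mesh) -> PropertyField:
    """Point-in-disk property evaluation at the mesh nodes."""
    mu_a, mu_s = phantom.properties_at(mesh.node_coordinates)
    return PropertyField(mu_a_nodal=mu_a, mu_s_prime_nodal=mu_s)


def simulate(
    phantom: Phantom,
    mesh_rel_size: float = 1.0 / 25.0,
    constants: PhysicsConstants = PhysicsConstants(),
    mesh: Optional[Mesh] = None,
    layout: Optional[ProbeLayout] = None,
) -> MeasurementSet:
    """Full 16-source forward simulation of one phantom.

    ``mesh_rel_size`` is the element size as a fraction of the diameter
    (default diameter/25 at desk scale).
    """
    if mesh is None:
        mesh = build_circular_mesh(phantom.diameter, phantom.diameter * mesh_rel_size)
    if layout is None:
        layout = place_probes(
            phantom.diameter,
            constants,
            mu_s_prime_background=phantom.background_mu_s_prime,
        )
    props = nodal_properties(phantom, mesh)
    system = assemble_system(
        mesh, props, phantom.frequency_mhz, constants, layout=layout
    )
    fields = solve_all(system)
    return measure(fields, layout, phantom.frequency_mhz)


def add_noise(m: MeasurementSet, level: float = 0.15, rng=None) -> MeasurementSet:
    """Apply proportional amplitude noise and spread-scaled phase noise.

    Amplitude: multiplicative Gaussian, relative sigma = ``level``, clipped
    positive.  Phase: additive Gaussian with sigma = ``level`` times the
    per-sample phase standard deviation, re-wrapped to (-pi, pi].
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return MeasurementSet(m.amplitude.copy(), m.phase.copy(), m.frequency_mhz)
    rng = np.random.default_rng(rng)
    eps1 = rng.standard_normal(m.amplitude.shape)
    eps2 = rng.standard_normal(m.phase.shape)
    amp = m.amplitude * (1.0 + level * eps1)
    amp = np.maximum(amp, 1e-9 * m.amplitude)
    sigma_phase = float(np.std(m.phase))
    phase = forward.wrap_phase(m.phase + level * sigma_phase * eps2)
    return MeasurementSet(amplitude=amp, phase=phase, frequency_mhz=m.frequency_mhz)


@dataclass
class NormalizedInput:
    """16x15x2 network input: per-sample min-max scaled calibrated data."""

    array: np.ndarray  # (16, 15, 2)


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def calibrate(m: MeasurementSet, reference: MeasurementSet) -> NormalizedInput:
    """Reference-normalize measurements against a homogeneous phantom.

    Channel 0 is ``ln(amplitude) - ln(amplitude_ref)``, channel 1 the phase
    difference; each channel is then min-max scaled to [0, 1] per sample.
    """
    if np.any(m.amplitude <= 0) or np.any(reference.amplitude <= 0):
        raise ValueError("amplitudes must be positive for calibration")
    log_amp = np.log(m.amplitude) - np.log(reference.amplitude)
    phase = m.phase - reference.phase
    arr = np.stack([_minmax_scale(log_amp), _minmax_scale(phase)], axis=-1)
    return NormalizedInput(array=arr.astype(np.float32))


def calibration_channels(m: MeasurementSet, reference: MeasurementSet):
    """The two calibrated channels *before* min-max scaling."""
    return (
        np.log(m.amplitude) - np.log(reference.amplitude),
        m.phase - reference.phase,
    )
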