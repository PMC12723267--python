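"""Gauss-Newton reconstruction with Tikhonov regularization.

Minimizes ``||J dx - dPhi||^2 + lambda^2 ||dx||^2`` iteratively, where the
residual and Jacobian are parameterized in (log-amplitude, phase) and the
unknowns are the nodal absorption coefficient mu_a and diffusion
coefficient D.  Results are reported as (mu_a, mu_s') images on the 64x64
grid.  This is the classical baseline against which the learned
reconstructor is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .forward import (
    N_DETECTORS,
    N_SOURCES,
    FEMSystem,
    MeasurementSet,
    ProbeLayout,
    assemble_mua_d,
    element_data,
    interpolation_vectors,
    interpolate_to_grid,
    place_probes,
    wrap_phase,
)
from .mesh import Mesh, build_circular_mesh
from .phantoms import GRID, PropertyImage
from .physics import PhysicsConstants, diffusion_coefficient


@dataclass
class TRConfig:
    """Inverse-solver settings.

    ``lambda_relative`` scales the regularization weight to the largest
    diagonal entry of J^T J (so the absolute lambda follows the data scale);
    the regularization matrix is the identity.
    """

    lambda_relative: float = 0.01
    max_iterations: int = 20
    relative_residual_tolerance: float = 1e-3
    positivity_floor: float = 1e-5

    def __post_init__(self):
        if self.lambda_relative <= 0:
            raise ValueError("lambda_relative must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Jacobian:
    """Sensitivity of the 480 data values to the 2*n_nodes parameters.

    Row blocks: 240 log-amplitude rows then 240 phase rows (source-major
    pair order).  Column blocks: d/d(mu_a) then d/dD.
    """

    matrix: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[1] // 2


def _detector_functionals(mesh: Mesh, layout: ProbeLayout) -> np.ndarray:
    """(16, n_nodes) interpolation vectors at the canonical detector ring."""
    radius = np.linalg.norm(layout.source_positions[0])
    ring = layout.detector_radius_factor * radius
    pts = ring * np.stack(
        [np.cos(layout.source_angles), np.sin(layout.source_angles)], axis=1
    )
    nodes, weights = interpolation_vectors(mesh, pts)
    w = np.zeros((N_SOURCES, mesh.n_nodes))
    for k in range(N_SOURCES):
        w[k, nodes[k]] += weights[k]
    return w


def _forward_state(system: FEMSystem):
    """Direct fields, adjoint fields and complex detector values."""
    lu = system.factorize()
    phi = lu.solve(system.source_vectors.T).T            # (16, n)
    w = _detector_functionals(system.mesh, system.layout)
    psi = lu.solve(w.T.astype(complex)).T                # (16, n)
    det_map = system.layout.detector_index_map()
    vals = np.empty((N_SOURCES, N_DETECTORS), dtype=complex)
    for s in range(N_SOURCES):
        vals[s] = w[det_map[s]] @ phi[s]
    return phi, psi, vals, det_map


def _log_amp_phase(vals: np.ndarray):
    return np.log(np.abs(vals)), wrap_phase(np.angle(vals))


def _jacobian_from_state(system: FEMSystem, phi, psi, vals, det_map) -> Jacobian:
    if np.any(vals == 0):
        raise RuntimeError("zero photon density at a detector")
    elems = system.elements
    tri = elems.nodes
    n_nodes = system.n_nodes
    u = phi[:, tri]                                     # (16, n_e, 3)
    v = psi[:, tri]
    ku = np.einsum("eij,sej->sei", elems.stiffness_unit, u)
    mu = np.einsum("eij,sej->sei", elems.mass_unit, u)
    sk = np.einsum("dei,sei->sde", v, ku)               # (16, 16, n_e)
    sm = np.einsum("dei,sei->sde", v, mu)
    n_e = tri.shape[0]
    incidence = sp.coo_matrix(
        (
            np.full(3 * n_e, 1.0 / 3.0),
            (np.repeat(np.arange(n_e), 3), tri.ravel()),
        ),
        shape=(n_e, n_nodes),
    ).tocsr()
    # dPhi_sd/dp_node = -psi_d^T (dA/dp) phi_s, scattered from elements
    ck = -(sk.reshape(-1, n_e) @ incidence)             # (256, n_nodes) cplx
    cm = -(sm.reshape(-1, n_e) @ incidence)
    rows_la = np.empty((N_SOURCES * N_DETECTORS, 2 * n_nodes))
    rows_ph = np.empty_like(rows_la)
    for s in range(N_SOURCES):
        for j, d in enumerate(det_map[s]):
            idx = s * N_SOURCES + d
            pair = s * N_DETECTORS + j
            inv = 1.0 / vals[s, j]
            rows_la[pair, :n_nodes] = (inv * cm[idx]).real   # d/d mu_a
            rows_la[pair, n_nodes:] = (inv * ck[idx]).real   # d/d D
            rows_ph[pair, :n_nodes] = (inv * cm[idx]).imag
            rows_ph[pair, n_nodes:] = (inv * ck[idx]).imag
    return Jacobian(matrix=np.vstack([rows_la, rows_ph]))


def compute_jacobian(
    mesh: Mesh,
    props,
    layout: ProbeLayout,
    frequency_mhz: float,
    constants: PhysicsConstants = PhysicsConstants(),
) -> Jacobian:
    """Adjoint-method Jacobian of (log-amplitude, phase) data with respect
    to nodal (mu_a, D) for the full 240-pair layout."""
    system = assemble_mua_d(
        mesh,
        np.asarray(props.mu_a_nodal, dtype=float),
        np.asarray(props.diffusion_nodal, dtype=float),
        frequency_mhz,
        constants,
        layout=layout,
    )
    state = _forward_state(system)
    return _jacobian_from_state(system, *state)


def tr_update(J, residual: np.ndarray, lambda_abs: float) -> np.ndarray:
    """Solve the regularized normal equations ``(J'J + l^2 I) dx = J' r``.

    When the system is underdetermined the dual form
    ``dx = J'(JJ' + l^2 I)^{-1} r`` is used; the two are algebraically
    identical for lambda > 0.
    """
    mat = J.matrix if isinstance(J, Jacobian) else np.asarray(J, dtype=float)
    residual = np.asarray(residual, dtype=float)
    if mat.shape[0] != residual.shape[0]:
        raise ValueError("residual length does not match Jacobian rows")
    if lambda_abs < 0:
        raise ValueError("lambda must be >= 0")
    m, n = mat.shape
    if lambda_abs == 0.0:
        gram = mat.T @ mat
        rhs = mat.T @ residual
        try:
            cond = np.linalg.cond(gram)
            if not np.isfinite(cond) or cond > 1e12:
                raise np.linalg.LinAlgError
            return np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "rank-deficient Jacobian with lambda = 0; "
                "use a positive regularization parameter"
            ) from exc
    if m < n:
        dual = mat @ mat.T
        dual[np.diag_indices_from(dual)] += lambda_abs**2
        return mat.T @ np.linalg.solve(dual, residual)
    gram = mat.T @ mat
    gram[np.diag_indices_from(gram)] += lambda_abs**2
    return np.linalg.solve(gram, mat.T @ residual)


@dataclass
class TikhonovResults:
    """Reconstruction output with its iteration diagnostics."""

    property_image: PropertyImage
    mu_a_nodal: np.ndarray
    mu_s_prime_nodal: np.ndarray
    mesh: Mesh
    residual_history: list
    iterations_run: int
    converged: bool
    diverged: bool
    background_estimate: tuple

    def summary(self) -> str:
        lines = [
            "Tikhonov-regularized Gauss-Newton reconstruction",
            "=" * 48,
            f"iterations run        : {self.iterations_run}",
            f"converged             : {self.converged}",
            f"flagged divergent     : {self.diverged}",
            f"initial data misfit   : {self.residual_history[0]:.6g}",
            f"final data misfit     : {self.residual_history[-1]:.6g}",
            (
                "background estimate   : mu_a={0:.5g} mm^-1, "
                "mu_s'={1:.5g} mm^-1".format(*self.background_estimate)
            ),
        ]
        return "\n".join(lines)


def estimate_background(
    measurements: MeasurementSet,
    mesh: Mesh,
    diameter: float,
    constants: PhysicsConstants,
    x0=(0.0175, 1.75),
) -> tuple:
    """Fit a homogeneous (mu_a, mu_s') pair to the boundary data.

    The probe layout is rebuilt for every trial point so the effective
    source depth (one transport mean free path) stays consistent with the
    candidate scattering coefficient.
    """
    elements = element_data(mesh)
    meas = np.concatenate(
        [np.log(measurements.amplitude).ravel(), measurements.phase.ravel()]
    )

    def misfit(x):
        mu_a, mu_s = x
        d = diffusion_coefficient(mu_a, mu_s)
        layout = place_probes(diameter, constants, mu_s_prime_background=mu_s)
        system = assemble_mua_d(
            mesh,
            np.full(mesh.n_nodes, mu_a),
            np.full(mesh.n_nodes, d),
            measurements.frequency_mhz,
            constants,
            layout=layout,
            elements=elements,
        )
        _, _, vals, _ = _forward_state(system)
        la, ph = _log_amp_phase(vals)
        return np.concatenate([la.ravel(), ph.ravel()]) - meas

    res = least_squares(
        misfit,
        x0=np.asarray(x0),
        bounds=([1e-4, 0.1], [0.1, 5.0]),
        xtol=1e-8,
        max_nfev=40,
    )
    return float(res.x[0]), float(res.x[1])


class TikhonovReconstruction:
    """Model object: boundary data plus geometry, fitted by Gauss-Newton.

    Parameters
    ----------
    measurements : MeasurementSet
        Noisy (or clean) 16x15 amplitude/phase data.
    diameter : float, mm
        Phantom diameter.
    config : TRConfig
    initial_guess : (mu_a, mu_s'), optional
        Homogeneous starting point; estimated from the data if omitted.
    mesh_rel_size : float
        Element size as a fraction of the diameter.
    """

    def __init__(
        self,
        measurements: MeasurementSet,
        diameter: float,
        config: TRConfig = None,
        constants: PhysicsConstants = PhysicsConstants(),
        initial_guess=None,
        mesh_rel_size: float = 1.0 / 25.0,
    ):
        self.measurements = measurements
        self.diameter = float(diameter)
        self.config = config or TRConfig()
        self.constants = constants
        self.initial_guess = initial_guess
        self.mesh = build_circular_mesh(diameter, diameter * mesh_rel_size)
        self._elements = element_data(self.mesh)

    def _layout(self, mu_s_prime: float) -> ProbeLayout:
        return place_probes(
            self.diameter, self.constants, mu_s_prime_background=mu_s_prime
        )

    def fit(self) -> TikhonovResults:
        cfg = self.config
        meas = np.concatenate(
            [
                np.log(self.measurements.amplitude).ravel(),
                self.measurements.phase.ravel(),
            ]
        )
        bg = estimate_background(
            self.measurements,
            self.mesh,
            self.diameter,
            self.constants,
            x0=self.initial_guess or (0.0175, 1.75),
        )
        layout = self._layout(bg[1])
        n = self.mesh.n_nodes
        start = tuple(self.initial_guess) if self.initial_guess else bg
        mu_a = np.full(n, start[0])
        d = np.full(n, diffusion_coefficient(*start))

        def data_of(mu_a_v, d_v):
            system = assemble_mua_d(
                self.mesh,
                mu_a_v,
                d_v,
                self.measurements.frequency_mhz,
                self.constants,
                layout=layout,
                elements=self._elements,
            )
            state = _forward_state(system)
            la, ph = _log_amp_phase(state[2])
            return system, state, np.concatenate([la.ravel(), ph.ravel()])

        system, state, model = data_of(mu_a, d)
        residual = meas - model
        history = [float(np.linalg.norm(residual))]
        best = (mu_a.copy(), d.copy(), history[0])
        grow_streak = 0
        iterations = 0
        converged = history[0] < 1e-9 * float(np.linalg.norm(meas))
        diverged = False
        for _ in range(cfg.max_iterations if not converged else 0):
            iterations += 1
            jac = _jacobian_from_state(system, *state)
            # Gauss-Newton step in log-parameters: multiplicative updates
            # keep (mu_a, D) positive and put both blocks on one scale so
            # the identity regularizer acts evenly.
            x = np.concatenate([mu_a, d])
            jlog = jac.matrix * x[None, :]
            diag = np.einsum("ij,ij->j", jlog, jlog)
            lam = np.sqrt(cfg.lambda_relative * diag.max())
            dx = np.clip(tr_update(jlog, residual, lam), -2.0, 2.0)
            accepted = False
            alpha = 1.0
            for _ in range(10):
                x_new = np.maximum(x * np.exp(alpha * dx), cfg.positivity_floor)
                mu_a_new, d_new = x_new[:n], x_new[n:]
                system_new, state_new, model_new = data_of(mu_a_new, d_new)
                r_new = meas - model_new
                norm_new = float(np.linalg.norm(r_new))
                if norm_new <= history[-1]:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                grow_streak += 1
                if grow_streak >= 3:
                    diverged = True
                    break
                continue
            grow_streak = 0
            mu_a, d = mu_a_new, d_new
            system, state, model = system_new, state_new, model_new
            residual = meas - model
            history.append(norm_new)
            if norm_new < best[2]:
                best = (mu_a.copy(), d.copy(), norm_new)
            change = abs(history[-2] - history[-1]) / max(history[-2], 1e-30)
            if change < cfg.relative_residual_tolerance:
                converged = True
                break
        mu_a, d = best[0], best[1]
        mu_s = np.maximum(
            1.0 / (3.0 * d) - mu_a, cfg.positivity_floor
        )
        grid_mu_a = interpolate_to_grid(
            self.mesh, mu_a, self.diameter, GRID, fill=bg[0]
        )
        grid_mu_s = interpolate_to_grid(
            self.mesh, mu_s, self.diameter, GRID, fill=bg[1]
        )
        pitch = self.diameter / GRID
        centers = -self.diameter / 2 + pitch * (np.arange(GRID) + 0.5)
        xx, yy = np.meshgrid(centers, centers, indexing="xy")
        mask = np.hypot(xx, yy) <= self.diameter / 2
        image = PropertyImage(
            values=np.stack([grid_mu_a, grid_mu_s], axis=-1),
            pixel_pitch=pitch,
            domain_mask=mask,
        )
        return TikhonovResults(
            property_image=image,
            mu_a_nodal=mu_a,
            mu_s_prime_nodal=mu_s,
            mesh=self.mesh,
            residual_history=[float(h) for h in history],
            iterations_run=iterations,
            converged=converged,
            diverged=diverged,
            background_estimate=bg,
        )


def reconstruct_tr(
    measurements: MeasurementSet,
    diameter: float,
    config: TRConfig = None,
    **kwargs,
) -> TikhonovResults:
    """Functional wrapper around :class:`TikhonovReconstruction`."""
    return TikhonovReconstruction(
        measurements, diameter, config=config, **kwargs
    ).fit()
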