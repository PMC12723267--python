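import numpy as np
import pytest
import scipy.sparse.linalg as spla

from diffdot.forward import (
    PropertyField,
    assemble_system,
    element_data,
    interpolation_vector_sparse,
    measure,
    place_probes,
    solve_all,
    solve_forward,
    wrap_phase,
)
from diffdot.mesh import Mesh, build_circular_mesh
from diffdot.phantoms import Inclusion, Phantom, nodal_properties
from diffdot.physics import PhysicsConstants

PC = PhysicsConstants()


@pytest.fixture(scope="module")
def homogeneous_setup():
    mesh = build_circular_mesh(80.0, 80.0 / 20.0)
    props = PropertyField(
        np.full(mesh.n_nodes, 0.01), np.full(mesh.n_nodes, 1.0)
    )
    layout = place_probes(80.0, PC, mu_s_prime_background=1.0)
    return mesh, props, layout


# ---------------------------------------------------------------------------
# probe geometry

def test_probe_layout_240_pairs():
    layout = place_probes(100.0, PC, mu_s_prime_background=1.0)
    det = layout.detector_positions_per_source
    assert det.shape == (16, 15, 2)
    assert 16 * 15 == 240
    spacing = np.diff(layout.source_angles)
    assert np.allclose(np.degrees(spacing), 22.5)


def test_detectors_exclude_own_source_position():
    layout = place_probes(100.0, PC, mu_s_prime_background=1.0)
    angles = np.degrees(
        np.arctan2(
            layout.detector_positions_per_source[0, :, 1],
            layout.detector_positions_per_source[0, :, 0],
        )
    ) % 360
    assert np.allclose(sorted(angles), np.arange(1, 16) * 22.5)


def test_source_depth_is_transport_mean_free_path():
    layout = place_probes(100.0, PC, mu_s_prime_background=2.0)
    assert layout.source_depth_offset == pytest.approx(0.5)
    r_eff = np.linalg.norm(layout.effective_source_positions, axis=1)
    assert np.allclose(r_eff, 50.0 - 0.5)


# ---------------------------------------------------------------------------
# assembly against hand-built P1 elements

def unit_square_mesh():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 2, 3]])
    flags = np.ones(4, dtype=bool)
    return Mesh(coords, tris, flags, 1.0)


def test_element_matrices_match_hand_assembly():
    mesh = unit_square_mesh()
    data = element_data(mesh)
    # triangle (0,0),(1,0),(1,1): area 1/2, gradients (-1,0),(1,-1),(0,1)
    grads = np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]])
    k_hand = 0.5 * grads @ grads.T
    assert np.allclose(data.stiffness_unit[0], k_hand)
    m_hand = (0.5 / 12.0) * np.array(
        [[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]
    )
    assert np.allclose(data.mass_unit[0], m_hand)
    assert np.allclose(data.areas, [0.5, 0.5])


def test_zero_frequency_system_real_symmetric(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    system = assemble_system(mesh, props, 0.0, PC, layout)
    a = system.system_matrix
    assert abs(a.imag).max() == 0.0
    asym = abs(a - a.T).max()
    assert asym < 1e-12 * abs(a).max()


def test_imaginary_part_linear_in_frequency(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    a1 = assemble_system(mesh, props, 50.0, PC, layout).system_matrix
    a2 = assemble_system(mesh, props, 100.0, PC, layout).system_matrix
    assert np.allclose(a2.imag.toarray(), 2.0 * a1.imag.toarray())
    assert np.allclose(a2.real.toarray(), a1.real.toarray())


# ---------------------------------------------------------------------------
# solving and measuring

def test_zero_frequency_field_is_real(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    system = assemble_system(mesh, props, 0.0, PC, layout)
    field = solve_forward(system, 0)
    phi = field.nodal_photon_density
    assert abs(phi.imag).max() / abs(phi.real).max() < 1e-10
    m = measure(solve_all(system), layout, 0.0)
    assert abs(m.phase).max() < 1e-10
    assert (m.amplitude > 0).all()


def test_reciprocity_heterogeneous():
    mesh = build_circular_mesh(60.0, 60.0 / 18.0)
    phantom = Phantom(
        60.0, 0.008, 1.2, 70.0,
        inclusions=(Inclusion((8.0, -5.0), 9.0, 3.0, 2.0),),
    )
    props = nodal_properties(phantom, mesh)
    layout = place_probes(60.0, PC, mu_s_prime_background=1.2)
    system = assemble_system(mesh, props, 70.0, PC, layout)
    lu = spla.splu(system.system_matrix.tocsc())
    p = layout.effective_source_positions[0]
    d = layout.detector_positions_per_source[0, 7]
    w_p = interpolation_vector_sparse(mesh, p)
    w_d = interpolation_vector_sparse(mesh, d)
    m_pd = w_d @ lu.solve(w_p.astype(complex))
    m_dp = w_p @ lu.solve(w_d.astype(complex))
    assert abs(m_pd - m_dp) / abs(m_pd) < 1e-8


def test_amplitude_decreases_with_chord_distance(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    system = assemble_system(mesh, props, 50.0, PC, layout)
    m = measure(solve_all(system), layout, 50.0)
    det_map = layout.detector_index_map()
    for s in range(16):
        sep = (det_map[s] - s) % 16          # angular separation steps
        chord = np.minimum(sep, 16 - sep)    # chord grows to separation 8
        order = np.argsort(chord, kind="stable")
        ordered = m.amplitude[s][order]
        chords = chord[order]
        # strictly decreasing wherever the chord strictly increases
        for a, b in zip(range(14), range(1, 15)):
            if chords[b] > chords[a]:
                assert ordered[b] < ordered[a]


def test_source_scaling_linearity(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    system = assemble_system(mesh, props, 50.0, PC, layout)
    m1 = measure(solve_all(system), layout, 50.0)
    system.source_vectors = system.source_vectors * 3.0
    m2 = measure(solve_all(system), layout, 50.0)
    assert np.allclose(m2.amplitude, 3.0 * m1.amplitude, rtol=1e-12)
    assert np.allclose(m2.phase, m1.phase, atol=1e-12)


def test_wrap_phase_principal_interval(rng):
    raw = rng.uniform(-10, 10, size=1000)
    wrapped = wrap_phase(raw)
    assert (wrapped > -np.pi).all() and (wrapped <= np.pi).all()
    assert np.allclose(np.exp(1j * wrapped), np.exp(1j * raw))


def test_invalid_source_index(homogeneous_setup):
    mesh, props, layout = homogeneous_setup
    system = assemble_system(mesh, props, 50.0, PC, layout)
    with pytest.raises(IndexError):
        solve_forward(system, 16)
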