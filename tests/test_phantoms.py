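import numpy as np
import pytest
from scipy.stats import chisquare

from diffdot.forward import MeasurementSet
from diffdot.phantoms import (
    CATEGORY_PROBS,
    Inclusion,
    Phantom,
    add_noise,
    calibrate,
    calibration_channels,
    rasterize,
    sample_phantom,
    simulate,
)


# ---------------------------------------------------------------------------
# sampling

def test_sampling_deterministic():
    a = sample_phantom(123)
    b = sample_phantom(123)
    assert a == b


def test_sampled_parameters_within_ranges():
    rng = np.random.default_rng(0)
    for _ in range(200):
        p = sample_phantom(rng)
        assert 60 <= p.diameter <= 150
        assert 0.005 <= p.background_mu_a <= 0.03
        assert 0.5 <= p.background_mu_s_prime <= 3.0
        assert 10 <= p.frequency_mhz <= 100
        assert len(p.inclusions) <= 2
        for inc in p.inclusions:
            assert 2.0 <= inc.radius <= 30.0
            assert 1.5 <= inc.contrast_a <= 8.0
            assert 1.5 <= inc.contrast_s <= 8.0
            # fully inside the phantom
            r = np.hypot(*inc.center)
            assert r + inc.radius <= p.diameter / 2 + 1e-9
        if len(p.inclusions) == 2:
            a, b = p.inclusions
            gap = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            assert gap >= a.radius + b.radius


def test_category_proportions_converge():
    rng = np.random.default_rng(42)
    counts = np.zeros(3)
    n = 10000
    for _ in range(n):
        counts[len(sample_phantom(rng).inclusions)] += 1
    stat = chisquare(counts, np.array(CATEGORY_PROBS) * n)
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# rasterization

def test_rasterize_homogeneous_constant():
    p = Phantom(80.0, 0.01, 1.5, 50.0)
    img = rasterize(p)
    assert img.values.shape == (64, 64, 2)
    assert np.allclose(img.mu_a, 0.01)
    assert np.allclose(img.mu_s_prime, 1.5)
    assert img.pixel_pitch == pytest.approx(80.0 / 64)


def test_rasterize_inclusion_contrast_and_area():
    p = Phantom(
        64.0, 0.006, 1.0, 50.0,
        inclusions=(Inclusion((5.0, -3.0), 10.0, 4.0, 2.0),),
    )
    img = rasterize(p)
    # value at the inclusion center pixel
    iy = int(((-3.0) + 32.0) / img.pixel_pitch)
    ix = int((5.0 + 32.0) / img.pixel_pitch)
    assert img.mu_a[iy, ix] == pytest.approx(0.024)
    assert img.mu_s_prime[iy, ix] == pytest.approx(2.0)
    # pixel count of the zone close to the disk area
    n_in = int((img.mu_a > 0.02).sum())
    expected = np.pi * 10.0**2 / img.pixel_pitch**2
    perimeter_band = 2 * np.pi * 10.0 / img.pixel_pitch
    assert abs(n_in - expected) < perimeter_band


def test_domain_mask_marks_disk():
    p = Phantom(100.0, 0.01, 1.0, 20.0)
    img = rasterize(p)
    frac = img.domain_mask.mean()
    assert abs(frac - np.pi / 4) < 0.02  # disk fills pi/4 of the square


# ---------------------------------------------------------------------------
# simulation

def test_simulation_output_shape_and_symmetry():
    from diffdot.forward import place_probes

    p = Phantom(90.0, 0.012, 1.4, 60.0)
    m = simulate(p)
    assert m.amplitude.shape == (16, 15) and m.phase.shape == (16, 15)
    # homogeneous disk: measurement depends only on source-detector angular
    # separation, up to mesh-asymmetry interpolation error
    det_map = place_probes(90.0).detector_index_map()
    sep = (det_map - np.arange(16)[:, None]) % 16
    log_amp = np.log(m.amplitude)
    scale = log_amp.max() - log_amp.min()
    for k in range(1, 16):
        group_la = log_amp[sep == k]
        group_ph = m.phase[sep == k]
        assert group_la.std() / scale < 0.05
        assert group_ph.std() / (m.phase.max() - m.phase.min()) < 0.05


def test_absorbing_inclusion_attenuates_transmission():
    base = Phantom(80.0, 0.008, 1.0, 50.0)
    with_inc = Phantom(
        80.0, 0.008, 1.0, 50.0,
        inclusions=(Inclusion((0.0, 0.0), 15.0, 5.0, 1.0),),
    )
    m0 = simulate(base)
    m1 = simulate(with_inc)
    # transmission detectors (opposite side, index 7) see less light
    assert (m1.amplitude[:, 7] < m0.amplitude[:, 7]).all()


# ---------------------------------------------------------------------------
# noise

def _toy_measurement():
    amp = np.exp(np.random.default_rng(3).uniform(-8, -2, (16, 15)))
    phase = np.random.default_rng(4).uniform(0.1, 1.5, (16, 15))
    return MeasurementSet(amp, phase, 50.0)


def test_noise_level_zero_is_identity():
    m = _toy_measurement()
    out = add_noise(m, 0.0, rng=0)
    assert np.array_equal(out.amplitude, m.amplitude)
    assert np.array_equal(out.phase, m.phase)


def test_noise_is_zero_mean_and_has_requested_spread():
    m = _toy_measurement()
    rng = np.random.default_rng(11)
    ratios = []
    for _ in range(10000):
        noisy = add_noise(m, 0.15, rng)
        ratios.append(np.mean(noisy.amplitude / m.amplitude))
    assert abs(np.mean(ratios) - 1.0) < 3 * 0.15 / 100
    rel = np.concatenate(
        [
            (add_noise(m, 0.15, np.random.default_rng(100 + i)).amplitude
             / m.amplitude - 1.0).ravel()
            for i in range(5)
        ]
    )
    assert abs(np.std(rel) - 0.15) < 0.05 * 0.15


# ---------------------------------------------------------------------------
# calibration

def test_calibration_self_reference_zero():
    m = _toy_measurement()
    la, ph = calibration_channels(m, m)
    assert np.allclose(la, 0.0) and np.allclose(ph, 0.0)
    out = calibrate(m, m)
    assert out.array.shape == (16, 15, 2)
    assert np.allclose(out.array, 0.0)  # zero-range channels map to zero


def test_calibration_scaling_in_unit_interval_and_order_preserving():
    m = _toy_measurement()
    factors = np.exp(np.random.default_rng(7).uniform(-0.5, 0.5, (16, 15)))
    ref = MeasurementSet(
        m.amplitude * factors, m.phase - 0.2, m.frequency_mhz
    )
    out = calibrate(m, ref).array
    assert out.min() >= 0.0 and out.max() <= 1.0
    la, _ = calibration_channels(m, ref)
    assert np.array_equal(
        np.argsort(la.ravel()), np.argsort(out[..., 0].ravel())
    )


def test_calibration_rejects_nonpositive_amplitude():
    m = _toy_measurement()
    bad = MeasurementSet(m.amplitude.copy(), m.phase, 50.0)
    bad.amplitude[0, 0] = 0.0
    with pytest.raises(ValueError):
        calibrate(bad, m)
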