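"""Stimulus generator: carrier statistics, envelope geometry, set composition."""

from dataclasses import replace

import numpy as np
import pytest

from frfnet import stimuli
from frfnet.stimuli import (
    CarrierParams, EnvelopeParams, make_carrier, make_envelope, make_stimulus,
    make_stimulus_set, micropattern, to_uint8, trial_plan,
)

SMALL = CarrierParams(image_size=64, micropattern_count=128, micropattern_size=8,
                      uniformity_grid=2)


def test_carrier_requires_at_least_one_micropattern():
    with pytest.raises(ValueError):
        CarrierParams(micropattern_count=0)


def test_carrier_rms_contrast_is_exact():
    carrier = make_carrier(SMALL, seed=3)
    assert carrier.shape == (64, 64)
    assert abs(carrier.std() - 0.14) < 1e-6
    assert abs(carrier.mean()) < 1e-12


def test_carrier_is_deterministic_under_seed():
    a = make_carrier(SMALL, seed=11)
    b = make_carrier(SMALL, seed=11)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, make_carrier(SMALL, seed=12))


@pytest.mark.parametrize("seed", range(12))
def test_carrier_block_rms_uniformity_is_enforced(seed):
    """Accepted carriers satisfy the configured block-rms criterion."""
    params = SMALL
    carrier = make_carrier(params, seed=seed)
    g = params.uniformity_grid
    block = params.image_size // g
    blocks = carrier.reshape(g, block, g, block).swapaxes(1, 2).reshape(g * g, -1)
    block_rms = np.sqrt((blocks**2).mean(axis=1))
    global_rms = np.sqrt((carrier**2).mean())
    assert np.all(np.abs(block_rms - global_rms) <= params.uniformity_tolerance * global_rms)


def test_multi_orientation_carrier_builds():
    params = replace(SMALL, orientations=(0.0, 90.0), aspect_ratio=2.0)
    carrier = make_carrier(params, seed=2)
    assert abs(carrier.std() - 0.14) < 1e-6


def test_micropattern_is_odd_phase():
    patch = micropattern(16)
    # odd (sine) phase: zero at center, antisymmetric across the carrier axis
    assert patch[8, 8] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(patch, -patch[:, ::-1], atol=1e-12)


def test_envelope_zero_on_boundary_line():
    # the center lies between pixels; the two pixels straddling the boundary
    # have antisymmetric envelope values averaging to zero
    env, _ = make_envelope(EnvelopeParams(orientation=45.0, image_size=64))
    assert env[31, 31] + env[32, 32] == pytest.approx(0.0, abs=1e-12)
    assert abs(env[31, 31]) < 0.25  # within the half-cosine taper, near zero


def test_envelope_phase_flip_negates():
    p0 = EnvelopeParams(orientation=45.0, image_size=64, phase=0)
    p180 = EnvelopeParams(orientation=45.0, image_size=64, phase=180)
    e0, w0 = make_envelope(p0)
    e180, w180 = make_envelope(p180)
    np.testing.assert_allclose(e180, -e0)
    np.testing.assert_array_equal(w0, w180)


def test_envelope_mirror_symmetry_between_oblique_orientations():
    ep, _ = make_envelope(EnvelopeParams(orientation=45.0, image_size=64))
    em, _ = make_envelope(EnvelopeParams(orientation=-45.0, image_size=64))
    np.testing.assert_allclose(ep[:, ::-1], em, atol=1e-12)


def test_envelope_taper_slope_matches_half_cosine():
    """Max |dE/ds| along the boundary normal equals pi / taper width."""
    n = 128
    env, _ = make_envelope(EnvelopeParams(orientation=90.0, image_size=n))
    # orientation 90: boundary is horizontal, normal along y -> columns vary
    profile = env[:, n // 2]
    slope = np.max(np.abs(np.diff(profile)))
    assert slope == pytest.approx(np.pi / (0.2 * n), rel=0.05)


def test_envelope_values_bounded():
    env, w = make_envelope(EnvelopeParams(orientation=30.0, image_size=64))
    assert env.min() >= -1 and env.max() <= 1
    assert w.min() >= 0 and w.max() <= 1


def test_stimulus_composition_and_m_zero():
    carrier = make_carrier(SMALL, seed=5)
    env, w = make_envelope(EnvelopeParams(orientation=45.0, image_size=64))
    s0 = make_stimulus(carrier, env, w, 0.0)
    np.testing.assert_allclose(s0, w * carrier)
    with pytest.raises(ValueError):
        make_stimulus(carrier, env[:32, :32], w, 0.2)
    with pytest.raises(ValueError):
        make_stimulus(carrier, env, w, 1.5)


def test_full_modulation_extinguishes_low_side():
    carrier = make_carrier(SMALL, seed=5)
    env, w = make_envelope(EnvelopeParams(orientation=45.0, image_size=64, phase=0))
    s1 = make_stimulus(carrier, env, w, 1.0)
    low = (env < -0.99) & (w > 0.99)
    high = (env > 0.99) & (w > 0.99)
    assert s1[low].std() < 1e-3 * s1[high].std()
    assert s1[high].std() > 0.1


def test_side_rms_ratio_matches_modulation():
    """Side-wise rms contrast ratio approximates (1+m)/(1-m) in taper-free interiors."""
    m = 0.32
    ratios = []
    env, w = make_envelope(EnvelopeParams(orientation=45.0, image_size=64, phase=0))
    high = (env > 0.99) & (w > 0.99)
    low = (env < -0.99) & (w > 0.99)
    for seed in range(8):
        carrier = make_carrier(SMALL, seed=seed)
        stim = make_stimulus(carrier, env, w, m)
        ratios.append(stim[high].std() / stim[low].std())
    assert np.mean(ratios) == pytest.approx((1 + m) / (1 - m), rel=0.1)


def test_no_first_order_cue():
    """Mean luminance contrast in each half-disc interior is ~0 (zero-mean carrier)."""
    env, w = make_envelope(EnvelopeParams(orientation=45.0, image_size=64, phase=0))
    high = (env > 0.99) & (w > 0.99)
    means = []
    for seed in range(8):
        stim = make_stimulus(make_carrier(SMALL, seed=seed), env, w, 0.32)
        means.append(stim[high].mean())
    assert abs(np.mean(means)) < 0.01


def test_trial_plan_balance_and_determinism(tiny_design):
    plan = trial_plan(tiny_design, 40, seed=1)
    assert len(plan) == 40
    levels = [p[1] for p in plan]
    for level in tiny_design.levels:
        assert sum(np.isclose(levels, level)) == 4
    cats = [p[2] for p in plan]
    assert abs(cats.count("L") - cats.count("R")) <= len(tiny_design.levels)
    assert plan == trial_plan(tiny_design, 40, seed=1)
    with pytest.raises(ValueError):
        trial_plan(tiny_design, 41, seed=1)


def test_stimulus_set_reproducible_and_unique_carriers(tiny_design):
    a = make_stimulus_set(tiny_design, 10, seed=4)
    b = make_stimulus_set(tiny_design, 10, seed=4)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.pixels, sb.pixels)
        assert sa.category == sb.category and sa.phase == sb.phase
    assert len({s.seed for s in a}) == 10  # never the same carrier twice


def test_design_level_grids():
    d1 = stimuli.get_design("exp1_var")
    assert len(d1.levels) == 10 and d1.levels[0] == 0.0
    np.testing.assert_allclose(d1.levels[1], 0.08)
    np.testing.assert_allclose(d1.levels[-1], 0.32)
    np.testing.assert_allclose(d1.levels[5], np.sqrt(0.08 * 0.32), rtol=1e-9)  # centered at 16%
    d2 = stimuli.get_design("exp2_var")
    np.testing.assert_allclose([d2.levels[1], d2.levels[-1]], [0.16, 0.64])
    assert stimuli.get_design("exp2_fix", jnd_deg=6.0).boundary_orientation == 6.0
    with pytest.raises(ValueError):
        stimuli.get_design("exp4")


def test_to_uint8_midpoint():
    assert to_uint8(np.zeros((2, 2)))[0, 0] == 128
    assert to_uint8(np.array([[1.0, -1.0]])).tolist() == [[255, 1]]
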