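"""Wrap-simulation correctness: the single-wrap relation, the modular
generalization against a brute-force oracle, ground-truth exactness, and the
mask-driven round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowunwrap.aliasing import WrapSpec, draw_venc_fractions, unwrap_with_mask, wrap_velocity
from flowunwrap.core import VelocityField


def _wrap_scalar_oracle(v, venc):
    """Brute force: shift by 2*venc until the value lies in [-venc, venc)."""
    while v >= venc:
        v -= 2 * venc
    while v < -venc:
        v += 2 * venc
    return v


def make_field(values, venc=150.0):
    values = np.asarray(values, dtype=float)
    return VelocityField(values=values, venc=venc)


class TestWrapVelocity:
    def test_single_wrap_worked_example(self):
        # 1.0 m/s at a simulated venc of 0.6 m/s folds to -0.2 m/s
        vals = np.zeros((1, 1, 1, 1, 3))
        vals[..., 2] = 100.0  # cm/s
        field = make_field(vals, venc=150.0)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_sim=60.0))
        assert aliased.values[0, 0, 0, 0, 2] == pytest.approx(-20.0)
        assert truth[0, 0, 0, 0, 2]
        assert aliased.venc == 60.0

    def test_below_venc_is_identity(self):
        vals = np.zeros((1, 1, 1, 1, 3))
        vals[..., 2] = 50.0
        field = make_field(vals, venc=150.0)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_sim=60.0))
        assert aliased.values[0, 0, 0, 0, 2] == 50.0
        assert not truth.any()

    def test_uniform_grid_matches_brute_force_oracle(self):
        venc = 100.0
        vt = np.linspace(-300.0, 300.0, 1201, endpoint=False)
        vals = np.zeros((vt.size, 1, 1, 1, 3))
        vals[:, 0, 0, 0, 0] = vt
        field = make_field(vals, venc=400.0)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_sim=venc))
        expected = np.array([_wrap_scalar_oracle(v, venc) for v in vt])
        np.testing.assert_allclose(aliased.values[:, 0, 0, 0, 0], expected, atol=1e-9)
        np.testing.assert_array_equal(truth[:, 0, 0, 0, 0], vt != expected)

    def test_boundary_value_wraps_to_negative_venc(self):
        vals = np.zeros((1, 1, 1, 1, 3))
        vals[..., 0] = 100.0
        field = make_field(vals, venc=150.0)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_sim=100.0))
        assert aliased.values[0, 0, 0, 0, 0] == -100.0
        assert truth[0, 0, 0, 0, 0]

    def test_output_range_half_open(self, noisy_phantom):
        field, _, _ = noisy_phantom
        aliased, _ = wrap_velocity(field, WrapSpec(venc_fraction=0.4))
        assert aliased.values.min() >= -aliased.venc
        assert aliased.values.max() < aliased.venc

    def test_truth_mask_is_magnitude_threshold_on_clean_fields(self, ubend_clean):
        field, _, _ = ubend_clean
        aliased, truth = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        np.testing.assert_array_equal(truth, np.abs(field.values) >= aliased.venc)

    def test_monotone_mask_growth_when_lowering_venc(self, ubend_clean):
        field, _, _ = ubend_clean
        _, t_high = wrap_velocity(field, WrapSpec(venc_fraction=0.7))
        _, t_low = wrap_velocity(field, WrapSpec(venc_fraction=0.4))
        assert np.all(t_low | ~t_high)  # every 0.7-aliased voxel also aliases at 0.4

    def test_input_not_modified(self, ubend_clean):
        field, _, _ = ubend_clean
        before = field.values.copy()
        wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        np.testing.assert_array_equal(field.values, before)

    def test_venc_sim_at_or_above_original_rejected(self, ubend_clean):
        field, _, _ = ubend_clean
        for bad in (field.venc, field.venc * 1.5):
            with pytest.raises(ValueError):
                wrap_velocity(field, WrapSpec(venc_sim=bad))
        with pytest.raises(ValueError):
            WrapSpec(venc_sim=50.0, venc_fraction=0.5).resolve(150.0)

    @settings(max_examples=50, deadline=None)
    @given(
        vt=st.floats(min_value=-299.0, max_value=299.0),
        venc=st.floats(min_value=10.0, max_value=100.0),
    )
    def test_wrapped_value_in_range_and_congruent(self, vt, venc):
        vals = np.full((1, 1, 1, 1, 3), vt)
        field = make_field(vals, venc=300.0)
        aliased, truth = wrap_velocity(field, WrapSpec(venc_sim=venc))
        va = aliased.values[0, 0, 0, 0, 0]
        assert -venc <= va < venc
        # differs from the true value by an exact multiple of 2*venc
        k = round((vt - va) / (2 * venc))
        assert va + 2 * venc * k == pytest.approx(vt, abs=1e-9)
        assert bool(truth[0, 0, 0, 0, 0]) == (k != 0)


class TestUnwrapWithMask:
    def test_inverse_of_single_wrap(self):
        vals = np.full((1, 1, 1, 1, 3), -20.0)
        aliased = make_field(vals, venc=60.0)
        mask = np.ones_like(vals, dtype=bool)
        out = unwrap_with_mask(aliased, mask)
        assert out.values[0, 0, 0, 0, 0] == pytest.approx(100.0)

    def test_empty_mask_is_identity(self, ubend_clean):
        field, _, _ = ubend_clean
        aliased, _ = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        out = unwrap_with_mask(aliased, np.zeros(aliased.shape, bool))
        np.testing.assert_array_equal(out.values, aliased.values)

    def test_round_trip_restores_clean_fields_bit_exactly(self):
        # invertible regime: every wrapped magnitude below 2*venc_sim
        from flowunwrap.phantom import PhantomSpec, generate_phantom

        for seed in range(6):
            spec = PhantomSpec(grid_shape=(32, 24, 8), n_frames=6, vessel_radius=10.0,
                               snr=np.inf, seed=seed)
            field, _, _ = generate_phantom(spec)
            aliased, truth = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
            assert 2 * aliased.venc > np.abs(field.values).max()
            out = unwrap_with_mask(aliased, truth)
            assert np.array_equal(out.values, field.values)

    def test_corrected_magnitudes_exceed_venc(self, ubend_clean):
        field, _, _ = ubend_clean
        aliased, truth = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        out = unwrap_with_mask(aliased, truth)
        mags = np.abs(out.values[truth])
        assert np.all(mags > aliased.venc)
        assert np.all(mags <= 3 * aliased.venc)

    def test_shape_mismatch_rejected(self, ubend_clean):
        field, _, _ = ubend_clean
        aliased, _ = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        with pytest.raises(ValueError):
            unwrap_with_mask(aliased, np.zeros((2, 2, 2, 2, 3), bool))

    def test_mismatched_venc_rejected(self, ubend_clean):
        field, _, _ = ubend_clean
        aliased, truth = wrap_velocity(field, WrapSpec(venc_fraction=0.5))
        with pytest.raises(ValueError):
            unwrap_with_mask(aliased, truth, venc=aliased.venc * 2)


def test_draw_venc_fractions_range_and_determinism():
    f1 = draw_venc_fractions(1000, rng=9)
    f2 = draw_venc_fractions(1000, rng=9)
    np.testing.assert_array_equal(f1, f2)
    assert f1.min() >= 0.40 and f1.max() <= 0.70
    # spread across the whole range, not clustered
    assert np.ptp(f1) > 0.25
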