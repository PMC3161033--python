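import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoromix import (
    Roi,
    SpectralChannel,
    Spectrum,
    apply_nfe_correction,
    build_autofluorescence_reference,
    build_dsred_reference,
    default_channelset,
    extract_mean_spectrum,
)
from fluoromix.spectra import NFE, RADIANCE, ChannelSet, SpectralStack

from conftest import make_stack


class TestTypes:
    def test_stokes_shift_enforced(self):
        with pytest.raises(ValueError, match="excitation"):
            SpectralChannel(600, 540)

    @pytest.mark.parametrize("factor", [0.0, -1.0, float("nan")])
    def test_correction_factor_positive(self, factor):
        with pytest.raises(ValueError, match="correction_factor"):
            SpectralChannel(465, 540, correction_factor=factor)

    def test_channelset_rejects_duplicates(self):
        ch = SpectralChannel(465, 540)
        with pytest.raises(ValueError, match="duplicate"):
            ChannelSet((ch, SpectralChannel(465, 540, correction_factor=2.0)))

    def test_stack_rejects_nan(self, channelset4):
        data = np.ones((4, 3, 3))
        data[2, 1, 2] = np.nan
        with pytest.raises(ValueError, match=r"channel 2.*row=1.*col=2"):
            SpectralStack(data, channelset4)

    def test_stack_channel_count_mismatch(self, channelset4):
        with pytest.raises(ValueError, match="pages"):
            SpectralStack(np.ones((3, 2, 2)), channelset4)

    def test_spectrum_rejects_zero_vector(self):
        with pytest.raises(ValueError, match="zero vector"):
            Spectrum(np.zeros(4))

    def test_roi_helpers(self):
        rect = Roi.rectangle(1, 2, 2, 3)
        assert len(rect) == 6 and (1, 2) in rect and (2, 4) in rect
        disk = Roi.disk((5, 5), 1.0)
        assert set(disk) == {(5, 5), (4, 5), (6, 5), (5, 4), (5, 6)}

    def test_roi_nonempty_and_bounds(self):
        with pytest.raises(ValueError, match="at least one"):
            Roi([])
        roi = Roi([(0, 0), (5, 5)])
        with pytest.raises(ValueError, match="bounds"):
            roi.check_bounds((4, 4))


class TestNfeCorrection:
    def test_unit_factors_identity(self):
        cs = default_channelset()  # all factors 1.0
        stack = make_stack(np.arange(4.0) + 1, cs, units=RADIANCE)
        out = apply_nfe_correction(stack)
        assert out.units == NFE
        np.testing.assert_array_equal(out.data, stack.data)

    def test_elementwise_division(self, channelset4):
        # factors (1, 0.8, 1.25, 2): pixel (8, 8, 10, 6) -> (8, 10, 8, 3)
        stack = make_stack([8.0, 8.0, 10.0, 6.0], channelset4, units=RADIANCE)
        out = apply_nfe_correction(stack)
        np.testing.assert_allclose(out.data[:, 0, 0], [8.0, 10.0, 8.0, 3.0], rtol=1e-15)

    def test_requires_radiance_units(self, channelset4):
        stack = make_stack(np.ones(4), channelset4, units=NFE)
        with pytest.raises(ValueError, match="radiance"):
            apply_nfe_correction(stack)

    @settings(deadline=None, max_examples=25)
    @given(
        alpha=st.floats(-5, 5, allow_nan=False),
        beta=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, alpha, beta, seed):
        """Correction of αX + βY equals α·corr(X) + β·corr(Y)."""
        cs = default_channelset([1.0, 0.8, 1.25, 2.0])
        r = np.random.default_rng(seed)
        X, Y = r.uniform(0, 10, (4, 5, 5)), r.uniform(0, 10, (4, 5, 5))
        corr = lambda arr: apply_nfe_correction(
            SpectralStack(arr, cs, units=RADIANCE)
        ).data
        np.testing.assert_allclose(
            corr(alpha * X + beta * Y), alpha * corr(X) + beta * corr(Y), atol=1e-10
        )


class TestMeanSpectrum:
    def test_singleton_and_constant(self, channelset4, rng):
        data = rng.uniform(0, 5, (4, 6, 6))
        stack = SpectralStack(data, channelset4, units=NFE)
        s = extract_mean_spectrum(stack, Roi([(2, 3)]))
        np.testing.assert_array_equal(s.values, data[:, 2, 3])
        const = make_stack(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 4)).reshape(4, 2, 2), channelset4)
        s2 = extract_mean_spectrum(const, Roi.rectangle(0, 0, 2, 2))
        np.testing.assert_allclose(s2.values, [1, 2, 3, 4])

    def test_two_pixel_mean(self, channelset4):
        data = np.zeros((4, 1, 2))
        data[:, 0, 0] = [1, 2, 3, 4]
        data[:, 0, 1] = [3, 2, 1, 0]
        stack = SpectralStack(data, channelset4, units=NFE)
        s = extract_mean_spectrum(stack, Roi([(0, 0), (0, 1)]))
        np.testing.assert_allclose(s.values, [2, 2, 2, 2])

    def test_order_invariance(self, channelset4, rng):
        data = rng.uniform(0, 5, (4, 8, 8))
        stack = SpectralStack(data, channelset4, units=NFE)
        pixels = [(1, 1), (5, 2), (0, 7), (3, 3)]
        a = extract_mean_spectrum(stack, Roi(pixels))
        b = extract_mean_spectrum(stack, Roi(reversed(pixels)))
        np.testing.assert_array_equal(a.values, b.values)


class TestReferences:
    def test_autofluor_3_4_5(self, channelset4):
        stack = make_stack([3.0, 0.0, 4.0, 0.0], channelset4)
        ref = build_autofluorescence_reference(stack, Roi([(0, 0)]))
        np.testing.assert_allclose(ref.values, [0.6, 0, 0.8, 0], atol=1e-15)
        assert ref.normalized and ref.label == "autofluorescence"

    def test_autofluor_idempotent_on_unit(self, channelset4):
        v = np.array([1.0, 1.0, 1.0, 1.0]) / 2.0
        ref = build_autofluorescence_reference(make_stack(v, channelset4), Roi([(0, 0)]))
        np.testing.assert_allclose(ref.values, v, rtol=1e-15)

    def test_autofluor_unit_norm_invariant(self, channelset4, rng):
        for _ in range(20):
            stack = make_stack(rng.uniform(0.1, 9, 4), channelset4)
            ref = build_autofluorescence_reference(stack, Roi([(0, 0)]))
            assert abs(np.linalg.norm(ref.values) - 1) < 1e-12

    def test_projection_arithmetic(self, channelset4):
        a_hat = Spectrum(np.array([1.0, 0, 0, 0]), "autofluorescence").unit()
        stack = make_stack([2.0, 3.0, 0.0, 0.0], channelset4)
        d = build_dsred_reference(stack, Roi([(0, 0)]), a_hat, subtract_mode="projection")
        np.testing.assert_allclose(d.values, [0, 1, 0, 0], atol=1e-15)

    def test_projection_orthogonality(self, channelset4, rng):
        """Projection-mode output is orthogonal to the background reference."""
        for _ in range(20):
            a_hat = Spectrum(rng.uniform(0.1, 1, 4)).unit("autofluorescence")
            stack = make_stack(rng.uniform(0.1, 5, 4), channelset4)
            d = build_dsred_reference(
                stack, Roi([(0, 0)]), a_hat, subtract_mode="projection"
            )
            assert abs(d.values @ a_hat.values) < 1e-10
            assert abs(np.linalg.norm(d.values) - 1) < 1e-12

    def test_pure_autofluorescence_region_errors(self, channelset4):
        a_hat = Spectrum(np.array([0.5, 0.5, 0.5, 0.5]), "autofluorescence").unit()
        stack = make_stack(5 * a_hat.values, channelset4)
        with pytest.raises(ValueError, match="indistinguishable"):
            build_dsred_reference(stack, Roi([(0, 0)]), a_hat, subtract_mode="projection")

    def test_direct_mode_recovers_true_spectrum(self, channelset4):
        """Subtracting the same-ROI background spectrum cancels it exactly."""
        a = Spectrum(np.array([0.62, 0.54, 0.45, 0.34])).unit("autofluorescence")
        d_true = Spectrum(np.array([0.05, 0.15, 0.35, 0.92])).unit("DsRed")
        background = Spectrum(1.7 * a.values, "background")  # unscaled day-0 mean
        mixed = make_stack(1.7 * a.values + 2.3 * d_true.values, channelset4)
        d = build_dsred_reference(
            mixed, Roi([(0, 0)]), a, subtract_mode="direct", background=background
        )
        np.testing.assert_allclose(d.values, d_true.values, atol=1e-12)

    def test_orthogonal_mean_passes_through(self, channelset4):
        a_hat = Spectrum(np.array([1.0, 0, 0, 0])).unit("autofluorescence")
        m = np.array([0.0, 0.0, 3.0, 4.0])
        d = build_dsred_reference(
            make_stack(m, channelset4), Roi([(0, 0)]), a_hat, subtract_mode="projection"
        )
        np.testing.assert_allclose(d.values, [0, 0, 0.6, 0.8], atol=1e-15)
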