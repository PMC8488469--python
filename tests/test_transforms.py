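import numpy as np
import pytest
from scipy.signal import hilbert as scipy_hilbert

from plantppi.io_formats import Profile
from plantppi.profiles import CondensedMatrix
from plantppi.transforms import (
    alt_features,
    dht1,
    dht2,
    dht_features,
    extract_descriptor,
)


def brute_force_analytic(x):
    """Direct DFT -> one-sided mask -> inverse DFT, written from the
    definition with explicit loops."""
    n = len(x)
    X = np.array(
        [sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)) for k in range(n)]
    )
    h = np.zeros(n)
    h[0] = 1
    if n % 2 == 0:
        h[n // 2] = 1
        h[1 : n // 2] = 2
    else:
        h[1 : (n + 1) // 2] = 2
    Xm = X * h
    return np.array(
        [sum(Xm[k] * np.exp(2j * np.pi * k * t / n) for k in range(n)) / n for t in range(n)]
    )


class TestDht1:
    def test_constant_has_zero_imaginary_part(self):
        out = dht1(np.full(8, 3.5))
        np.testing.assert_allclose(out.real, 3.5)
        np.testing.assert_allclose(out.imag, 0.0, atol=1e-12)

    def test_cosine_quadrature_pair(self):
        N = 16
        t = np.arange(N)
        out = dht1(np.cos(2 * np.pi * t / N))
        np.testing.assert_allclose(out.imag, np.sin(2 * np.pi * t / N), atol=1e-10)

    def test_impulse_matches_brute_force_dft(self):
        x = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(dht1(x), brute_force_analytic(x), atol=1e-12)

    @pytest.mark.parametrize("n", [5, 8, 13, 16])
    def test_real_part_identity(self, rng, n):
        x = rng.normal(size=n)
        np.testing.assert_allclose(dht1(x).real, x, atol=1e-9)

    @pytest.mark.parametrize("n", [6, 7, 16, 21])
    def test_one_sided_spectrum(self, rng, n):
        x = rng.normal(size=n)
        spectrum = np.fft.fft(dht1(x))
        negative = spectrum[(n // 2) + 1 :]
        np.testing.assert_allclose(np.abs(negative), 0.0, atol=1e-9)

    def test_matches_scipy_hilbert(self, rng):
        x = rng.normal(size=32)
        np.testing.assert_allclose(dht1(x), scipy_hilbert(x), atol=1e-10)

    def test_padding_and_truncation(self, rng):
        x = rng.normal(size=10)
        padded = dht1(x, n=16)
        np.testing.assert_allclose(padded.real, np.pad(x, (0, 6)), atol=1e-9)
        truncated = dht1(x, n=6)
        np.testing.assert_allclose(truncated.real, x[:6], atol=1e-9)

    def test_complex_input_warns_and_uses_real_part(self):
        with pytest.warns(UserWarning, match="imaginary"):
            out = dht1(np.array([1 + 2j, 3 + 4j]))
        np.testing.assert_allclose(out.real, [1, 3], atol=1e-12)

    def test_invalid_length_errors(self):
        with pytest.raises(ValueError):
            dht1(np.ones(4), n=0)


class TestDht2:
    def test_zeros_map_to_zeros(self):
        out = dht2(np.zeros((20, 20)))
        np.testing.assert_array_equal(out.values, np.zeros((20, 20), dtype=complex))

    def test_equals_sequential_1d_application(self, rng):
        M = rng.normal(size=(20, 20))
        # columns first, then rows of the (complex) intermediate: apply the
        # 1-D mask to the rows in the frequency domain directly
        inter = np.array([dht1(M[:, j]) for j in range(20)]).T
        h = np.zeros(20)
        h[0] = h[10] = 1
        h[1:10] = 2
        rows = np.fft.ifft(np.fft.fft(inter, axis=1) * h, axis=1)
        np.testing.assert_allclose(dht2(M).values, rows, atol=1e-10)

    def test_matches_sequential_scipy_hilbert(self, rng):
        """Independent oracle: scipy's 1-D analytic signal applied along
        columns, then (by linearity) along rows of the complex result."""
        M = rng.normal(size=(20, 20))
        cols = scipy_hilbert(M, axis=0)
        rows = scipy_hilbert(cols.real, axis=1) + 1j * scipy_hilbert(
            cols.imag, axis=1
        )
        np.testing.assert_allclose(dht2(M).values, rows, atol=1e-10)

    def test_linearity(self, rng):
        M = rng.normal(size=(20, 20))
        np.testing.assert_allclose(dht2(3 * M).values, 3 * dht2(M).values, atol=1e-10)

    def test_wrong_shape_errors(self):
        with pytest.raises(ValueError):
            dht2(np.ones((10, 10)))


class TestDhtFeatures:
    def test_zeros_give_zero_vector(self):
        desc = dht_features(np.zeros((20, 20)))
        assert desc.dim == 400
        np.testing.assert_array_equal(desc.values, np.zeros(400))

    def test_length_is_400_and_nonnegative(self, rng):
        desc = dht_features(rng.normal(size=(20, 20)))
        assert desc.dim == 400
        assert np.all(desc.values >= 0)

    def test_entries_match_elementwise_modulus(self, rng):
        M = rng.normal(size=(20, 20))
        desc = dht_features(M)
        analytic = dht2(M).values
        for i, j in [(0, 0), (3, 17), (19, 19), (7, 2)]:
            assert desc.values[20 * i + j] == pytest.approx(abs(analytic[i, j]))

    def test_squared_energy_option(self, rng):
        M = rng.normal(size=(20, 20))
        np.testing.assert_allclose(
            dht_features(M, energy="squared").values,
            dht_features(M).values ** 2,
            atol=1e-12,
        )


class TestAltFeatures:
    @pytest.mark.parametrize("kind,dim", [("dct", 400), ("fft", 400), ("dwt", 400)])
    def test_zeros_give_zero_vector(self, kind, dim):
        desc = alt_features(np.zeros((20, 20)), kind)
        assert desc.dim == dim
        np.testing.assert_array_equal(desc.values, np.zeros(dim))

    def test_dct_of_constant_concentrates_at_dc(self):
        desc = alt_features(np.full((20, 20), 2.0), "dct")
        coeffs = desc.values.reshape(20, 20)
        assert coeffs[0, 0] != 0
        rest = coeffs.copy()
        rest[0, 0] = 0
        np.testing.assert_allclose(rest, 0.0, atol=1e-10)

    def test_fft_is_modulus_of_2d_dft(self, rng):
        M = rng.normal(size=(20, 20))
        np.testing.assert_allclose(
            alt_features(M, "fft").values, np.abs(np.fft.fft2(M)).ravel()
        )

    def test_dwt_haar_subband_layout(self, rng):
        import pywt

        M = rng.normal(size=(20, 20))
        cA, (cH, cV, cD) = pywt.dwt2(M, "haar")
        desc = alt_features(M, "dwt")
        np.testing.assert_allclose(desc.values[:100], cA.ravel())
        np.testing.assert_allclose(desc.values[300:], cD.ravel())

    def test_ac_hand_evaluated_single_column(self):
        # column [1,2,3] at lag 1: ((1-2)(2-2)+(2-2)(3-2))/2 = 0
        P = np.zeros((3, 20))
        P[:, 0] = [1, 2, 3]
        desc = alt_features(Profile(P, source="synthetic"), "ac", ac_lag=1)
        assert desc.dim == 20
        assert desc.values[0] == pytest.approx(0.0)

    def test_ac_matches_formula(self, rng):
        U, g = 30, 5
        P = rng.normal(size=(U, 20))
        desc = alt_features(Profile(P, source="synthetic"), "ac", ac_lag=g)
        assert desc.dim == 100
        means = P.mean(axis=0)
        j, lag = 7, 3
        expected = sum(
            (P[t, j] - means[j]) * (P[t + lag, j] - means[j]) for t in range(U - lag)
        ) / (U - lag)
        assert desc.values[j * g + (lag - 1)] == pytest.approx(expected)

    def test_ac_lag_too_large_errors(self):
        P = np.ones((4, 20))
        with pytest.raises(ValueError, match="lag"):
            alt_features(Profile(P, source="synthetic"), "ac", ac_lag=5)

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError):
            alt_features(np.zeros((20, 20)), "pca")

    @pytest.mark.parametrize("kind", ["dct", "dwt"])
    def test_linearity_of_linear_transforms(self, rng, kind):
        A = rng.normal(size=(20, 20))
        B = rng.normal(size=(20, 20))
        fa = alt_features(A, kind).values
        fb = alt_features(B, kind).values
        fab = alt_features(A + 2 * B, kind).values
        np.testing.assert_allclose(fab, fa + 2 * fb, atol=1e-9)


class TestExtractDescriptor:
    def test_dispatch_matches_direct_calls(self, rng):
        P = Profile(rng.normal(size=(40, 20)), source="synthetic")
        from plantppi.profiles import condense

        M = condense(P)
        np.testing.assert_array_equal(
            extract_descriptor(P, "dht").values, dht_features(M).values
        )
        np.testing.assert_array_equal(
            extract_descriptor(P, "ac").values,
            alt_features(P, "ac", ac_lag=5).values,
        )
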